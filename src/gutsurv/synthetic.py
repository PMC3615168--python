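"""Synthetic study data with known ground truth.

Two generators make every other module testable without external files:

* :func:`simulate_acute_test` draws acute-test survivor trajectories from
  known GUTS parameters under a standard OECD-203-style design (geometric
  concentration series held for four days, daily counts, pooled control
  groups), exactly reproducing each limit case's probabilistic assumptions
  — conditional-binomial interval deaths for stochastic death, one
  log-logistic threshold per fish compared with the running dose-metric
  maximum for individual tolerance.

* :func:`generate_pulse_train` emits multi-pulse exposure profiles of the
  statistical shape of drainage-scenario fate-model output — log-normal
  pulse heights, durations and gaps, an exponentially decaying tail after
  each pulse, and an optional raised baseline — together with the true
  pulse boundaries for validating peak detection.  It emulates only the
  statistical shape of such output, not the underlying fate physics.

All randomness flows through one seeded generator per call.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np

from .core import GUTSParams, ITParams, SDParams
from .exposure import ExposureProfile
from .likelihood import ControlGroup, SurvivalDataset, Treatment, survival_at_constant

__all__ = ["AcuteTestDesign", "PulseTrainDesign", "PulseMeta",
           "simulate_acute_test", "generate_pulse_train"]

# carp-like stochastic-death truth used as the default generating model
_DEFAULT_TRUTH = SDParams(ke=1.0, kk=1.42, z=4.06, h_controls=0.018)


@dataclass(frozen=True)
class AcuteTestDesign:
    """Design of a simulated acute toxicity test.

    Defaults mirror a standard 96-h fish acute test: six concentrations in
    a geometric series of which only the two highest exceed the effect
    threshold, daily observations, and two unexposed (control and solvent
    control) groups.
    """

    concentrations: tuple[float, ...] = (0.56, 1.0, 1.8, 3.2, 5.6, 10.0)
    n_fish: int = 10
    observation_times: tuple[float, ...] = (0.0, 1.0, 2.0, 3.0, 4.0)
    params: GUTSParams = _DEFAULT_TRUTH
    n_control_groups: int = 2
    seed: int | None = None

    def __post_init__(self) -> None:
        if any(c < 0 for c in self.concentrations):
            raise ValueError("concentrations must be >= 0")
        if self.n_fish <= 0:
            raise ValueError("n_fish must be positive")
        times = np.asarray(self.observation_times, dtype=float)
        if times[0] != 0.0 or not np.all(np.diff(times) > 0):
            raise ValueError("observation times must start at 0 and increase")


def _sd_trajectory(rng, n_fish: int, s: np.ndarray) -> np.ndarray:
    """Conditional-binomial survivor counts given the survival curve."""
    counts = np.empty(s.size, dtype=int)
    counts[0] = n_fish
    for i in range(1, s.size):
        p = s[i] / s[i - 1] if s[i - 1] > 0 else 0.0
        counts[i] = rng.binomial(counts[i - 1], min(max(p, 0.0), 1.0))
    return counts


def _it_trajectory(rng, n_fish: int, times: np.ndarray,
                   running_max: np.ndarray, params: ITParams) -> np.ndarray:
    """Per-fish thresholds vs the running dose-metric maximum, plus
    exponential background deaths."""
    u = rng.uniform(size=n_fish)
    thresholds = params.alpha * (u / (1.0 - u)) ** (1.0 / params.beta)
    if params.h_controls > 0:
        bg_death = rng.exponential(1.0 / params.h_controls, size=n_fish)
    else:
        bg_death = np.full(n_fish, np.inf)
    counts = np.empty(len(times), dtype=int)
    for i, m in enumerate(running_max):
        alive = (thresholds > m) & (bg_death > times[i])
        counts[i] = int(np.count_nonzero(alive))
    return counts


def simulate_acute_test(design: AcuteTestDesign) -> SurvivalDataset:
    """Draw one acute-test dataset from the design's true parameters."""
    rng = np.random.default_rng(design.seed)
    times = np.asarray(design.observation_times, dtype=float)
    params = design.params

    treatments = []
    for conc in design.concentrations:
        if isinstance(params, SDParams):
            s = survival_at_constant(conc, params, times)
            counts = _sd_trajectory(rng, design.n_fish, s)
        else:
            ci = conc * (1.0 - np.exp(-params.ke * times))  # running max
            counts = _it_trajectory(rng, design.n_fish, times, ci, params)
        treatments.append(Treatment(conc, times.copy(), counts))

    controls = []
    s_bg = np.exp(-params.h_controls * times)
    for _ in range(design.n_control_groups):
        counts = _sd_trajectory(rng, design.n_fish, s_bg)
        controls.append(ControlGroup(times.copy(), counts))
    return SurvivalDataset(tuple(treatments), tuple(controls))


# ---------------------------------------------------------------------------
# pulse trains
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PulseMeta:
    """Ground truth for one generated pulse (rectangle part, before tail)."""

    start: float
    end: float
    height: float
    merged_with_previous: bool = False


@dataclass(frozen=True)
class PulseTrainDesign:
    """Design of a synthetic multi-pulse exposure profile.

    Heights, durations and inter-pulse gaps are log-normal (median and
    log-scale sigma); each pulse is a rectangle followed by an exponential
    decay tail toward the baseline at ``tail_rate`` (1/d).  ``min_gap``
    floors the end-to-start gap so generated pulses stay separable.
    Presets mimic the fate-scenario shapes: :meth:`many_pulse` (dense train
    of similar-magnitude events on a raised baseline), :meth:`sparse_pulse`
    (few well-separated pulses) and :meth:`single_event` (one concentrated
    exposure event).
    """

    horizon: float = 485.0
    n_pulses: int = 17
    height_median: float = 0.5      # µg/L
    height_sigma: float = 0.5
    duration_median: float = 2.0    # d
    duration_sigma: float = 0.2
    gap_median: float = 20.0        # d, end-to-start
    gap_sigma: float = 0.2
    min_gap: float = 2.5            # d
    baseline: float = 0.0           # µg/L
    tail_rate: float = 4.0          # 1/d
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.horizon <= 0 or self.n_pulses < 0:
            raise ValueError("horizon must be positive and n_pulses >= 0")
        for name in ("height_median", "duration_median", "gap_median",
                     "tail_rate"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.baseline < 0 or self.min_gap < 0:
            raise ValueError("baseline and min_gap must be >= 0")

    @classmethod
    def many_pulse(cls, seed: int | None = None, **kw) -> "PulseTrainDesign":
        """Dense train of recurring, similar-magnitude pulses spread over the
        whole horizon with a raised baseline — the drainage-ditch shape in
        which many episodes sit near a common concentration level."""
        kw.setdefault("n_pulses", 73)
        kw.setdefault("duration_median", 3.0)
        kw.setdefault("gap_median", 3.2)
        kw.setdefault("height_sigma", 0.15)
        kw.setdefault("baseline", 0.005)
        return cls(seed=seed, **kw)

    @classmethod
    def single_event(cls, seed: int | None = None, **kw) -> "PulseTrainDesign":
        """One concentrated exposure event — the opposite extreme shape."""
        kw.setdefault("n_pulses", 1)
        kw.setdefault("duration_median", 3.0)
        kw.setdefault("height_median", 5.0)
        return cls(seed=seed, **kw)

    @classmethod
    def sparse_pulse(cls, seed: int | None = None, **kw) -> "PulseTrainDesign":
        """Few, well-separated pulses — stream-scenario peak statistics."""
        kw.setdefault("n_pulses", 17)
        kw.setdefault("duration_median", 8.0)
        kw.setdefault("gap_median", 14.0)
        return cls(seed=seed, **kw)


def _lognormal(rng, median: float, sigma: float, size: int) -> np.ndarray:
    return np.exp(rng.normal(math.log(median), sigma, size=size))


def generate_pulse_train(design: PulseTrainDesign
                         ) -> tuple[ExposureProfile, tuple[PulseMeta, ...]]:
    """Generate a step-hold exposure profile with known pulse boundaries.

    Raises if the drawn pulses do not fit within the horizon.  If a decay
    tail is still substantial (above 5% of the next pulse height) when the
    next pulse starts, the two pulses are flagged as merged in the metadata
    and a warning is issued.
    """
    rng = np.random.default_rng(design.seed)
    b = design.baseline
    if design.n_pulses == 0:
        profile = ExposureProfile(np.array([0.0, design.horizon]),
                                  np.array([b, b]), interpolation="step")
        return profile, ()

    heights = _lognormal(rng, design.height_median, design.height_sigma,
                         design.n_pulses)
    durations = _lognormal(rng, design.duration_median, design.duration_sigma,
                           design.n_pulses)
    gaps = np.maximum(_lognormal(rng, design.gap_median, design.gap_sigma,
                                 design.n_pulses), design.min_gap)

    tail_span = 3.0 / design.tail_rate  # tail sampled down to ~5% of height
    n_tail = 6

    times = [0.0]
    concs = [b]
    meta: list[PulseMeta] = []
    cursor = gaps[0] * 0.5
    for k in range(design.n_pulses):
        start, dur, h = cursor, durations[k], heights[k]
        end = start + dur
        if end + tail_span >= design.horizon:
            raise ValueError("pulses do not fit within the horizon; reduce "
                             "n_pulses, durations or gaps")
        merged = False
        if k > 0:
            prev = meta[-1]
            residual = b + (prev.height - b) * math.exp(
                -design.tail_rate * (start - prev.end))
            if residual > 0.05 * h + b:
                merged = True
        if merged:
            warnings.warn(f"pulse {k} overlaps the tail of pulse {k - 1}; "
                          "flagged as merged in metadata")
        times.append(start)
        concs.append(h)
        tail_t = end + tail_span * (np.arange(n_tail) + 1) / n_tail
        tail_c = b + (h - b) * np.exp(-design.tail_rate * (tail_t - end))
        times.extend([end, *tail_t[:-1]])
        concs.extend([float(tail_c[0]), *map(float, tail_c[1:])])
        times.append(float(tail_t[-1]))
        concs.append(b)
        meta.append(PulseMeta(start, end, float(h), merged))
        cursor = end + gaps[k] if k + 1 < design.n_pulses else end

    times.append(design.horizon)
    concs.append(b)
    profile = ExposureProfile(np.asarray(times), np.asarray(concs),
                              interpolation="step")
    return profile, tuple(meta)
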