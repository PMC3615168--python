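"""Survival datasets and the multinomial likelihood for acute-test data.

An acute fish toxicity test (OECD 203 style) observes, for each treatment
concentration, the number of survivors at a handful of daily inspection
times.  Conditional on the model survival function S(t), the deaths in the
inspection intervals are multinomial, giving the log likelihood

    ln l = sum_i (y_{i-1} - y_i) * ln(S(t_{i-1}) - S(t_i)) + y_n * ln S(t_n)

per treatment (multinomial coefficient omitted — it is constant in the
parameters); treatments are independent, so their ln-likelihoods sum.
Per-interval death probabilities are floored at 1e-12 before the log so the
objective stays finite at degenerate parameter values.

The background hazard rate is estimated separately from the pooled control
and solvent-control groups under S(t) = exp(-h*t), and is held fixed when
the toxicity parameters are calibrated.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq, minimize_scalar
from scipy.special import expit
from scipy.stats import chi2

from .core import GUTSParams, ITParams, SDParams

__all__ = [
    "Treatment",
    "ControlGroup",
    "SurvivalDataset",
    "BackgroundHazardResult",
    "neg_log_likelihood",
    "log_likelihood",
    "fit_background_hazard",
    "hazard_from_survival_fraction",
    "survival_at_constant",
    "PROBABILITY_FLOOR",
]

PROBABILITY_FLOOR = 1e-12


def _check_counts(times, survivors, what: str):
    times = np.asarray(times, dtype=float)
    survivors = np.asarray(survivors, dtype=float)
    if times.ndim != 1 or survivors.ndim != 1 or times.size != survivors.size:
        raise ValueError(f"{what}: times and survivors must be 1-d, equal length")
    if times.size < 2:
        raise ValueError(f"{what}: need at least two observation times")
    if times[0] != 0.0:
        raise ValueError(f"{what}: observation times must start at t = 0")
    if not np.all(np.diff(times) > 0):
        raise ValueError(f"{what}: observation times must be strictly increasing")
    if np.any(survivors < 0) or np.any(np.diff(survivors) > 0):
        raise ValueError(f"{what}: survivor counts must be non-negative and non-increasing")
    return times, survivors


@dataclass(frozen=True)
class Treatment:
    """One treatment of an acute test: constant measured exposure plus the
    daily survivor record, starting at t = 0 with the initial stocking."""

    concentration: float
    times: np.ndarray
    survivors: np.ndarray

    def __post_init__(self) -> None:
        if not math.isfinite(self.concentration) or self.concentration < 0:
            raise ValueError("treatment concentration must be finite and >= 0")
        t, y = _check_counts(self.times, self.survivors, "treatment")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "survivors", y)

    @property
    def initial_count(self) -> int:
        return int(self.survivors[0])

    @property
    def mortality(self) -> float:
        """Observed mortality fraction at the last observation."""
        return 1.0 - float(self.survivors[-1]) / max(self.initial_count, 1)


@dataclass(frozen=True)
class ControlGroup:
    """Survivor record of an unexposed (control or solvent-control) group."""

    times: np.ndarray
    survivors: np.ndarray

    def __post_init__(self) -> None:
        t, y = _check_counts(self.times, self.survivors, "control group")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "survivors", y)

    @property
    def initial_count(self) -> int:
        return int(self.survivors[0])


@dataclass(frozen=True)
class SurvivalDataset:
    """Calibration data: treatments plus pooled control groups."""

    treatments: tuple[Treatment, ...]
    controls: tuple[ControlGroup, ...] = ()

    def __post_init__(self) -> None:
        object.__setattr__(self, "treatments", tuple(self.treatments))
        object.__setattr__(self, "controls", tuple(self.controls))

    @property
    def concentrations(self) -> np.ndarray:
        return np.array([tr.concentration for tr in self.treatments])

    def has_partial_mortality(self) -> bool:
        return any(0.0 < tr.mortality < 1.0 for tr in self.treatments)


# ---------------------------------------------------------------------------
# survival under maintained exposure (closed form)
# ---------------------------------------------------------------------------

def survival_at_constant(concentration: float, params: GUTSParams,
                         times) -> np.ndarray:
    """S(t) for exposure held constant at ``concentration`` from t = 0.

    Closed-form evaluation of the piecewise-analytic model for the special
    case of maintained exposure (Ci approaches the water concentration
    exponentially, so the threshold crossing and hazard integral are
    explicit).  Agrees with the general engine; used on the hot path of the
    likelihood.
    """
    t = np.asarray(times, dtype=float)
    c = float(concentration)
    ke = params.ke
    ci = c * (1.0 - np.exp(-ke * t))
    if isinstance(params, SDParams):
        hazard = params.h_controls * t
        if params.kk > 0.0 and c > params.z:
            t_star = -math.log(1.0 - params.z / c) / ke if params.z > 0 else 0.0
            above = t > t_star
            ta = t[above]
            integral = ((c - params.z) * (ta - t_star)
                        + (c / ke) * (np.exp(-ke * ta) - math.exp(-ke * t_star)))
            hazard = hazard.copy()
            hazard[above] += params.kk * integral
        return np.exp(-hazard)
    if isinstance(params, ITParams):
        cdf = np.zeros_like(t)
        pos = ci > 0.0
        cdf[pos] = expit(params.beta * (np.log(ci[pos]) - math.log(params.alpha)))
        return (1.0 - cdf) * np.exp(-params.h_controls * t)
    raise TypeError(f"unsupported parameter type {type(params).__name__}")


# ---------------------------------------------------------------------------
# likelihood
# ---------------------------------------------------------------------------

def _interval_nll(times: np.ndarray, survivors: np.ndarray,
                  model_survival: np.ndarray) -> float:
    """-ln multinomial likelihood of one survivor record given model S."""
    deaths = -np.diff(survivors)
    p_die = np.maximum(-np.diff(model_survival), PROBABILITY_FLOOR)
    p_live = max(float(model_survival[-1]), PROBABILITY_FLOOR)
    return -(float(deaths @ np.log(p_die)) + float(survivors[-1]) * math.log(p_live))


def neg_log_likelihood(data: SurvivalDataset, params: GUTSParams,
                       model: str | None = None) -> float:
    """-ln likelihood of the treatment survivor records under ``params``.

    ``model`` ("SD" or "IT") is optional and only validated against the
    parameter type.  Control groups are not included here; the background
    hazard they inform enters through ``params.h_controls`` (see
    :func:`fit_background_hazard`).
    """
    if model is not None:
        expected = SDParams if model.upper() == "SD" else ITParams
        if not isinstance(params, expected):
            raise TypeError(f"model {model!r} does not match {type(params).__name__}")
    total = 0.0
    for tr in data.treatments:
        if tr.initial_count == 0:
            continue
        s = survival_at_constant(tr.concentration, params, tr.times)
        total += _interval_nll(tr.times, tr.survivors, s)
    return total


def log_likelihood(data: SurvivalDataset, params: GUTSParams,
                   model: str | None = None) -> float:
    """ln likelihood (the negative of :func:`neg_log_likelihood`)."""
    return -neg_log_likelihood(data, params, model)


# ---------------------------------------------------------------------------
# background hazard
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BackgroundHazardResult:
    """Constant-hazard MLE from pooled controls, with profile CI."""

    h_controls: float
    ci: tuple[float, float]
    neg_log_likelihood: float
    messages: tuple[str, ...] = field(default=())


def _controls_nll(controls, h: float) -> float:
    total = 0.0
    for grp in controls:
        if grp.initial_count == 0:
            continue
        s = np.exp(-h * grp.times)
        total += _interval_nll(grp.times, grp.survivors, s)
    return total


def fit_background_hazard(controls, confidence: float = 0.95,
                          h_max: float = 10.0) -> BackgroundHazardResult:
    """Maximum-likelihood background hazard rate from pooled control groups.

    Assumes S(t) = exp(-h*t).  With no observed control deaths the MLE is
    h = 0, which is returned with a warning: a background mortality rate of
    zero is biologically implausible and the user should supply a floor
    (e.g. from a natural-lifespan argument, see
    :func:`hazard_from_survival_fraction`).
    """
    controls = tuple(controls)
    if not controls:
        raise ValueError("no control groups supplied")
    total_deaths = sum(g.initial_count - int(g.survivors[-1]) for g in controls)
    cutoff = chi2.ppf(confidence, df=1) / 2.0

    if total_deaths == 0:
        msg = ("no deaths observed in controls: background hazard MLE is 0, "
               "which is biologically implausible; supply a fixed floor "
               "(e.g. from a lifespan argument)")
        warnings.warn(msg)
        target = cutoff  # nll(0) = 0 for a death-free record
        upper = brentq(lambda h: _controls_nll(controls, h) - target,
                       0.0, h_max, xtol=1e-12)
        return BackgroundHazardResult(0.0, (0.0, upper), 0.0, (msg,))

    res = minimize_scalar(lambda u: _controls_nll(controls, math.exp(u)),
                          bounds=(math.log(1e-8), math.log(h_max)),
                          method="bounded",
                          options={"xatol": 1e-10})
    h_hat = math.exp(res.x)
    nll_min = float(res.fun)
    target = nll_min + cutoff

    def excess(h: float) -> float:
        return _controls_nll(controls, h) - target

    lo = brentq(excess, 0.0, h_hat, xtol=1e-12) if excess(0.0) > 0 else 0.0
    hi = brentq(excess, h_hat, h_max, xtol=1e-12) if excess(h_max) > 0 else h_max
    return BackgroundHazardResult(h_hat, (lo, hi), nll_min)


def hazard_from_survival_fraction(survival: float = 0.10,
                                  duration: float = 730.0) -> float:
    """Constant hazard rate (1/d) giving ``survival`` over ``duration`` days.

    The natural-lifespan argument used when controls show no deaths: e.g.
    10% survival over a two-year (730-d) lifespan gives about 0.00315 1/d.
    """
    if not 0.0 < survival < 1.0:
        raise ValueError("survival fraction must be in (0, 1)")
    if duration <= 0:
        raise ValueError("duration must be positive")
    return -math.log(survival) / duration
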