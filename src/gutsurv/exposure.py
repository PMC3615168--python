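"""Time-variable exposure profiles.

An :class:`ExposureProfile` is an ordered water-concentration record
``(t_i, Cw_i)`` in days and µg/L — the in-memory stand-in for an hourly
surface-water fate-model output (e.g. a FOCUS-SW/TOXSWA series) or for a
laboratory exposure regime.  Two interpolation rules are supported:

``"step"``
    step-hold-left: the concentration recorded at ``t_i`` holds on
    ``[t_i, t_{i+1})``.  This matches hourly fate-model output, where each
    row reports the concentration for the hour that starts at its stamp.
``"linear"``
    straight-line interpolation between records.

Outside ``[t_first, t_last]`` the concentration is zero: the record is the
whole exposure history.  A dimensionless ``factor`` scales every evaluated
concentration; it carries the exposure multiplication factor used for
margin-of-safety analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterator

import numpy as np

__all__ = ["ExposureProfile", "Segment", "constant_profile", "rectangular_pulse"]


@dataclass(frozen=True)
class Segment:
    """One interval on which the water concentration has a single closed form.

    ``c0`` applies at ``t0`` and ``c1`` at ``t1``; under the step rule
    ``c1 == c0``.  Concentrations already include the profile factor.
    """

    t0: float
    t1: float
    c0: float
    c1: float

    @property
    def slope(self) -> float:
        return (self.c1 - self.c0) / (self.t1 - self.t0)

    @property
    def constant(self) -> bool:
        return self.c0 == self.c1


@dataclass(frozen=True)
class ExposureProfile:
    """Time-ordered water-concentration series.

    Parameters
    ----------
    times :
        Strictly increasing time stamps in days, at least two.
    concentrations :
        Water concentrations in µg/L, finite and non-negative, one per stamp.
    interpolation :
        ``"step"`` (hold-left, default) or ``"linear"``.
    factor :
        Dimensionless multiplier applied to every evaluated concentration.
    """

    times: np.ndarray
    concentrations: np.ndarray
    interpolation: str = "step"
    factor: float = 1.0

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        c = np.asarray(self.concentrations, dtype=float)
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "concentrations", c)
        if t.ndim != 1 or c.ndim != 1 or t.size != c.size:
            raise ValueError("times and concentrations must be 1-d and equal length")
        if t.size < 2:
            raise ValueError("an exposure profile needs at least two time points")
        if not np.all(np.isfinite(t)) or not np.all(np.diff(t) > 0):
            raise ValueError("times must be finite and strictly increasing")
        if not np.all(np.isfinite(c)) or np.any(c < 0):
            raise ValueError("concentrations must be finite and >= 0")
        if self.interpolation not in ("step", "linear"):
            raise ValueError(f"unknown interpolation rule {self.interpolation!r}")
        if not np.isfinite(self.factor) or self.factor < 0:
            raise ValueError("factor must be finite and >= 0")

    # -- basic geometry ---------------------------------------------------

    @property
    def start(self) -> float:
        return float(self.times[0])

    @property
    def end(self) -> float:
        return float(self.times[-1])

    def scaled(self, factor: float) -> "ExposureProfile":
        """Return a copy whose effective factor is ``self.factor * factor``."""
        return replace(self, factor=self.factor * factor)

    # -- evaluation --------------------------------------------------------

    def concentration(self, t) -> np.ndarray:
        """Water concentration at time(s) ``t`` (µg/L), zero outside the record."""
        t = np.asarray(t, dtype=float)
        scalar = t.ndim == 0
        t = np.atleast_1d(t)
        out = np.zeros_like(t)
        inside = (t >= self.times[0]) & (t <= self.times[-1])
        if self.interpolation == "linear":
            out[inside] = np.interp(t[inside], self.times, self.concentrations)
        else:
            idx = np.searchsorted(self.times, t[inside], side="right") - 1
            idx = np.clip(idx, 0, self.times.size - 1)
            out[inside] = self.concentrations[idx]
        out *= self.factor
        return float(out[0]) if scalar else out

    def segments(self, t_start: float, t_end: float,
                 extra: np.ndarray | None = None) -> Iterator[Segment]:
        """Closed-form pieces of Cw(t) covering ``[t_start, t_end]``.

        Pieces outside the record carry concentration zero.  Factor applied.
        ``extra`` times (e.g. an output grid) are inserted as piece edges.
        """
        if t_end <= t_start:
            return
        knots = self.times[(self.times > t_start) & (self.times < t_end)]
        if extra is not None:
            extra = np.asarray(extra, dtype=float)
            extra = extra[(extra > t_start) & (extra < t_end)]
            knots = np.unique(np.concatenate([knots, extra]))
        edges = np.concatenate([[t_start], knots, [t_end]])
        f = self.factor
        for a, b in zip(edges[:-1], edges[1:]):
            if b <= self.times[0] or a >= self.times[-1]:
                yield Segment(float(a), float(b), 0.0, 0.0)
            elif self.interpolation == "step":
                j = int(np.searchsorted(self.times, 0.5 * (a + b), side="right") - 1)
                c = float(self.concentrations[j]) * f
                yield Segment(float(a), float(b), c, c)
            else:
                ca = float(np.interp(a, self.times, self.concentrations)) * f
                cb = float(np.interp(b, self.times, self.concentrations)) * f
                yield Segment(float(a), float(b), ca, cb)

    def auc(self) -> float:
        """Area under the exposure curve (µg·d/L), consistent with the
        interpolation rule: rectangle sum for step-hold, trapezoid for linear."""
        dt = np.diff(self.times)
        if self.interpolation == "step":
            area = float(np.sum(self.concentrations[:-1] * dt))
        else:
            c = self.concentrations
            area = float(np.sum(0.5 * (c[:-1] + c[1:]) * dt))
        return area * self.factor


def constant_profile(concentration: float, duration: float,
                     interpolation: str = "step") -> ExposureProfile:
    """Maintained exposure at one concentration for ``duration`` days."""
    return ExposureProfile(np.array([0.0, float(duration)]),
                           np.array([concentration, concentration]),
                           interpolation=interpolation)


def rectangular_pulse(height: float, start: float = 0.0, duration: float = 1.0,
                      tail: float = 0.0) -> ExposureProfile:
    """Single rectangular pulse of ``height`` µg/L.

    ``tail`` days of explicit zero record are appended after the pulse; the
    concentration is zero beyond the record either way, so the tail only
    extends ``end``.
    """
    times = [start, start + duration]
    conc = [height, 0.0]
    if tail > 0:
        times.append(start + duration + tail)
        conc.append(0.0)
    return ExposureProfile(np.array(times), np.array(conc), interpolation="step")
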