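"""Independent brute-force oracles used to check the analytic engine.

Everything here integrates the model equations directly on a dense fixed
step with an explicit scheme (Heun/RK2 for the uptake ODE, trapezoid for
the hazard integral, grid running-maximum for the threshold CDF), sharing
no code with the piecewise-analytic implementation under test.
"""

from __future__ import annotations

import numpy as np
from scipy.signal import lfilter

from gutsurv import ExposureProfile, ITParams, SDParams


def dense_concentration(profile: ExposureProfile, grid: np.ndarray) -> np.ndarray:
    """Sample Cw on a dense grid (duplicate of the interpolation rules)."""
    out = np.zeros_like(grid)
    inside = (grid >= profile.times[0]) & (grid <= profile.times[-1])
    if profile.interpolation == "linear":
        out[inside] = np.interp(grid[inside], profile.times,
                                profile.concentrations)
    else:
        idx = np.searchsorted(profile.times, grid[inside], side="right") - 1
        out[inside] = profile.concentrations[np.clip(idx, 0,
                                                     profile.times.size - 1)]
    return out * profile.factor


def brute_force_internal(profile: ExposureProfile, ke: float, t_end: float,
                         dt: float = 1e-4):
    """Fixed-step explicit (Heun) integration of dCi/dt = ke (Cw - Ci)."""
    n = int(round(t_end / dt))
    grid = np.arange(n + 1) * dt
    cw = dense_concentration(profile, grid)
    kedt = ke * dt
    alpha = 1.0 - kedt + 0.5 * kedt * kedt
    if profile.interpolation == "step":
        # forcing is constant within each step (breakpoints grid-aligned),
        # so both RK2 stages see the left sample
        b0, b1 = 0.0, kedt - 0.5 * kedt * kedt
    else:
        # linear forcing: trapezoidal (Heun) stages
        b0, b1 = 0.5 * kedt, 0.5 * kedt - 0.5 * kedt * kedt
    # y[i] = alpha*y[i-1] + b0*x[i] + b1*x[i-1], y[0] = 0
    ci, _ = lfilter([b0, b1], [1.0, -alpha], cw, zi=np.array([-b0 * cw[0]]))
    return grid, np.maximum(ci, 0.0)


def brute_force_survival(profile: ExposureProfile, params, t_end: float,
                         dt: float = 1e-4):
    """Survival on a dense grid by direct integration of the model equations."""
    grid, ci = brute_force_internal(profile, params.ke, t_end, dt)
    if isinstance(params, SDParams):
        r = np.maximum(ci - params.z, 0.0)
        trapz = np.concatenate([[0.0], np.cumsum(0.5 * (r[1:] + r[:-1]))]) * dt
        hazard = params.kk * trapz + params.h_controls * grid
        return grid, np.exp(-hazard)
    if isinstance(params, ITParams):
        run_max = np.maximum.accumulate(ci)
        cdf = np.zeros_like(run_max)
        pos = run_max > 0
        cdf[pos] = 1.0 / (1.0 + (run_max[pos] / params.alpha) ** (-params.beta))
        return grid, (1.0 - cdf) * np.exp(-params.h_controls * grid)
    raise TypeError(type(params).__name__)


def random_step_profile(rng: np.random.Generator, t_end: float = 12.0,
                        cmax: float = 3.0, align: float = 0.01) -> ExposureProfile:
    """Random multi-pulse step profile with breakpoints on an `align` grid
    (so the dense-grid oracle samples it without misalignment error)."""
    n_break = int(rng.integers(3, 9))
    times = np.sort(rng.choice(np.arange(1, int(t_end / align)), size=n_break,
                               replace=False)) * align
    times = np.concatenate([[0.0], times])
    conc = rng.uniform(0.0, cmax, size=times.size)
    conc[rng.uniform(size=times.size) < 0.4] = 0.0  # quiet stretches
    return ExposureProfile(times, conc, interpolation="step")


def random_sd_params(rng: np.random.Generator) -> SDParams:
    return SDParams(ke=float(rng.uniform(0.3, 1.5)),
                    kk=float(rng.uniform(0.1, 1.0)),
                    z=float(rng.uniform(0.3, 1.5)),
                    h_controls=float(rng.choice([0.0, 0.01])))


def random_it_params(rng: np.random.Generator) -> ITParams:
    return ITParams(ke=float(rng.uniform(0.3, 1.5)),
                    alpha=float(rng.uniform(0.5, 2.0)),
                    beta=float(rng.uniform(1.0, 12.0)),
                    h_controls=float(rng.choice([0.0, 0.01])))
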