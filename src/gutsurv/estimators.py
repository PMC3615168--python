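"""Calibration of the reduced GUTS models: simplex fit and profile CIs.

Free parameters (ke, kk, z for stochastic death; ke, alpha, beta for
individual tolerance) are searched on the log scale — all are positive, so
the Nelder-Mead simplex needs no explicit constraints — from several
restarts with jittered initial values, keeping the best optimum.  The
background hazard is held fixed throughout, as it is calibrated separately
from the control groups.

Confidence limits come from the profile likelihood: a parameter is stepped
away from its optimum, all other free parameters are re-optimized, and the
bound is where the profiled -ln likelihood exceeds the minimum by
chi-square(1 df)/2 of the requested confidence (1.9207 at 95%).  Profiles
that never cross the cutoff inside the search range are reported censored
at the range limit.

:class:`GUTSSD` and :class:`GUTSIT` wrap this machinery as scikit-learn
style estimators (``fit`` / ``predict`` / ``get_params``); the module-level
:func:`fit` and :func:`profile_ci` are the functional surface.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.optimize import brentq, minimize
from scipy.stats import chi2
from sklearn.base import BaseEstimator

from .core import GUTSParams, ITParams, PredictionResult, SDParams, predict
from .exposure import ExposureProfile
from .likelihood import (SurvivalDataset, fit_background_hazard,
                         neg_log_likelihood)

__all__ = ["FitResult", "fit", "profile_ci", "GUTSSD", "GUTSIT"]

_FREE_NAMES = {"SD": ("ke", "kk", "z"), "IT": ("ke", "alpha", "beta")}
_BETA_CAP = 1e3
_LOG_RANGE = 8.0  # profile search range, log units around the optimum
_NM_OPTIONS = {"xatol": 1e-6, "fatol": 1e-6, "maxiter": 2000, "maxfev": 4000}


@dataclass
class FitResult:
    """Best-fit parameters with likelihood value and profile confidence limits.

    ``ci95`` maps each free parameter name to its (lower, upper) limits;
    ``ci_censored`` flags limits that hit the search range instead of the
    likelihood cutoff.
    """

    params: GUTSParams
    neg_log_likelihood: float
    ci95: dict[str, tuple[float, float]]
    converged: bool
    n_restarts: int
    fixed_params: dict[str, float]
    model: str
    ci_censored: dict[str, tuple[bool, bool]]
    messages: tuple[str, ...] = ()

    def value(self, name: str) -> float:
        return getattr(self.params, name)


def _make_params(model: str, free: np.ndarray, h_controls: float) -> GUTSParams:
    if model == "SD":
        return SDParams(ke=free[0], kk=free[1], z=free[2], h_controls=h_controls)
    return ITParams(ke=free[0], alpha=free[1], beta=min(free[2], _BETA_CAP),
                    h_controls=h_controls)


def _objective(model: str, data: SurvivalDataset, h_controls: float):
    def nll_of_log(u: np.ndarray) -> float:
        theta = np.exp(np.clip(u, -30.0, 30.0))
        try:
            return neg_log_likelihood(data, _make_params(model, theta, h_controls))
        except (ValueError, OverflowError):
            return 1e12
    return nll_of_log


def _default_init(model: str, data: SurvivalDataset) -> np.ndarray:
    """Heuristic starting values from the dose-mortality pattern."""
    concs = data.concentrations
    mort = np.array([tr.mortality for tr in data.treatments])
    t_end = max(float(tr.times[-1]) for tr in data.treatments)
    lethal = concs[mort > 0.1]
    ke0 = 1.0
    if model == "SD":
        z0 = 0.7 * float(lethal.min()) if lethal.size else float(concs.max())
        z0 = max(z0, 1e-3)
        kk0 = 1.0 / max((concs.max() - z0) * t_end, 1e-3)
        return np.array([ke0, kk0, z0])
    if lethal.size:
        alpha0 = float(np.exp(np.interp(0.5, mort[np.argsort(mort)],
                                        np.log(np.maximum(concs[np.argsort(mort)], 1e-6)))))
    else:
        alpha0 = float(max(concs.max(), 1e-3))
    return np.array([ke0, max(alpha0, 1e-3), 2.0])


def _run_simplex(objective, u0: np.ndarray):
    res = minimize(objective, u0, method="Nelder-Mead", options=_NM_OPTIONS)
    return res


def fit(data: SurvivalDataset, model: str = "SD",
        init: Sequence[float] | dict[str, float] | None = None,
        fixed: dict[str, float] | None = None,
        n_restarts: int = 10, seed: int | None = None,
        compute_ci: bool = True, confidence: float = 0.95) -> FitResult:
    """Maximum-likelihood calibration of one reduced GUTS model.

    Parameters
    ----------
    data :
        Acute-test survivor records.  At least one treatment with partial
        mortality is needed for the toxicity parameters to be identifiable;
        otherwise the fit proceeds with a warning and the result is flagged.
    model :
        ``"SD"`` or ``"IT"``.
    init :
        Starting values for the free parameters, either in model order or
        as a name->value mapping; missing entries fall back to heuristics.
    fixed :
        Values held constant; only ``h_controls`` is supported.  If absent
        it is estimated from ``data.controls`` (zero, with a warning, when
        there are none).
    n_restarts :
        Number of simplex starts; the first uses ``init``, the rest jitter
        it by +/-50% log-uniformly.
    """
    model = model.upper()
    if model not in _FREE_NAMES:
        raise ValueError(f"model must be 'SD' or 'IT', got {model!r}")
    names = _FREE_NAMES[model]
    messages: list[str] = []

    fixed = dict(fixed or {})
    unknown = set(fixed) - {"h_controls"}
    if unknown:
        raise ValueError(f"only h_controls can be fixed, got {sorted(unknown)}")
    if "h_controls" in fixed:
        h_controls = float(fixed["h_controls"])
    elif data.controls:
        h_controls = fit_background_hazard(data.controls).h_controls
        messages.append(f"h_controls = {h_controls:.6g} estimated from controls "
                        "and held fixed")
    else:
        h_controls = 0.0
        messages.append("no controls and no fixed h_controls supplied; "
                        "background hazard held at 0")
    fixed = {"h_controls": h_controls}

    if not data.has_partial_mortality():
        msg = ("no treatment shows partial mortality; toxicity parameters are "
               "poorly identifiable (threshold only bounded by the tested "
               "concentrations)")
        warnings.warn(msg)
        messages.append(msg)

    theta0 = _default_init(model, data)
    if init is not None:
        if isinstance(init, dict):
            for i, name in enumerate(names):
                if name in init:
                    theta0[i] = float(init[name])
        else:
            theta0 = np.asarray(list(init), dtype=float)
    if np.any(theta0 <= 0):
        raise ValueError("initial values must be positive")

    objective = _objective(model, data, h_controls)
    rng = np.random.default_rng(seed)
    u0 = np.log(theta0)
    best = None
    any_success = False
    for k in range(max(n_restarts, 1)):
        start = u0 if k == 0 else u0 + rng.uniform(math.log(0.5), math.log(1.5),
                                                   size=u0.size)
        res = _run_simplex(objective, start)
        any_success = any_success or bool(res.success)
        if best is None or res.fun < best.fun:
            best = res
    if not any_success:
        messages.append("simplex did not report convergence in any restart")

    theta_hat = np.exp(best.x)
    params = _make_params(model, theta_hat, h_controls)
    result = FitResult(params=params,
                       neg_log_likelihood=float(best.fun),
                       ci95={}, converged=bool(any_success),
                       n_restarts=max(n_restarts, 1),
                       fixed_params=fixed, model=model,
                       ci_censored={}, messages=tuple(messages))
    if compute_ci:
        for name in names:
            (lo, hi), cens = profile_ci(data, result, name, confidence=confidence)
            result.ci95[name] = (lo, hi)
            result.ci_censored[name] = cens
    return result


def _profiled_nll(model: str, data: SurvivalDataset, h_controls: float,
                  names: tuple[str, ...], index: int, value: float,
                  warm: np.ndarray) -> tuple[float, np.ndarray]:
    """Minimum -ln likelihood with parameter ``index`` pinned at ``value``."""
    others = [i for i in range(len(names)) if i != index]
    base = _objective(model, data, h_controls)

    def reduced(u_others: np.ndarray) -> float:
        u = np.empty(len(names))
        u[index] = math.log(value)
        u[others] = u_others
        return base(u)

    res = minimize(reduced, warm[others], method="Nelder-Mead",
                   options=_NM_OPTIONS)
    # a second start from the unconstrained optimum guards against the
    # warm-started simplex stalling in a side valley
    res2 = minimize(reduced, warm[others] * 0.97 + 0.03, method="Nelder-Mead",
                    options=_NM_OPTIONS)
    if res2.fun < res.fun:
        res = res2
    full = np.empty(len(names))
    full[index] = math.log(value)
    full[others] = res.x
    return float(res.fun), full


def profile_ci(data: SurvivalDataset, fit_result: FitResult, parameter: str,
               confidence: float = 0.95,
               log_range: float = _LOG_RANGE) -> tuple[tuple[float, float],
                                                       tuple[bool, bool]]:
    """Profile-likelihood confidence limits for one free parameter.

    Returns ``((lower, upper), (lower_censored, upper_censored))``.  A
    censored flag means the profiled -ln likelihood never exceeded the
    cutoff within ``log_range`` log units of the optimum (an open-ended
    profile) and the search bound itself is reported.
    """
    model = fit_result.model
    names = _FREE_NAMES[model]
    if parameter not in names:
        raise ValueError(f"{parameter!r} is not a free parameter of GUTS-{model}")
    index = names.index(parameter)
    h_controls = fit_result.fixed_params["h_controls"]
    cutoff = chi2.ppf(confidence, df=1) / 2.0
    nll_min = fit_result.neg_log_likelihood
    target = nll_min + cutoff
    theta_hat = np.array([fit_result.value(n) for n in names])
    u_hat = np.log(theta_hat)
    cap = math.log(_BETA_CAP) if (model == "IT" and parameter == "beta") else None

    bounds = []
    censored = []
    for direction in (-1.0, +1.0):
        limit = u_hat[index] + direction * log_range
        if cap is not None and direction > 0:
            limit = min(limit, cap)
        warm = u_hat.copy()
        step = 0.125
        u_prev = u_hat[index]
        nll_prev = nll_min
        crossed = False
        while True:
            u_try = u_hat[index] + direction * step
            past_limit = (u_try - limit) * direction >= 0
            if past_limit:
                u_try = limit
            nll_try, warm = _profiled_nll(model, data, h_controls, names, index,
                                          math.exp(u_try), warm)
            if nll_try >= target:
                crossed = True
                break
            u_prev, nll_prev = u_try, nll_try
            if past_limit:
                break
            step *= 2.0
        if not crossed:
            bounds.append(math.exp(limit))
            censored.append(True)
            continue

        # bisect between the last sub-cutoff point and the crossing point;
        # plain bisection (not brentq) because re-optimization makes the
        # profiled value very slightly evaluation-dependent
        warm_root = warm.copy()
        u_in, u_out = u_prev, u_try
        while abs(u_out - u_in) > 2e-3:
            u_mid = 0.5 * (u_in + u_out)
            nll_mid, warm_root = _profiled_nll(model, data, h_controls, names,
                                               index, math.exp(u_mid), warm_root)
            if nll_mid >= target:
                u_out = u_mid
            else:
                u_in = u_mid
        bounds.append(math.exp(0.5 * (u_in + u_out)))
        censored.append(False)

    lower, upper = sorted(bounds)
    return (lower, upper), (censored[bounds.index(lower)],
                            censored[bounds.index(upper)])


# ---------------------------------------------------------------------------
# estimator classes
# ---------------------------------------------------------------------------

class _GUTSEstimator(BaseEstimator):
    """Shared fit/predict plumbing for the two limit cases."""

    _model: str = ""
    _free: tuple[str, ...] = ()

    def _init_values(self) -> dict[str, float]:
        return {n: getattr(self, n) for n in self._free
                if getattr(self, n) is not None}

    def fit(self, data: SurvivalDataset, h_controls: float | None = None):
        """Calibrate the free parameters to an acute-test dataset.

        ``h_controls`` (or, if None, the estimator's ``h_controls`` setting
        when data has no controls) is held fixed during the fit.
        """
        fixed = None
        if h_controls is not None:
            fixed = {"h_controls": float(h_controls)}
        elif not data.controls:
            fixed = {"h_controls": float(self.h_controls)}
        init = self._init_values() or None
        result = fit(data, model=self._model, init=init, fixed=fixed,
                     n_restarts=self.n_restarts, seed=self.seed,
                     compute_ci=self.compute_ci, confidence=self.confidence)
        for name in self._free:
            setattr(self, name + "_", result.value(name))
        self.h_controls_ = result.params.h_controls
        self.neg_log_likelihood_ = result.neg_log_likelihood
        self.ci95_ = dict(result.ci95)
        self.converged_ = result.converged
        self.result_ = result
        return self

    @property
    def params_(self) -> GUTSParams:
        """Current parameter set: fitted if available, else constructor values."""
        if hasattr(self, "result_"):
            return self.result_.params
        values = self._init_values()
        missing = [n for n in self._free if n not in values]
        if missing:
            raise ValueError(f"parameters {missing} are unset; call fit() or "
                             "construct with explicit values")
        return _make_params(self._model,
                            np.array([values[n] for n in self._free]),
                            float(self.h_controls))

    def predict(self, profile: ExposureProfile, horizon: float | None = None,
                step: float = 1.0, grid=None) -> PredictionResult:
        """Survival prediction for an exposure profile (see :func:`gutsurv.predict`)."""
        return predict(profile, self.params_, horizon=horizon, step=step,
                       grid=grid)

    def predict_survival(self, profile: ExposureProfile, t: float,
                         factor: float = 1.0) -> float:
        """Survival probability at time ``t`` under ``profile`` scaled by ``factor``."""
        result = predict(profile.scaled(factor), self.params_,
                         grid=np.array([0.0, float(t)]))
        return float(result.survival[-1])

    def score(self, data: SurvivalDataset) -> float:
        """ln likelihood of ``data`` under the current parameters (higher is better)."""
        return -neg_log_likelihood(data, self.params_)


class GUTSSD(_GUTSEstimator):
    """Stochastic-death GUTS estimator.

    Constructor arguments double as fixed values for prediction-only use
    and as initial guesses for :meth:`fit`; fitted values land in ``ke_``,
    ``kk_``, ``z_`` with profile confidence limits in ``ci95_``.
    """

    _model = "SD"
    _free = ("ke", "kk", "z")

    def __init__(self, ke: float | None = None, kk: float | None = None,
                 z: float | None = None, h_controls: float = 0.0,
                 n_restarts: int = 10, seed: int | None = None,
                 compute_ci: bool = True, confidence: float = 0.95):
        self.ke = ke
        self.kk = kk
        self.z = z
        self.h_controls = h_controls
        self.n_restarts = n_restarts
        self.seed = seed
        self.compute_ci = compute_ci
        self.confidence = confidence


class GUTSIT(_GUTSEstimator):
    """Individual-tolerance GUTS estimator (log-logistic threshold spread).

    Same contract as :class:`GUTSSD` with free parameters ``ke``,
    ``alpha``, ``beta``.
    """

    _model = "IT"
    _free = ("ke", "alpha", "beta")

    def __init__(self, ke: float | None = None, alpha: float | None = None,
                 beta: float | None = None, h_controls: float = 0.0,
                 n_restarts: int = 10, seed: int | None = None,
                 compute_ci: bool = True, confidence: float = 0.95):
        self.ke = ke
        self.alpha = alpha
        self.beta = beta
        self.h_controls = h_controls
        self.n_restarts = n_restarts
        self.seed = seed
        self.compute_ci = compute_ci
        self.confidence = confidence
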