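# Methods

## Model

`gutsurv` implements the two reduced limit cases of the General Unified
Threshold model of Survival (GUTS), the standard toxicokinetic-
toxicodynamic (TKTD) framework for predicting survival of aquatic
organisms under time-variable chemical exposure.

**Dose metric.** Without measured internal concentrations, both limit
cases use the *scaled internal concentration* `Ci(t)` (internal
concentration divided by the bioconcentration factor, units µg/L):

    dCi/dt = ke (Cw(t) − Ci(t)),    Ci(0) = 0,

where `Cw(t)` is the water concentration and `ke` (1/d) the *dominant
rate constant* — the slower of chemical elimination and organism (damage)
recovery, which the one-compartment reduction cannot distinguish.
Organisms are assumed unexposed at the start of a simulation; pre-exposure
(e.g. of embryos before hatch) is out of scope.

**Stochastic death (SD).** All individuals share one threshold `z`
(µg/L); above it, death is a chance process with hazard proportional to
the exceedance:

    dH/dt = kk max(0, Ci − z) + h_controls,    S(t) = exp(−H(t)),

with killing rate constant `kk` (L µg⁻¹ d⁻¹) and background hazard
`h_controls` (1/d).

**Individual tolerance (IT).** Thresholds vary across the population with
a log-logistic distribution (median `alpha`, shape `beta`); an individual
dies the instant its threshold is first exceeded, so toxicant mortality
tracks the running maximum of the dose metric:

    F(t) = 1 / (1 + (max_{s≤t} Ci(s) / alpha)^−beta),
    S(t) = (1 − F(t)) · exp(−h_controls · t).

The two cases bracket the behaviour of real populations; predictions
should always be made with both.  Their signature difference appears
under repeated pulses: if a first pulse kills half the population, an
identical, toxicologically independent second pulse kills a quarter of
the survivors under SD (death is a chance process, same fraction every
time) and nobody under IT (the survivors are the tolerant individuals).

## Numerics

Exposure profiles are piecewise-constant (step-hold-left, the default —
matching hourly fate-model output where each record holds until the next
stamp) or piecewise-linear; evaluation outside the record is zero, and a
dimensionless `factor` rescales the whole series.  Within each segment
the uptake ODE has a closed-form solution, so the engine marches exactly
from breakpoint to breakpoint:

* SD hazard: the `Ci = z` crossing inside a segment is located exactly —
  analytically for constant segments, by bracketed root refinement
  (`brentq`, xtol 1e-13) on the single monotone spans of the
  linear-segment expression — and `kk (Ci − z)` is integrated from its
  antiderivative on the super-threshold spans.  No global step size
  exists, so survival carries no step-size error and threshold crossings
  cannot be skipped.
* IT running maximum: computed per segment from the endpoint values and
  the single possible interior stationary point, never by grid sampling,
  so pulse peaks between output points cannot be missed.  `F` is
  evaluated as `expit(beta·(ln M − ln alpha))` for numerical stability at
  large `beta`.
* Output grids are the union of the user grid, every profile breakpoint
  and (for SD) every threshold crossing; refining the grid changes
  nothing but the reporting resolution.

The test suite checks this engine against an independent dense fixed-step
explicit (RK2) integrator at 1e-4 d on random multi-pulse profiles and
parameter draws (agreement to 1e-4 absolute survival probability).

## Calibration

The likelihood of an acute-test survivor record is the multinomial
deaths-per-interval form: with survivors `y_i` at inspection times `t_i`,

    ln l = Σ_i (y_{i−1} − y_i) ln(S(t_{i−1}) − S(t_i)) + y_n ln S(t_n),

summed over treatments.  Interval death probabilities are floored at
1e-12 before the log so the objective stays finite at degenerate
parameter values.  Free parameters (`ke, kk, z` or `ke, alpha, beta`) are
searched on the log scale — all are positive, so the Nelder-Mead simplex
needs no constraints — with `beta` capped at 1e3 (beyond which the
tolerance distribution is numerically a step).  Ten restarts with ±50%
log-uniform jitter guard against local optima (the simplex is local);
convergence tolerances are 1e-6 on objective and parameters, below the
precision at which such fits are reported.

The background hazard is calibrated separately from the pooled control
and solvent-control groups under `S = exp(−h t)` and held fixed while the
toxicity parameters are fitted.  Death-free controls give an MLE of zero,
which is biologically implausible; the package returns it with a warning
and provides `hazard_from_survival_fraction` for the standard
lifespan-based floor (10% survival over a 730-d natural lifespan gives
0.00315 1/d).

**Confidence limits** come from the profile likelihood: each parameter is
stepped away from its optimum (geometric walk on the log scale), the
other free parameters are re-optimized at every step (two warm-started
simplex runs per evaluation), and the 95% bound is bisected to where the
profiled −ln likelihood exceeds the minimum by χ²₀.₉₅(1)/2 = 1.9207.
Profiles that never cross the cutoff within 8 log units (or the `beta`
cap) are reported censored at the search bound.  Plain bisection is used
rather than a derivative-based root finder because re-optimization makes
the profiled value very slightly evaluation-dependent.

On synthetic acute tests (six geometric concentrations of which only the
two highest are lethal, 60 fish per treatment, daily counts over four
days — the standard test pattern) the profile CIs cover the generating
parameters at close to the nominal 95% rate; the shipped recovery test
measures this over 100 seeded replicates.  `kk` is the most weakly
identified of the three free parameters under this design (only two
informative treatments, strong correlation with `ke`), so its intervals
are the widest and its replicate-to-replicate coverage the most variable;
the profiled bounds themselves sit exactly at the χ²/2 cutoff when
re-optimized to convergence with heavy multistarts.

## Risk metrics

* **Margin of safety**: the exposure multiplication factor at which a
  profile first reaches a defined onset-of-mortality proxy — by default
  10% mortality at a 485-d horizon, the convention for year-plus
  fate-model series; both numbers are configurable.  Mortality at the
  horizon is monotone in the factor, so the solver brackets geometrically
  from 1 and root-solves to a survival residual below 1e-4.  Background
  hazard is zeroed for these predictions (the question is the toxicant's
  contribution).
* **Organism recovery time**: after a 1-d pulse whose height is solved so
  the pulse eventually kills 50% (SD: episode hazard = ln 2; IT: peak
  dose metric = `alpha`), the time from the dose-metric maximum until it
  falls below 5% of that maximum.  The result depends only on `ke`
  (continuous limit ln(20)/ke).  By default the simulation is monitored
  on a 0.1-d output grid and the first monitored time below the mark is
  reported — the convention under which such simulations are read out to
  one decimal; `resolution=0` gives the exact crossing.  Pulses separated
  by more than this time are toxicologically independent.
* **Inherent toxicity potential**: each profile is scaled by its own
  margin of safety so all produce the same effect; the area under the
  scaled exposure curve (rectangle sum for step profiles, trapezoid for
  linear — always consistent with the interpolation rule) then ranks the
  pattern shapes, smaller equal-effect area meaning inherently more
  toxic.

* **Peak statistics**: exposure series are segmented into episodes above
  a threshold `max(r · profile maximum, absolute floor)` with defaults
  r = 0.01 and floor 0; sub-threshold gaps shorter than 1 d are merged.
  Intervals between peaks are measured start-to-start (stable under
  duration changes).  All three knobs are explicit arguments; published
  peak counts for fate scenarios rest on a differently-parameterized
  classification algorithm, so comparisons of absolute counts are
  qualitative.

* **Sensitivity**: one-at-a-time Monte Carlo — each parameter in turn is
  sampled uniformly between its profile confidence limits (1000 draws by
  default) while the others stay at their best fit, with exposure scaled
  by the margin of safety so the best-fit run sits at 90% survival.
  Ignoring parameter covariance overestimates the uncertainty; the spread
  is an outer bound.  The percent-variation axis is defined as
  100·(sample − best)/best.

## Synthetic data

The generators exist so every claim above is testable without external
fate-model output or raw test reports.

* `simulate_acute_test` reproduces each limit case's probabilistic
  assumptions exactly: conditional-binomial interval deaths given the
  model survival curve for SD; one log-logistic threshold per fish
  compared against the running dose-metric maximum, plus exponential
  background death times, for IT.  The default design mirrors the
  standard acute test: six geometric concentrations (0.56–10 µg/L) of
  which only the two highest exceed the default carp-like SD truth
  (ke = 1.0, kk = 1.42, z = 4.06, h = 0.018), 10 fish per treatment,
  daily counts over four days, two control groups.
* `generate_pulse_train` emits step profiles with log-normal pulse
  heights, durations and gaps, an exponential decay tail (rate 4/d)
  after each rectangle, and an optional raised baseline, plus the true
  pulse boundaries as metadata.  A gap floor (2.5 d) keeps pulses
  separable by the peak detector.  Presets give the two extreme
  fate-scenario shapes: `many_pulse` (73 similar-magnitude pulses,
  ~6-d start-to-start spacing, raised baseline — dense-drainage shape;
  the small height spread, log-sigma 0.15, is what makes many episodes
  sit near a common level so that threshold variation can recruit or
  release many of them at once) and `single_event` (one concentrated
  3-d event).  `sparse_pulse` (17 pulses, ~22-d spacing) mirrors
  stream-scenario peak statistics.  The generator emulates only the
  statistical shape of fate-model output, not drainage physics, so
  passing tests say nothing about any particular real scenario's
  absolute concentrations.

## Problem sizes used in the shipped checks

Recovery times use single-pulse simulations monitored at 0.1 d; the
oracle-equivalence check uses 50 random 12-d profiles at a 1e-4-d oracle
step; parameter recovery uses 100 seeded replicates of the 6 × 60-fish
design with 6 simplex restarts per fit; the pattern contrasts use one
485-d many-pulse train and one single-event profile.

## Known limitations

* One-compartment reduction: `ke` conflates elimination and damage
  recovery; organism growth and trait-dependent `ke` are not modelled.
* Constant-exposure treatments only in the likelihood (acute-test
  geometry); time-varying calibration exposures would need the general
  engine on the likelihood path.
* No Bayesian estimation or forward propagation of parameter
  uncertainty; the one-at-a-time analysis deliberately ignores
  covariance.
* Mixed SD/IT models, measured-toxicokinetics ("full GUTS") variants and
  population-level ecology are out of scope.
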