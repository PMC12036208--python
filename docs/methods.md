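# Methods

## Scope and data model

`respcurve` analyzes two experiment types, each held in a tidy container:

* **Dose–response (DR)**: replicated records (factors, replicate, dose,
  response).  Factor combinations define independent curves; every curve is
  fit separately.  Dose 0 (untreated control) is retained — it anchors the
  upper asymptote and the control-normalization — and is never
  log-transformed away.
* **Time-to-event (TE)**: interval-censored counts
  (time_before, time_after] per replicate with a group total.  Right
  censoring is encoded as `time_after = inf`; when recorded counts fall
  short of the declared total, the remainder is synthesized as a censored
  row at the last observation time, so counts always sum to the total.

## Curve families

Monotonic: LL.4, LL.5, W1.4, W2.4; biphasic (hormesis): BC.5 and the
CRS.5a/b/c, CRS.4a/b/c variants (α fixed at 1, 0.5, 0.25; the `.4` variants
pin c = 0).  Forms are written out in `respcurve.models`.  Two conventions
worth noting:

* W2.4 runs opposite to the LL/W1 slope convention: for b > 0 it *rises*
  from c to d, so its x→0 limit is c.  All x = 0 evaluations use the
  analytic limit of the form, for either sign of b.
* The hormesis families as written describe inverted-J curves
  (rise-then-fall).  J-shaped (dip-then-rise) biphasic data are detected
  from the per-dose means (interior minimum below both endpoints) and fit
  on the reflected response `(y_max + y_min) − y`; the reflection is stored
  on the fit and undone inside `predict`/`gradient`, so every downstream
  quantity (ED50, M, LDS, plots) lives on the original scale.

Event-time families TE_LL4, TE_W, TE_LN are sub-distributions
F(∞) = d ≤ 1: a fraction 1 − d of individuals never responds.  Slope signs
are folded so every CDF is non-decreasing; F(e) = d/2 for TE_LL4 and TE_LN.

## Fitting

DR fits are trust-region least squares (`scipy.optimize.least_squares`)
with analytic Jacobians.  Numerical choices:

* e is optimized as ln e; estimates and covariance are reported on the
  natural scale (Jacobian recomputed in natural parameters at the optimum).
* Starts: a data-driven self-start (asymptotes from extreme-dose means,
  e from the dose nearest mid-response, b from a logit linearization),
  a near-flat configuration (which guarantees the fitted RSS cannot end
  above the constant-mean model's — the nesting the no-effect test relies
  on), and `n_starts − 1` seeded jitters for the multimodal hormesis
  objectives.  Fitting is deterministic given data and seed.
* Box constraints keep the optimizer out of flat ridges: ln e within ±ln 10⁴
  of the tested dose window, |b| ≤ 50 (beyond which the curve is a step
  between adjacent doses), asymptotes within 3 observed-response spans,
  LL.5's f in [10⁻³, 10³].  These bind only on degenerate data.
* Covariance σ̂²(JᵀJ)⁻¹ with σ̂² = RSS/(n − p), computed via SVD with tiny
  singular values truncated, so it stays positive semi-definite even for
  ill-conditioned fits (which are flagged in `fit.messages`).

TE fits maximize the interval-censored log-likelihood
Σ nᵢ ln[F(rᵢ) − F(lᵢ)] with censored rows contributing ln[1 − F(lᵢ)]
(replicates pooled within a curve), via Nelder–Mead then BFGS on
transformed parameters (ln b, logit d, ln e) from three slope starts; the
covariance is the inverse finite-difference Hessian on the natural scale.

Information criteria: Gaussian likelihood with σ²_ML = RSS/n and the
variance counted as a parameter, so AIC = −2 logL̂ + 2(p + 1) for DR fits;
TE fits use their own log-likelihood with p = 3.  AIC offsets differ
between software conventions — only differences within one data type are
meaningful, and model selection never compares criteria across likelihood
families.  Ties break toward fewer parameters, then registry order.

## ED50 / T50

Absolute estimates target a fixed response level (default 50 on the
percent scale, 0.5 on proportions), meaningful after control
normalization; relative estimates target the midpoint of the fitted span.
For biphasic curves the per-phase relative span runs from the phase's
asymptote (the dose-0 plateau for the low phase, the parameter-c plateau
for the high phase) to the response at the extremum dose M — a convention
recorded here because the span's endpoints are not unique for a biphasic
curve.

* **Delta method** (`ritz_gerhard`): closed form where available (LL.4
  relative ED50 is exactly ê), otherwise bracketed root-finding on the
  fitted curve.  The gradient ∂ED/∂θ is taken by central differences of
  the full ED map, which keeps closed-form cases exact (for LL.4 the map
  is θ ↦ e, so SE(ED50) = √Σ_ee identically); SE = √(gᵀΣg), Wald CI.
  Biphasic: high phase only — the low phase is directed to the
  interpolation method.
* **Interpolation** (`serra_greco`): 10⁴-point log-spaced grid over the
  tested dose range (extended down to min-positive/1000 when dose 0 was
  tested, so crossings below the first nonzero dose remain locatable);
  target crossings by inverse linear interpolation; per-phase segmentation
  at M for biphasic fits.  CI: doses where the pointwise delta-method
  confidence band crosses the target within the same phase; absent if the
  band never crosses inside the grid.
* **Reed–Muench** (`reed_muench`): linear interpolation between the two
  adjacent dose means bracketing the target, on log₁₀ dose (the classic
  convention, matching log-axis plots); a bracketing pair containing dose 0
  falls back to the linear scale; non-monotone means use the first
  crossing and flag the ambiguity.  SE/CI by bootstrap over replicates
  (2000 resamples, seeded) since no analytic formula exists for this
  estimator.

Biphasic metrics: M by coarse grid + bounded scalar refinement; LDS as the
root of fitted(x) = fitted(0) beyond M; f reported with its Wald test.
When f̂ = 0 or the fitted hump does not exceed the control response the
metrics are flagged undefined.

T50: absolute = smallest t with F(t) ≥ ½ (whole sample); relative =
smallest t with F(t)/F_max ≥ ½, where F_max is d (parametric) or the CDF at
the last observation (nonparametric).  Inside a Turnbull equivalence
interval the NPMLE CDF is not uniquely defined; the default
"midpoint-linear" evaluator interpolates linearly across the interval, and
a "right-endpoint" step convention is available.  All estimates are
restricted to the observed window: out-of-range values keep their raw
value internally but are masked (NaN) in every exported table, with a
closed upper bound (a value equal to the range maximum is in range).

## NPMLE and kernel smoothing

The Turnbull estimator assigns mass to the innermost equivalence intervals
of the observation set and iterates the self-consistency equations
(EM, tolerance 10⁻¹⁰, cap 10⁴ iterations).  For non-overlapping intervals
the fixed point is reached in one step and equals the empirical
proportions.  The NPMLE log-likelihood bounds every parametric fit's from
above, which the tests exploit as an optimality check.  Kernel smoothing
places each finite class's mass at the class midpoint under a Gaussian
kernel; "auto" bandwidth is a weighted Silverman rule
0.9 · σ_w · n_eff^(−1/5) with n_eff = 1/Σw².  As the bandwidth shrinks the
smoothed CDF converges to the Turnbull step CDF outside the classes.

## Assessment tests

* **Lack-of-fit**: F comparison of the model RSS against the pure-error
  RSS of the one-mean-per-dose ANOVA; requires replicated doses.
* **Neill**: the grouping-based generalization.  Default grouping: each
  dose its own group when replicates exist (reducing exactly to the
  classic test), otherwise adjacent dose pairs (odd leftover dose joins
  the last group).  Requires more groups than parameters and ≥ 2
  observations per group.
* **No-effect**: likelihood-ratio test against the constant-mean model,
  n ln(RSS₀/RSS_model) referred to χ²(p−1).  The LRT form was chosen over
  the F form after simulation showed the F version conservative under a
  flat null (the flat-data optimum sits on a boundary ridge of the model
  manifold, deflating the effective numerator df); the LRT's measured
  type-I error is ≈ 0.04 at α = 0.05.
* **Parameters ≠ 0**: per-parameter Wald t tests on n − p df; the
  hormesis f is the scientifically interesting one for biphasic fits.

## Synthetic data

`simulate_dose_response` adds iid homoscedastic Gaussian noise to a known
curve (an optional proportional-noise mode exists for robustness checks);
`simulate_time_to_event` draws a binomial number of responders (probability
d), samples their event times by inverse CDF, bins them into the
inspection schedule, and books the rest as right-censored.  Seeds fully
determine outputs.  Default study conditions mirror common bench designs:
7–9 log-spaced doses plus an untreated control, 4 replicates, noise sd ≈ 5%
of the response span; germination-style schedules of 6–12 h inspections
over a week, 100–200 individuals per dish.  What the generator does *not*
emulate: between-replicate (plate/dish) random effects, heteroscedasticity
tied to the mean, non-Gaussian error, or correlated seeds within a dish —
so passing recovery tests demonstrate correctness of the estimators under
their own assumptions, not robustness to those violations.

## Problem sizes used in the automated checks

Recovery and coverage run 200 simulated assays per family (8 log-spaced
doses + control × 4 replicates, noise sd 2 for DR; 28 six-hour inspection
intervals × 200 individuals for TE).  The five-parameter log-logistic uses
a denser design (10 doses × 8 replicates, sd 1) because its e and f
parameters trade off almost exactly on sparser layouts.  Test calibration
uses 1000 null simulations; brute-force oracle comparisons scan 10⁶-point
dose grids.

## Known limitations

* Replicate-level clustering/frailty in TE data is ignored (replicates are
  pooled); NPMLE quantile uncertainty would need grouped resampling.
* Wald intervals can misbehave near boundaries (d̂ → 1 in TE fits; f̂ → 0
  in hormesis fits); profile likelihood is not implemented.
* The Serra–Greco CI is a confidence-band crossing, not a full bootstrap;
  it can be one-sided-missing when the band never crosses the target
  inside the tested range.
* Model selection compares criteria only within one likelihood family;
  DR (least squares) and TE (interval-censored ML) criteria are never
  mixed.
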