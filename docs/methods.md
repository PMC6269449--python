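# Methods

## The ureide index and its coordinate system

Soybean exports symbiotically fixed N from nodules as ureides
(allantoin/allantoate), while soil-derived N moves mostly as nitrate. The
relative abundance of ureides in stem tissue,
`RAU (%) = 100 · 4U / (4U + N)`, weights the ureide concentration by 4
because each ureide molecule carries four N atoms. RAU is a ratio of like
quantities, so any single consistent concentration unit works; the readers
enforce one unit per column. RAU is undefined (0/0) when both
concentrations are zero — that is raised, never silently imputed.

Season position is measured in thermal time: the daily increment is
`max(0, (Tmax + Tmin)/2 − 8 °C)`, summed from the V2 stage. Negative
increments are clamped at zero (backward development is meaningless and
clamping is the standard degree-day convention); no upper temperature
cutoff is applied. The clock reads exactly 0 at V2 and accrues a day's
increment on the day itself (a half-open convention that makes readings
additive over contiguous ranges). Stage dates must be supplied — the
pipeline never infers phenology. The flowering-stage sample is labelled R2
even where field sampling extended into early pod formation.

## The beta growth function

Seasonal RAU is modelled as
`RAU(t) = RAU_max (1 + (t_max − t)/(t_max − t_m)) (t/t_max)^{t_max/(t_max − t_m)}`,
the determinate-growth beta function: 0 at t = 0, a single inflection at
t_m, the peak RAU_max exactly at t_max, decline beyond. The power term uses
base `t/t_max`; that is the only base for which the curve actually attains
RAU_max at t_max, and it reproduces the derived traits of the reference
fits — e.g. the high-fixation control triple (90, 397, 1117) gives
t_0.5 = 473 °Cd and a maximum rate of 0.116 % °Cd⁻¹, matching the values
those fits report. At t_m = 0 (the low-fixation group sits on this
boundary) all 0⁰ terms are taken as 1 by continuous limit.

Derived traits:

* **maximum rate** — closed form
  `RAU_max (2t_max − t_m)/(t_max(t_max − t_m)) (t_m/t_max)^{t_m/(t_max − t_m)}`,
  which equals the analytic derivative of the curve at t = t_m (tested to
  1e-9 relative);
* **t_0.5** — unique root of RAU(t) = RAU_max/2 on (0, t_max), found by
  Brent's method (the curve is strictly increasing there);
* **AUC** — composite-Simpson integral of max(RAU, 0) on [0, t_end] with
  2000 panels, where t_end is the last observed stage thermal time of the
  group; reported raw (% °Cd) and normalized by the largest raw AUC in the
  table, so the dataset maximum is exactly 1.

## Curve fitting

`fit_beta` minimizes unweighted SSE with scipy's trust-region-reflective
least squares. Replicate-level observations enter individually (no
pre-averaging); fitting stage-level means instead is the caller's choice.
Internally the parameters are (RAU_max, frac, t_max) with t_m = frac·t_max
and frac ∈ [0, 0.995], so the ordering 0 ≤ t_m < t_max holds throughout
optimization; bounds are 0 < RAU_max ≤ 110 and t_max ≤ 1.5 × max observed
t. Initialization: RAU_max₀ = max observed RAU, t_max₀ = t at that maximum,
t_m₀ = 0.4 t_max₀ — robust for sigmoidal data sampled at four stages.
Standard errors come from the Jacobian at the solution; the SE of t_m uses
the delta method on (frac, t_max), which is exact to first order.
Goodness of fit: R² = 1 − SSE/SST and Syx = √(SSE/(n − 3)). Constant-RAU
input is rejected (the curve is not identifiable), and a non-converged fit
raises with its final parameter state; boundary-pinned solutions carry an
`at_boundary` flag.

In a seeded 200-replicate study at the trial design (12 sites × 4 stages,
Gaussian noise SD 12), each parameter's ±2 SE interval covers its true
value in ≥ 90% of replicates, and with noise calibrated to the reference
Syx (12.8) the mean refit R² falls inside the 0.62–0.87 band those fits
report. The recovery study samples stage times inside the span where the
declining arm is still non-negative; clipping noisy RAU to [0, 100] at
times past that span would otherwise distort the Gaussian-noise premise.

## AICc treatment comparison

Whether a fertilized treatment needs its own curve is decided by AICc on
pooled data: shared model = one triple on the pool (k = 4, counting the
error variance), separate = one triple per set (k = 7), with
`AICc = n ln(SSE/n) + 2k + 2k(k+1)/(n − k − 1)`. The smaller AICc wins;
`exp(|Δ|/2)` is reported as the evidence ratio. Comparisons are run
control vs each fertilized treatment within a fixation group — pairwise,
not all-subsets. The small-sample correction matters here: pooled n ≈ 96
with k = 7 is well inside the regime where plain AIC over-selects.

## Grouping and site summaries

Sites are split by the quartiles (linear interpolation between order
statistics) of control-treatment RAU_R6: strictly below q25 → low, at or
above q75 → high, otherwise medium; ties at q25 stay medium, and when
q25 = q75 (no spread) every site is medium. On the published 23-site
control values this reproduces the six-site high group exactly; the
published low/medium split is not recoverable from rounded values (two
sites print the same RAU yet were grouped differently from unrounded
data), so the deterministic tie rule above is documented rather than
matched. Site summaries are across-treatment means with t-distribution
95% CIs on n − 1 df; with only treatment means available the balanced-mean
equivalence is used, and exact CI reproduction is not attempted.

## Phenology de-trending and residual regressions

Thermal time to R6 spans roughly 909–1733 °Cd across the network and
confounds maturity-group allocation with every agronomic outcome. Each
trait (seed yield, harvest index, seed oil; protein and biomass are
computed but flagged as expected non-significant) is de-trended with a
continuous two-segment linear model: slope a and intercept b before the
breakpoint TT_o, slope d after, the segments meeting at TT_o. Continuity
is enforced because the fitted trend is a single response curve — a free
disjoint second segment would make "residual" ill-defined at the break —
and with it the model has four parameters (a, b, d, TT_o). A
through-the-origin second segment (d derived from the other three) was
considered and rejected: it cannot represent a flat trait profile, which
the plateau of yield against season length approximates.

The breakpoint is profiled over the observed x values (two extremes
trimmed at each end, ≥ 3 points required on each side), with (a, b, d)
solved by linear least squares on the hinge basis per candidate —
deterministic and reproducible at the ~92-point scale of site × treatment
means (the default aggregation; plot-level fitting is a flag).

Residuals are regressed on RAU_R6 by OLS (slope, intercept, two-sided p
for slope = 0; significance stars at 0.05/0.01/0.001 with no multiplicity
correction) and by check-loss quantile regression at τ = 0.99 and 0.01
(statsmodels' IRLS solver, deterministic), tracing the upper and lower
response boundaries. Extreme quantiles are refused below 20 points and
documented as unstable below ~50. The fitted 0.99 and 0.01 lines bracket
the mean line pointwise over the observed RAU range under exchangeable
noise; no ordering of the *slopes* is asserted — extreme-quantile slope
estimates fluctuate around zero far more than the OLS slope in finite
samples.

## Synthetic trial generator

The generator emulates the reference network's structure: 23 sites ×
4 treatments (control, N at sowing, N at V4, N at R2) × 3 blocks, four
stem assays per plot, daily weather per site, and plot-level outcomes.
Defaults are the study conditions:

* group base curves (90, 397, 1117), (84, 362, 1066), (71, 0, 931) for
  high/medium/low, with additive treatment shifts taken from the
  high-group fertilized fits (late N depresses the peak by 15 points);
* RAU noise: additive Gaussian, SD 13 (middle of the 11–16 Syx band),
  clipped to [0, 100] — no distributional claim is inherited, so Gaussian
  is a documented choice;
* per-site amplitude effects on RAU_max (SD 5 points, the within-group
  spread of control RAU_R6 across sites) and a per-site thermal-axis
  scale t_max ∝ season length, so R6 samples near the peak in short- and
  long-season sites alike — without these, RAU_R6 would be a deterministic
  function of phenology and the residual analysis would have nothing to
  estimate, which real networks contradict;
* thermal time to R6 uniform on [909, 1733] °Cd; V4/R2/R8 at fractions
  0.20/0.55/1.25 of it; weather synthesized so degree-day accumulation
  from V2 reproduces every stage thermal time exactly (piecewise-constant
  daily means ≤ 22 °C);
* outcomes: bilinear trends on thermal time to R6 spanning the observed
  trait ranges, plus linear RAU_R6 costs of −13 kg ha⁻¹ per % (yield) and
  −0.0011 per % (harvest index), a small negative oil effect, and none for
  protein; biomass is yield/HI so the harvest-index identity holds by
  construction. A heteroscedasticity toggle inflates HI noise where the
  expected HI is low, for exercising the boundary-quantile contrast.

Assay pairs invert the RAU formula exactly (ureide ≡ 1,
nitrate = 4(100 − RAU)/RAU), so recomputing RAU from the emitted table
reproduces the simulated value; zero RAU is emitted as (0, 1).

What the generator does **not** emulate: spatial/block correlation, soil N
dynamics, assay measurement structure beyond additive noise, treatment ×
phenology interactions, or mixed-model adjusted means (simple means stand
in for least-squares means throughout). Passing tests therefore show the
estimators recover known structure under these idealized conditions, not
that field data meet them.

## Problem sizes and determinism

Stochastic checks use seeded `numpy` Generators throughout: 200 replicates
for the curve-fit coverage, breakpoint-recovery and end-to-end slope
studies, 100 for AICc separation power, 20–50 where a mean is all that is
compared. The full pipeline is deterministic for a fixed seed (byte-equal
JSON reports). The residual-slope recovery shows mild attenuation
(≈ −11.5 recovered for −13 injected): the bilinear de-trend absorbs the
component of the RAU signal collinear with phenology, an inherent property
of the residual method, not an implementation defect.

## Known limitations

* Mixed-model adjusted means (block as random effect) are out of scope;
  all aggregation is by simple means.
* The AUC of the declining arm is truncated at the last observed stage;
  extrapolation beyond R8 is deliberately avoided.
* Quantile-regression inference (standard errors/p-values at extreme τ) is
  not reported; only point estimates of the boundaries.
* The percent peak-RAU reduction under late N is reported as computed from
  the fits, without asserting any particular rounding.
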