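# Methods

This note documents the models behind each pipeline stage, the defaults and
why they were chosen, what the synthetic data do and do not emulate, and the
numerical decisions a user may want to audit or change.

## 1. Epoch processing (`accelerometry`)

Input is a table of fixed-length epochs (default 5 s) of mean acceleration
magnitude in g units with a wear flag, plus a sleep log of wake and sleep
onset clock times per day.

* **Waking restriction.** Only epochs in the half-open window
  [wake onset, sleep onset) are analyzed; the half-open convention avoids
  double-counting the transition epoch. The first and last recorded days are
  dropped (device fitting and return), so a 9-day recording contributes 7
  analysis days.
* **Validity.** A day is valid when the worn fraction of its waking epochs
  is ≥ 2/3 (inclusive); a participant is retained with ≥ 2 valid weekdays
  and ≥ 2 valid weekend days. Weekend means Saturday/Sunday by calendar
  weekday. Validity is judged on raw wear *before* imputation; imputation is
  then applied only to valid days. The ordering is a design decision — the
  alternative (impute first, then test wear) would make the wear test
  vacuous.
* **Nonwear imputation.** Each nonworn waking epoch receives the mean
  acceleration at the same clock slot across the participant's other valid
  worn days; slots never worn fall back to the participant's overall worn
  waking mean. This transparent same-clock-time rule stands in for
  device-specific published imputation algorithms, whose inputs (raw
  sub-second signal) are outside this pipeline's scope.
* **Intensity classes.** Sedentary < 0.03 g ≤ light < 0.10 g ≤ MVPA, with
  both bounds inclusive on the upper class, matching the printed
  inequalities of the convention.
* **Weekly summaries.** Daily minutes per class are plain means when all 7
  days are valid, otherwise reweighted (5·weekday mean + 2·weekend mean)/7.
  The same weighting produces daily waking time T_i.
* Epoch spacing is inferred from the data (median within-day time step), so
  tables at other resolutions (e.g. 60 s) are summarized correctly.

## 2. Activity densities (`activity_density`)

x = ln(1 + a) mildly decompresses the right-skewed acceleration scale;
f_i is a Gaussian-kernel KDE of a participant's waking x values and
A_i(x) = T_i f_i(x) integrates to the daily waking minutes.

* **Bandwidth.** Two-stage direct plug-in (Gaussian kernel): a normal-scale
  estimate of the 8th-order density functional seeds pilot bandwidths for
  the 6th- and 4th-order functionals, and
  h = (R(K)/(ψ̂₄ n))^{1/5}. Pair sums use the exact double sum below
  n = 3000 and linear-binned FFT autocorrelation (4096 bins) above. The
  selector is scale-equivariant and, on Gaussian samples, lands within a few
  percent of the closed-form AMISE optimum. Bandwidths are per participant;
  the density is an individual summary, not a pooled one.
* **Shared grid.** 4096 equally spaced points from 0 to the cohort maximum
  of x plus 4 pooled bandwidths. Epoch distributions pile up near the
  sedentary end; realized plug-in bandwidths are ~1e-3 on the x scale, so
  the grid step must be a fraction of that for quadrature to hold. With the
  grid resolving the kernels, every density integrates to 1 within 1e-3 and
  every A_i to T_i within 0.5 min.
* **Evaluation.** Exact summation for small samples; linear binning + FFT
  convolution with a discretely renormalized kernel for large ones (mass
  preserved exactly; pointwise agreement to ~1e-5 relative once the grid
  resolves h). Kernel mass leaking below x = 0 (the Gaussian kernel has
  unbounded support but x ≥ 0) is lumped into the first grid cell; no other
  boundary correction is applied, and the leak is tiny because the data sit
  a few bandwidths above zero.

## 3. Spirometry curves (`spirometry_curves`)

Per participant the trial with the largest FEV1 (ties: first listed) is
retained; participants without one complete trial are excluded and counted.

* **Flow-volume fit.** The anchor set is (v_pef, PEF), (0.25·FVC, FEF25),
  (0.50·FVC, FEF50), (0.75·FVC, FEF75), (FVC, 0), fit by a cubic B-spline
  (8 basis functions on the volume fraction scale) with a second-difference
  penalty; the terminal anchor is enforced exactly as a linear constraint.
  The smoothing parameter is selected by GCV over a dimensionless log grid
  (1e-8..1), rejecting candidates whose fit dips below zero on a dense grid
  or misses any anchor by more than 2% of PEF; if no candidate qualifies the
  least-violating one is used and flows are clipped at zero. The small basis
  is deliberate: with five anchors a larger basis reproduces the anchors
  while wiggling between them, and the wiggle propagates into the ODE.
* **Peak location.** Summary spirometry does not record the expired volume
  at peak flow; it is fixed at v_pef = 0.12·FVC (configurable). Below v_pef
  the flow curve is a linear ramp from the origin.
* **Volume-time ODE.** dy/dt = F(y) with y(1 s) = FEV1, integrated by RK45
  (rtol 1e-8) forward to 6 s and backward toward v_pef. Because F(0) = 0
  makes y ≡ 0 a solution, the curve cannot be launched from zero volume;
  anchoring at 1 s and integrating both directions honors the data, and the
  unresolvable rising limb is prepended as a linear volume segment from
  (0, 0) to the backward-reached time of v_pef. Integration stops at
  (1 − 1e-3)·FVC, after which y is held constant (F → 0 makes the asymptote
  stiff); output is resampled to a 0.01 s grid with y(1) = FEV1 exactly.

## 4. Scalar models (`scalar_models`)

OLS of FEV1 or FVC (ml) on minutes/day in one activity class, reported per
10 min/day. Model 1 adjusts for age, sex, ethnicity, height, weight,
smoking group and waking duration (so exposure minutes trade off against
the rest of the waking day); model 2 adds occupational position, education,
marital status, alcohol, fruit/vegetable consumption, respiratory disease,
chronic-disease count, and cigarettes/day within current and recent
ex-smokers (zero elsewhere). Height+weight is kept over BMI;
`compare_anthropometry` reports the AIC difference justifying that choice
on any given table. Analyses are complete-case; constant columns (e.g.
empty smoking strata in small subsets) are dropped, and genuine rank
deficiency raises an error naming the collinear columns.

Stratum-specific slopes come from one model with exposure × smoking-group
terms (never smokers as reference) via linear combinations sharing the
model covariance; the reported interaction p-value is the 1-df Wald test on
an exposure × ordinal-smoking product (0 = current … 3 = never), matching a
single-p-per-exposure reporting layout. These are two deliberate views of
the same question: the 1-df ordinal test has power against the graded
pattern of interest, the categorical model imposes no ordering on the
stratum estimates.

## 5. Function-on-function regression (`fof_regression`)

y_i(t) = α(t) + ∫ β_{g(i)}(x,t) A_i(x) dx + Z_i γ(t) + ε_i(t), all smoking
groups fitted jointly with shared α, γ and residual variance.

* **Bases and penalties.** β_g lives in a tensor product of cubic B-splines
  (default 15 in x, 15 in t) with second-difference penalties in both
  directions; α and each γ_j use the same t-basis with the t-penalty. Two
  smoothing parameters (λ_x for all surfaces, λ_t everywhere) are chosen by
  GCV on a 7-point log grid, with the effective degrees of freedom inflated
  by γ = 1.4 in the GCV denominator — the standard guard against GCV's
  tendency to undersmooth, which here occasionally let surface estimates
  explode in weakly identified directions of the predictor space.
* **t-knots follow the response.** Volume-time curves rise steeply inside
  the first ~1.5 s and then plateau. Interior t-breakpoints are placed at
  equal increments of a 50/50 blend of the mean curve's height and of time,
  concentrating flexibility in the rise. With uniform knots the rise is
  unrepresentable and its lack of fit contaminates whatever covariates can
  absorb it.
* **Centering.** All non-intercept design columns (scalar covariates and
  the discretized functional terms) are mean-centered. Since every
  participant's A_i carries nearly the same total mass (≈ T_i), the
  functional term is nearly collinear with the intercept, and any
  approximation error in α(t) would otherwise leak into β̂ as spurious,
  strongly "significant" structure. After centering, participant-constant
  lack of fit is orthogonal to the design by construction; the null
  significance-mask rate is restored to the nominal 5%.
* **Estimation and inference.** The x-integral is discretized by trapezoid
  weights on the shared grid, reducing the model to penalized least squares
  for Y ≈ X Θ C′ solved through its Kronecker normal equations (Cholesky
  with escalating jitter for semi-definite corner cases). Residuals are
  treated as independent across t (working independence) with variance
  estimated at each t-grid point; the covariance of the penalized estimator
  under that model gives pointwise Wald standard errors and p-values, and
  the significance mask is exactly p < 0.05. No simultaneous bands are
  attempted. Groups smaller than the x-basis dimension are skipped with a
  warning.
* **Fitting grid.** The t-grid subsamples the 0.01 s reconstruction to
  0.05 s on [0.05, 6]; the x-grid is inherited from the density stage.

## 6. Threshold analysis (`threshold_analysis`)

The threshold at spirometry time t (1 s for FEV1, 5 s for FVC) is the
smallest grid x whose significant-positive run extends unbroken to the top
of the group's occupied intensity range; it is reported back on the g scale
as e^x − 1, and "no threshold" is a valid outcome. The run requirement
prevents isolated significant pixels from defining a threshold. The
occupied range's upper limit excludes the top 1% of the group's pooled
activity mass: Gaussian-kernel (and mixture) densities are positive
everywhere, so a literal "where anyone has density" rule never binds, while
surfaces estimated on the top percentile of person-time are noise.

Time above threshold is computed two ways — T_i times the density tail mass
(trapezoid rule with partial-cell interpolation), and directly from epochs
with the 5:2 reweighting — and the two agree within a few percent on
synthetic participants. The per-10-minute effect is a within-group OLS of
the reconstructed volume at the outcome time on above-threshold minutes,
adjusted for the same covariates as the functional model (age, sex,
ethnicity, height, weight, respiratory disease, chronic-disease count);
outcomes are read off the reconstructed curves rather than the raw
spirometer fields for internal consistency (configurable by passing a
different outcome column). A scalar refit was chosen over integrating the
coefficient surface because it yields an honestly reported confidence
interval under the same working model as the conventional analysis; both
exposures (density path and epoch path) are exposed.

## 7. Synthetic cohort (`synthetic_cohort`)

The generator's defaults emulate the study conditions: four smoking-history
groups at proportions 2.8 / 4.8 / 40.8 / 51.6%, nine 24-hour days of 5-s
epochs, wake ≈ 07:00 and sleep onset ≈ 23:00 with ±20 min daily jitter,
wear gaps on 15% of days (30–120 min) and oversized gaps on 3% (failing the
2/3 rule), and 2% of participants with incomplete spirometry.

* **Epoch accelerations** follow a two-component lognormal mixture per
  group (sedentary-dominant component with median ≈ 0.012 g, active
  component with median ≈ 0.08 g); group activity shares are set so mean
  sedentary/light/MVPA minutes land near 700/210/75 with current smokers
  least active. Participant-level heterogeneity in the mixture weight,
  component medians and spreads gives the cohort's densities several
  directions of variation — without it the functional design is nearly
  rank-3 and coefficient surfaces are unidentifiable off that span. Epoch
  means are capped at 2 g (device dynamic range). Sleep epochs hover near
  0.003 g. The real epoch-level distribution shape of such cohorts is not
  published; the mixture is a documented stand-in, and the transform +
  plug-in-bandwidth machinery does not depend on it.
* **Spirometry** comes from a parametric flow-volume template
  F(v) ∝ v^a (FVC − v)^0.85 e^{−cv/FVC}, peaking at 0.12·FVC, whose decay
  knob c is solved per participant to hit the target FEV1. The sublinear
  terminal exponent makes blows finish in finite time so curves plateau
  near FVC within the 6-s test. FEV1/FVC is drawn in [0.72, 0.90] —
  deliberately excluding obstructive-range ratios, whose slow terminal
  decay would not plateau by 6 s; recoverability, not clinical case mix,
  is the generator's goal. PEF ≈ 1.9·FVC per second ±10%. Five trials per
  participant add ~1–2% multiplicative noise, and the largest-FEV1 trial is
  the retained blow.
* **Planted structure.** FVC is built as covariate effects (defaults near
  textbook magnitudes: −25 ml/yr age, −576 ml women, +32 ml/cm height,
  group offsets) plus a group-specific effect of realized minutes above a
  group threshold (defaults: 0.054 g at 3.5 ml/min for current smokers,
  0.094 g at 3.6, 0.074 g at 1.5, 0.161 g at 1.3 for never smokers) plus
  Gaussian noise (sd 300 ml, a typical adjusted-regression residual scale).
  The truth (thresholds, effects, per-participant exposures and outcomes)
  is serialized with the data.
* **`simulate_fof_design`** builds designs for which the
  function-on-function model holds *literally*: analytic mixture densities
  on the x-grid, planted β surfaces (separable b(x)·r(t) with r the
  normalized volume profile, or arbitrary surfaces), covariate functions
  γ_j(t) = c_j·r(t) (or a supplied profile), and independent Gaussian noise
  with sd 300·max(r(t), 0.05) ml. This is the workhorse for estimator-level
  studies without the epoch machinery.

What the generator does **not** emulate: circadian activity profiles within
the day (epochs are exchangeable within waking time), autocorrelated epoch
sequences, device calibration error, realistic sleep-detection error,
obstructive spirometry, missing covariates, or residual dependence between
activity and unmodeled health status. Passing tests therefore demonstrate
estimator correctness under the stated generative assumptions, not
robustness to everything real cohorts contain.

## 8. Validation study sizes

The test suite and `scripts/acceptance.py` size the simulation studies as
follows: pointwise mask type-I error from 100 null cohorts of n = 300
(40-point x-grid on [0, 0.30], bases 15×8); bump-surface recovery at
n = 500 (bump height 10 ml·min⁻¹ per unit mass, σ_x = 0.07, σ_t = 1.2 s,
bases 25×12, integrated squared error < 10% of the bump's square);
threshold localization from 50 cohorts of n = 500 with a planted ramp
rising over 0.03 x-units from a grid-aligned 0.08 g foot (30-point grid,
bases 25×8, within 2 grid steps ≥ 80%); smoker-vs-never threshold ordering
from 20–25 two-group cohorts of n = 1000; scalar slope recovery from
150–200 cohorts of n = 1000; and one full epoch-level pipeline run at
n = 200 with a 0.10 g planted threshold for the cross-check between the
threshold-based and conventional MVPA effect estimates. The planted ramp
effect (3.5 ml per minute) and simulation noise reuse the generator's
defaults; the bump amplitude is set so the recovery study probes estimator
bias rather than raw detectability.

## 9. Known limitations

* The x-direction smoothing that stabilizes coefficient surfaces also
  smears effect onsets by roughly one basis-knot spacing; recovered
  thresholds are accordingly resolved only to ~0.01 g at these sample
  sizes, and significance-onset thresholds sit slightly below a planted
  sharp onset when power is high.
* Pointwise inference ignores λ-selection variability and residual
  correlation across t; coverage of the pointwise bands is accurate on
  average but whole-band excursions occur (no simultaneous bands).
* The ODE reconstruction inherits the fixed v_pef = 0.12·FVC assumption;
  misspecifying the peak-flow volume distorts mainly the pre-1 s segment.
* Density-path exposures are KDE-smoothed and can differ from epoch-count
  exposures by a few percent near a threshold, which mildly inflates
  within-group effect estimates relative to the planted per-minute values
  (classical errors-in-exposure behavior, visible in the cross-module
  check's tolerance).
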