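# Methods

## The measurement model

Adherence is measured as the proportion of days covered (PDC). For one
patient and one drug subclass, each pharmacy fill contributes its
`days_supply` starting on the fill date; under the default **shift-forward
carryover** convention an early refill is deferred to begin the day after
the prior supply ends, so supply is conserved and overlapping fills extend
coverage rather than being lost. The alternative **truncate-overlap**
policy (interval union; overlapping days count once) is available for
sensitivity analysis and is never larger than shift-forward for the same
fills. PDC = distinct covered days within the window / window length
(365 days by default), hence always in [0, 1]. Supply never extends past
the window end, and no supply crosses the baseline/follow-up boundary: the
two periods are analyzed as separate 365-day observation units, each using
only the fills dated inside it.

When a patient fills k subclasses of a drug class in a window, the class
PDC is the unweighted mean of the k subclass PDCs (each already capped at 1
by construction, since it is a count of distinct days). A patient is
**adherent** when class PDC ≥ 0.80, boundary inclusive.

Internally all dates are integer day offsets from a fixed epoch and all
intervals are half-open `[start, end)`, so interval arithmetic is exact and
union lengths are additive. Files use ISO-8601 dates only.

### Implementation note

Both carryover policies are computed by one vectorized segmented scan over
all (patient, subclass) streams at once. For shift-forward the recurrence
`end_k = max(end_{k-1}, date_k) + supply_k` is rewritten as
`end_k = S_k + max_{j≤k}(date_j − S_{j−1})` with `S` the in-group supply
cumsum, which a per-group running maximum evaluates without a Python loop.
The same engine serves the single-stream API and the bulk table builder, so
a 50,000-patient study (~1.2 M fills) computes PDC in a few seconds. Tests
check the engine against two deliberately naive oracles: a day-by-day
supply-inventory simulation (shift-forward) and boolean day-marking
(truncate-overlap).

## Cohorts

A patient enters a drug-class cohort when (a) aged 18–89 at the baseline
window start (age is evaluated at a fixed point so the filter is
deterministic), (b) enrolled from the baseline start through the follow-up
end, and (c) holding at least one fill of the class in *each* period.
Filters run in a fixed order and an attrition log counts removals per rule;
membership itself is order-insensitive. Fills referencing unknown patients
are a referential-integrity error, not silently dropped.

## Effect estimation

* **Crude risk ratio** — Katz log method: `RR = (a/n₁)/(c/n₂)`, 95% CI
  `exp(ln RR ± 1.96·√(1/a − 1/n₁ + 1/c − 1/n₂))`, two-sided Wald p on the
  log scale. No continuity correction; a zero numerator cell yields a
  non-finite CI/p flag instead.
* **Adjusted risk ratio** — modified Poisson: a log-link Poisson GLM on the
  binary outcome with HC0 sandwich variance (statsmodels IRLS). This
  estimates the RR directly for a common outcome where logistic odds ratios
  would overstate it. With only the group indicator the estimate equals the
  crude RR exactly; with stratification covariates on multiplicative data
  it equals the Mantel-Haenszel RR (both are test oracles). Members with a
  missing covariate (BMI may be absent) are excluded from that model with a
  logged count. Class-specific covariate lists: diabetes, BMI and primary
  care visits/year for antihypertensives; diabetes and visits/year for
  antihyperlipidemics.
* **Transitions** — each member is classified by (baseline, follow-up)
  adherence into four levels. Each non-reference level is compared to the
  adherent→nonadherent reference as a conditional pairwise risk: within an
  arm, the probability of the level among members in {level, reference};
  the RR of those conditional risks is computed exactly as a restricted
  2×2 (Katz CI). The adjusted version runs the same modified-Poisson
  estimator on the restricted subset. The full four-category multinomial
  likelihood is deliberately not maximized; the pairwise estimator is the
  contract and reproduces the emulated study's printed values.
* **RD / NNT** — risk difference with Wald CI; NNT = round(1/RD) computed
  from the unrounded RD, reported only when RD > 0, flagged infinite at
  RD ≤ 0.
* **Baseline table** — two-sample t (symmetric continuous, mean/SD),
  Kruskal-Wallis (asymmetric continuous, median/IQR), Pearson chi-square
  without continuity correction (categorical, n/%). No multiple-testing
  adjustment anywhere, matching the emulated analysis.

Report formatting rounds RR/CI to 2 decimals, rates to 1 decimal and p to
two decimals without a leading zero (".04"); internal values are never
rounded.

## The synthetic-claims generator

The generator emulates the *statistical* structure of a two-wave-pooled,
two-arm observational adherence study; it does not model portal behavior,
note reading, seasonality, or real formulary structure, and its refill-gap
distribution is a stand-in, not a claim about real claim-level patterns.

* **Latent propensity.** Each patient draws an adherence propensity
  θ ∈ [0, 1] from a two-component mixture: with probability 0.8 a
  high-adherence bulk `0.8 + 0.2·Beta(2, 1)`, else a low tail
  `0.8·Beta(2, 2)`. A single-family distribution cannot simultaneously give
  mean PDC ≈ 0.86 and ~23% nonadherent; the mixture can, and the tail mean
  was chosen so the simulated mean PDC lands in the published 85–87% band
  while the adherent fraction stays in 75–80%.
* **Fills.** Per patient × class × subclass stream (1–3 subclasses, P =
  0.55/0.30/0.15; days-supply 30 or 90 with P = 0.4/0.6, fixed per stream):
  an initial fill within 7 days of the window start, then a renewal process
  where the next fill occurs at the previous coverage end plus a gap that
  is 0 with probability θ (an on-time refill) and otherwise exponential
  with mean `supply/θ`, so the long-run covered fraction is ≈ θ. In the
  θ→1 limit PDC is exactly 1; in the θ→0 limit each stream has a single
  fill.
* **Dynamics and effect.** The follow-up propensity is
  `μ + ρ(θ − μ) + ε + drift + effect·1[intervention]` with autocorrelation
  ρ = 0.8 and innovation SD 0.10, clipped to [0, 1]. Adherence transitions
  are therefore emergent, not imposed. The per-class drift and
  intervention-effect shifts are the only calibrated knobs: a one-time
  monotone bisection (`calibrate_effect`, n = 50,000, tolerance ±0.5
  percentage points on each rate) against the emulated study's follow-up
  adherence rates — (0.797, 0.753) antihypertensive, (0.776, 0.773)
  antihyperlipidemic — froze drift = {+0.0234, +0.0469} and effect =
  {+0.0469, 0.0}. Calibration simulates the same quantity the pipeline
  later measures (claims → PDC → adherence), so recovery tests are
  end-to-end.
* **Covariates** mirror the emulated cohort's published moments (age
  N(60.5, 12.9²) truncated to [18, 89]; 53% female; 99.3% white; 25%
  diabetic; log-normal BMI median 31.1 and visits/year median 3.3; gamma
  Charlson mean 0.85). They are independent of θ by default; a
  `diabetes_propensity_shift` knob introduces confounding so adjusted and
  crude estimates can be made to diverge in tests. Class membership is
  38.3/35.1/26.6% (both / antihypertensive-only / antihyperlipidemic-only).
* **Determinism.** One integer seed drives separate SeedSequence-spawned
  streams for roster, propensities, stream structure, per-period fills and
  dynamics, so rosters and claims are bit-reproducible and `simulate_fills`
  called per period is consistent with the one-shot `simulate_study`.

### What a green test does and does not establish

The recovery suites show the *pipeline* is consistent: data generated under
a known effect, pushed through PDC, cohort filters and the estimators,
return that effect within Monte-Carlo error, and null data produce ~95%
CI coverage. They do not validate the generator against real claims —
refill-gap shapes, covariate–adherence correlation, wave effects and
physician-level clustering in real data are all outside the emulation.
Published *unadjusted* effects are reproduced exactly from the study's
printed counts; published *adjusted* effects cannot be recomputed without
the proprietary patient-level covariates and are covered only by the
estimator-identity and recovery properties.

## Numerical choices and degenerate inputs

* Threshold comparison is inclusive (`PDC ≥ 0.80` is adherent).
* Zero cells: crude RR returns estimate 0/∞/NaN with non-finite CI and no
  p, rather than applying a continuity correction.
* GLM non-convergence raises with iteration diagnostics; rank-deficient
  designs raise naming the collinear columns before fitting.
* Empty fill sets give 0 covered days (not an error); an empty cohort is an
  error for rate estimation.
* Fills dated on/after the window end are ignored with a warning.
* NNT is rounded to the nearest integer from the unrounded RD.

## Known limitations

* One pooled enrollment wave by default; the two-wave design of the
  emulated study is handled by running the pipeline per wave and pooling,
  not by per-patient wave assignment.
* The conditional pairwise transition estimator does not reproduce one
  published transition cell (nonadherent→nonadherent, antihypertensive:
  computed 1.11 vs printed 1.03) nor the published transition CIs; the
  source's estimator for those is unstated. These are flagged as documented
  discrepancies in the reproduction table.
* Whether the emulated study capped PDC before or after subclass averaging
  is unstated; here each subclass PDC is capped structurally (distinct-day
  counting), which is the only choice consistent with counting days.
* No medication-possession-ratio variant, dose-level adherence, switching
  episodes, physician-level random effects, or survival analysis.
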