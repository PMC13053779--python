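# Methods

This note documents the statistical model behind each pipeline stage, the
defaults and why they hold, what the synthetic generators do and do not
emulate, and the design choices made where the procedure was genuinely open.

## Dose delivery (ARM)

The automated radiation modulator exposes a 384-pillar plate to a fixed
radiation slit; dose is controlled purely by dwell time. The model is an
abstract constant-rate source — no transport physics, scatter, or dosimeter
response.

- **Calibration.** The dwell-vs-dose fit is constrained through the origin
  (zero dwell ⇒ zero dose, which is physically forced): unit time
  `u = Σ dᵢtᵢ / Σ dᵢ²` seconds per gray. The packaged device calibration
  (1 Gy → 51.59 s, 2 → 102.98, 4 → 205.96, 8 → 411.92) is internally slightly
  inconsistent — the 1-Gy point implies 51.59 s/Gy while the other three are
  exactly proportional at 51.49 s/Gy. Both are retained as printed and the
  origin-constrained fit reconciles them at u ≈ 51.4912 s/Gy. The implied
  beam rate is 60/51.59 ≈ 1.163 Gy/min.
- **Delivery simulation.** Open wells receive rate × dwell × (1 + ε),
  ε ~ N(0, noise_sd); wells under the shield mask are additionally scaled by
  the shield transmission. Transmission defaults to 1/6, back-derived from
  the ~6 Gy open-field vs ~1 Gy shielded measurements; it is configurable.
  Scheduling followed by noiseless simulation recovers the target map
  exactly (a tested round-trip identity).
- **Quality statistics.** CV uses the sample standard deviation (n−1); the
  convention is unstated upstream and n−1 is the field default. R² comes
  from the simple linear regression of delivered dose on dwell. The device's
  published CV of 0.096% and R² = 0.9931 rest on raw dosimeter readings that
  were never printed, so they are covered by property tests (CV → 0 and
  R² → 1 as noise → 0; simulated CV matches the injected noise level)
  rather than value reproduction.

## Viability quantification

Viable area is the number of pixels with green intensity **strictly**
greater than 20 on the 0–255 scale, counted per pillar tile or per 8-pillar
strip. 16-bit scans are rescaled to 0–255 before thresholding, since the
threshold is defined on an 8-bit scale. No background correction is applied
before thresholding. There is no segmentation or per-organoid analysis: the
readout is aggregate thresholded area only.

- **Growth rate** is 100·A₅/A₁ by default. The defining phrase for the assay
  is ambiguous between A₅/A₁ and (A₅−A₁)/A₁; the ratio convention is chosen
  because the reference cohort contains growth values below 100 (e.g. 73.6),
  most naturally read as a day-5 area at 73.6% of day 1. The increase
  convention is available via `convention="increase"`.
- **Per-dose viability** is 100 × treated/control, clamped below at 0 and
  deliberately *not* clamped above 100: organoids can keep growing under low
  dose, and the AUC stage handles >100% inputs. Cohort AUC values of exactly
  800 then correspond to viability pinned at 100% across all doses.

## Dose-response AUC

RT_AUC is the trapezoid-rule integral of viability over the 0/2/4/8 Gy
ladder (no sigmoid/4PL fitting — the published analysis integrates the
plotted viabilities directly). Dose labels are per-fraction (0–8 Gy), not
cumulative over the two irradiation days; the cohort's maximum of
800 = 100% × 8 Gy fixes the integration span.

The AUC standard error propagates independent per-dose replicate SEMs
through the trapezoid weights, SE = √Σ(wᵢ·SEMᵢ)², with w = (1, 2, 3, 2) on
the default ladder (endpoints half their adjacent gap, interior points half
the span of their neighbours). The upstream SE formula is unstated; this
propagation is a documented choice validated by its algebraic properties.

## Cohort standardization

Features are Z-scored as (transform(x) − m)/s with m, s (sample SD, n−1)
frozen on the reference cohort and applied unchanged to any external cohort.
Growth rate is standardized on the natural-log scale and RT_AUC on the raw
scale. This combination is the package's central derived decision: it is the
unique pairing that reproduces all 28 printed per-patient Z entries of the
reference table to 4 decimal places (raw-scale growth standardization cannot
simultaneously yield the printed values for patients with growth 258.5 and
417.9; population-SD variants fail the same check). The tests lock this in.

HPV is coded positive = 1, negative = 0, then standardized like any feature;
on the 9-positive/5-negative reference split this gives Z(positive) = 0.7182
and Z(negative) = −1.2928. Records with missing HPV are excluded from
HPV-bearing statistics and models (no imputation).

One known fixture inconsistency: the printed validation-set Z(growth) column
disagrees with frozen-statistics recomputation by up to 0.007 (e.g. printed
−0.188 vs computed −0.1914), apparently rounded from slightly different
intermediates upstream; the validation Z(AUC) column reproduces to 3
decimals. Tests assert the computed behaviour with the printed column as a
near-reference. The fixture's printed OncoSensi column is not reproducible
from either published coefficient set applied to the printed Z columns; it
is stored as annotation only and never consumed.

## The OncoSensi index

The index is the Z-scored linear predictor of a logistic regression of
1-year recurrence (1 = recurrence) on the standardized features, so the
scored reference cohort has index mean 0 and SD 1, and index > 0 reads as
above-average predicted recurrence risk. Because Z-scoring is a positive
affine map, any ranking-based statistic (ROC AUC in particular) is identical
for the index and the raw linear predictor.

- **Fitting.** IRLS (Newton–Raphson on the penalized log-likelihood) with an
  optional ridge penalty excluded from the intercept; default penalty 0.
  With 14 patients and 4 events, complete separation is a live risk: a
  diverging unpenalized fit (|η| > 30) raises a `SeparationError` and the
  caller retries with penalty 0.5 (the pipeline's `refit` mode does this
  automatically). On well-behaved data the fitter matches statsmodels'
  Logit to <1e-4 (tested).
- **Published models.** The two- and three-parameter published coefficient
  sets are packaged as fixed models whose *downstream scores* are validated;
  re-deriving the printed coefficients themselves is not attempted — the
  exact estimation settings behind them (software, penalty, convergence) are
  unknown, and the package treats them as given inputs. The source calls the
  same coefficients both "logistic" and "linear" regression; logistic is
  primary (outcomes are explicitly coded 0/1 to predict recurrence) and an
  OLS comparison fitter is provided.
- **Classification.** Index cutoff defaults to 0 (the cohort mean); the
  upstream cutoff is unstated, so it is configurable. Ties go to sensitive.
  The two-axis variant calls (Z_AUC > 0, Z_growth > 0) strongly resistant,
  both non-positive strongly sensitive, and mixed signs moderately
  resistant.

## Validation statistics

- **ROC AUC** is pairwise Mann–Whitney concordance — the probability a
  recurrent patient outscores a non-recurrent one, ties credited 0.5
  (computed via midranks; equal to the trapezoid area under the empirical
  ROC curve). The 0.5 tie credit is required for binary predictors such as
  HPV status. Covariates whose risk direction is a convention are
  auto-oriented so AUC ≥ 0.5, with the sign reported: for HPV,
  HPV-negative is the risk-increasing direction (HPV-positive disease is
  the more radiosensitive). No DeLong confidence intervals.
- **Kaplan–Meier / log-rank.** Standard product-limit estimator;
  one-year RFS is Ŝ(365). The log-rank test is the 1-d.f. observed-vs-
  expected chi-square with hypergeometric variance and an asymptotic
  p-value (no exact/permutation variant, matching conventional reporting).
  Both are cross-checked against lifelines on 100 random datasets to 1e-4
  in the tests. The published survival splits' grouping cutoffs are
  unstated; the packaged regression test uses the reproducible observation
  that the two-parameter model's top five patients form the resistant group,
  giving one-year RFS 2/5 vs 8/9.

## Synthetic data

The generators exist so every stage is testable offline with known ground
truth; they are study-condition emulators, not image-realism exercises.

- **Plate images.** One aggregate disc per pillar, radius set so the disc
  area equals (Poisson organoid count × 12 px) × growth^(day−1) × SF(dose),
  with SF the linear-quadratic survival exp(−αD − βD²) (α = 0.25/Gy,
  β = 0.03/Gy², growth 1.25/day — a monotone dose-dependent target with
  standard radiobiology knobs; the assay itself only measures areas).
  Foreground intensity 120, background 8 (straddling the threshold of 20),
  optional Gaussian intensity noise, 8-bit TIFF output, default 640×960 px
  (40-px tiles). The emitted ground truth is the *discretized* painted pixel
  count, so noiseless quantification reproduces it exactly; the continuous
  survival model holds up to pixel discretization (~0.5% at default sizes).
  Not emulated: organoid morphology, Matrigel domes, scanner optics, uneven
  illumination — so passing image tests demonstrates correctness of the
  counting arithmetic, not robustness to real-scanner artefacts.
- **Cohorts.** (log growth, AUC) drawn bivariate normal (defaults matching
  the reference cohort's moments: log-growth 5.16 ± 0.69, AUC 514 ± 140,
  clamped to [0, 800]), HPV Bernoulli(9/14); recurrence is Bernoulli on the
  logistic linear predictor over within-cohort Z-scores (default slopes
  1.3/1.4, intercept −1.3), and event times are exponential with hazard
  increasing in the linear predictor, truncated below the administrative
  censoring horizon (900 days) for recurrent cases — the simplest model
  supporting logistic parameter-recovery and KM/log-rank tests. Real
  cohorts' covariate non-normality and informative censoring are not
  modelled.

## Numerical and degenerate-input conventions

Sample SD (n−1) everywhere a spread is estimated. Strict `>` threshold in
pixel counting. Constant features, all-zero measurements, single-class
outcomes, zero-variance predictors, log of non-positive values, empty
survival groups and negative times all raise `ValueError` rather than
returning NaN; a diverging logistic fit raises `SeparationError`. Delivery
R² is undefined (NaN) for repeated measurements at a single dwell. The
pipeline report is serialized with sorted keys so identical config + seed
yields byte-identical JSON.

## Problem sizes in tests

The suite exercises the cohort path at the fixture's real size (n = 14 + 6),
parameter recovery at n = 2000, generator moment checks at n = 5000, and the
reference cross-checks on 100 random small datasets each; plate-image tests
render full 384-pillar plates at 640×960 px. The whole suite runs in well
under a minute on one CPU.
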