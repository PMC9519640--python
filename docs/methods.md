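# Methods

## Scoring rules

All three systems are deterministic functions of a structured CT-findings
record. Volumes are the largest single lesion of each type in cm³ (the
clinical measuring convention; thresholds are phrased per lesion type,
not cumulative), midline shift in mm.

* **Helsinki CT score.** Additive: SDH present +2, ICH/contusion present
  +2, EDH present −3 (lesion-type points add across coexisting types —
  required for the documented range −3…14 to be attainable), largest
  haematoma volume strictly > 25 cm³ +2, IVH +3, suprasellar cisterns
  normal/compressed/obliterated 0/+1/+5.
* **Marshall classification.** Any lesion > 25 cm³ dominates and splits
  into V (evacuated) / VI (not evacuated); otherwise shift > 5 mm → IV,
  compressed/absent basal cisterns → III, any visible pathology → II,
  normal CT → I. "Visible pathology" is read broadly — any nonzero lesion,
  SAH/IVH/DAI/fracture/pneumocephalus/Duret, nonzero shift, hydrocephalus,
  herniation, or non-normal suprasellar cisterns — because class I is
  defined by the *absence* of visible intracranial pathology.
* **NIRIS (updated definitions).** The highest category whose criteria
  are met. Two boundary choices close gaps in the printed criteria:
  a lesion of exactly 0.5 cm³ is category 2 (criteria then partition the
  volume axis), and shift bands are half-open — (0,5] → 2, (5,10] → 3,
  > 10 → 4 — since a 0-mm shift alone is "no abnormal finding". Only the
  revised criterion set is implemented (the original thresholds for the
  starred items are not published), and categories run 0–4 per the
  published criteria table.

Unknown or missing findings fields are rejected, not imputed, mirroring
the exclusion of patients with unusable CTs.

## Models

First-level customization refits only the logistic link of each score:
Marshall and NIRIS are dummy-coded over observed levels (reference
I / 0; levels absent from the data are dropped with a logged warning),
Helsinki enters as one numeric term. Treating NIRIS as saturated dummies
rather than a single ordinal slope is deliberate: only the saturated
model reproduces the published explained variation from the published
cross-tabulation, while the AUC is identical either way (any strictly
increasing transform of a 5-level predictor gives the same ranking). The
clinical base model is a plain ML logit of age, GCS, modified SAPS II
and chronic comorbidity, all untransformed; combined models append one
CT coding to it.

Fitting is hand-written IRLS: start at the event-rate intercept, stop
when the relative log-likelihood change is below 1e-10 (max 100
iterations). Separation is reported as an explicit error — raised when a
coefficient exceeds 30 in absolute value on the log-odds scale, or when
the likelihood is driven to within 1e-8 of its supremum of zero (perfect
prediction): in both cases the MLE is at infinity and estimates would be
meaningless. Weights are floored at 1e-10 for numerical stability; no
shrinkage or penalisation is applied. The fitter is cross-checked against
statsmodels in the test suite (coefficients, log-likelihood and standard
errors to ≤ 1e-6 / 1e-4).

A constant comorbidity flag is dropped from the base model with a warning
(it is merely collinear with the intercept); a constant CT score is an
error, since the model then has no CT information at all.

## Performance battery

* **AUC**: ties-corrected pairwise concordance
  `(concordant + 0.5·tied) / (n_ev · n_nonev)`, computed through DeLong
  placement values (so the point estimate and the variance share one code
  path); 95% CI is Wald on the AUC scale with the DeLong variance,
  truncated to [0, 1]. The CI method is a design choice consistent with
  using DeLong tests for comparisons.
* **DeLong test**: per-event and per-non-event placement values for both
  models, 2×2 covariance, two-sided normal p for the AUC difference.
  Two-sided is the conventional choice. Comparing nested models fitted on
  the same data (Base vs Base+CT) is anticonservative; it is reported
  anyway because that is the comparison the validation design makes, and
  the report should be read accordingly.
* **Nagelkerke R²**: `R²_CS = 1 − exp(2(LL₀ − LL₁)/n)` rescaled by its
  maximum `1 − exp(2·LL₀/n)`; misuse with LL₁ < LL₀ is an error.
* **Hosmer–Lemeshow**: quantile bins of predicted risk with ties assigned
  to the lower bin, `Σ (obs − exp)² / (exp(1 − exp/n_bin))`, df =
  groups − 2. Models with fewer distinct risk levels than groups (the
  few-category CT scores) are refused with an explanatory error and
  reported NA — fixed-width-bin variants are out of scope.
* **IDI**: the difference-of-discrimination-slopes estimate is computed
  from the four group means; the IS/IP integrals are computed as exact
  step-function sums over [0, 1] (no smoothing) and the two
  representations are required to agree to 1e-8 at run time. The default
  95% CI is the normal approximation on the per-patient differences
  `p_new − p_old` within events and within non-events; a seeded
  patient-level bootstrap (2000 replicates) is available as an option.
* **Cross-tab chi-square**: Pearson, no continuity correction (scipy).

Full precision is kept internally; the reporting layer rounds to the
conventional display precision (AUC 2 dp, R²/IDI 3 dp).

## Synthetic cohort generator

The generator emulates the published marginal structure of the source
ICU cohort; patient-level registry data are unavailable. Calibrated
defaults (all overridable through `CohortParams`):

| parameter | default | source / rationale |
|---|---|---|
| `n` | 3031 | published cohort size |
| `niris_probs` | (320, 225, 1297, 526, 663)/3031 | published category counts (exact fractions, not the rounded percentages, so they sum to 1) |
| `mortality_by_category` | (27/320, 12/225, 220/1297, 142/526, 309/663) | published category-conditional deaths |
| `age_location_by_category` | (38, 43, 54, 59, 60) yr | published medians; log-normal spread per category derived from the published IQRs |
| `gcs_band_probs_by_category` | published 3-band counts | GCS 3–8 / 9–12 / 13–15 frequencies per category |
| `comorbidity_prob` | 252/3031 | published prevalence |
| `saps2_effect` | 12 SAPS-II points per severity SD | calibrated (below) |
| `severity_logit_coef` | 2.8 log-odds per severity SD | calibrated (below) |

Each patient gets a NIRIS category (from `niris_probs`) and an
independent latent severity `z ~ N(0,1)`. Findings are sampled to score
*exactly* to the drawn category — at least one criterion of the target
category and none of any higher one, asserted per draw — with continuous
magnitudes tilted upward in `z`. Mortality is Bernoulli with
`expit(α_c + γ·z)`, where the per-category intercepts `α_c` are solved by
Gauss–Hermite quadrature + Brent root-finding so the *expected*
category-conditional death rate equals the configured one for any `γ`;
consequently the NIRIS model's large-sample AUC on generated data matches
the value implied by the published cross-tabulation regardless of the
latent-severity strength. The modified SAPS II is
`max(0, 16 + saps2_effect·z + N(0, 5²))`, rounded to an integer; GCS is
drawn by band from the category-conditional frequencies, with the integer
within the band decreasing in `z`.

The two latent couplings were calibrated once, jointly: `γ = 2.8` and
`saps2_effect = 12` put the base model's AUC near the published 0.86 on
large cohorts, and the within-category severity signal is loaded mainly
on the findings the Helsinki score sees distinctively — suprasellar
cistern status and IVH — and only weakly on basal cisterns and shift.
The clinical reading is that evolving transtentorial mass effect
(suprasellar effacement) and ventricular blood are the outcome-laden
findings within a NIRIS stratum; the statistical consequence is that the
generator reproduces the published discrimination ordering
(Helsinki > NIRIS ≈ Marshall ≪ base model).

What the generator does **not** emulate — and what passing tests
therefore do not show about real data:

* the clinical–radiological information *overlap*: latent severity is
  independent of category, so CT category carries mortality information
  the clinical covariates lack, and combined models improve on the base
  model far more here (ΔAUC ≈ +0.04…0.06) than the published +0.01.
  Property checks on combined models are accordingly about ordering and
  contract, never about the size of the increment;
* calibration-in-the-small of the Helsinki linear logit (true risk is
  category-plus-severity, not exactly linear in the score), so its
  Hosmer–Lemeshow p on synthetic data is not meaningful as a check of the
  published value;
* Marshall/Helsinki marginals: they arise implicitly from the sampled
  findings; agreement with the published NIRIS-by-Marshall concordance is
  checked qualitatively (diagonal dominance), not fitted;
* ICU processes (length of stay, ICU/hospital death, interventions):
  carried only as printed-table fixture columns, not modelled.

Determinism: one `numpy` Generator seeded from `CohortParams.seed` drives
every draw in a fixed order, so identical parameters give byte-identical
cohort tables.

## Printed-table fixtures

The published category-by-outcome and category-by-Marshall tables are
shipped as constants and as regenerable CSVs (`tbict fixtures`).
`expand_crosstab` turns the outcome table into 3031 patient rows, each
carrying a canonical synthetic findings value for its category. On such
an expansion the pipeline computes the NIRIS row exactly (AUC 0.70,
R² 0.147 at printed precision) and reports NA for every row it cannot
compute honestly: base/combined models (no patient-level covariates in a
printed table) and Marshall/Helsinki (the representative findings carry
no information beyond the NIRIS category, so their "scores" would be
relabelings of it).

## Problem sizes in the test suite

Simulation-based checks use sizes chosen to bound Monte-Carlo error well
below the asserted tolerances while keeping the default suite fast:
calibration recovery at n = 50 000 (binomial SE ≤ 0.004 per category
against a ±0.01 band), AUC-ordering medians over 25 cohorts of n = 3031,
Hosmer–Lemeshow type-I error over 1000 replicates of n = 2000 (SE of the
rate ≈ 0.007 against a [0.03, 0.07] band), likelihood-ratio null
distribution over 400 permutations, and coefficient recovery over 200
replicates of n = 20 000.

## Known limitations

* The Helsinki/Marshall/base-model published point values (AUC 0.73 /
  0.68 / 0.86, the published HL p-values and IDIs of 0.011–0.028) depend
  on the unavailable patient-level registry and cannot be reproduced
  exactly; they are covered by the property battery instead.
* NIRIS herniation criteria distinguish only none/focal/diffuse; mixed or
  uncertain herniation patterns must be mapped by the data preparer.
* The scorer consumes structured findings; image reading (DICOM →
  findings) and inter-rater variability are out of scope, as are the
  Rotterdam and Stockholm CT scores and functional-outcome endpoints.
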