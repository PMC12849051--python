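# Methods

## Problem and design

The package evaluates candidate triage tests for ovarian cancer in
premenopausal women referred to secondary care.  Each index test is
dichotomised at its clinically used thresholds and cross-classified against
a composite reference standard (histology from surgery, biopsy or cytology;
12-month surveillance for conservatively managed women).  All tests are
compared pairwise against a fixed comparator (RMI 1 at 250, the NHS standard
of care) in a paired design: every participant contributes to both tests, so
differences in sensitivity and specificity are assessed on discordant pairs.

## Outcome definitions

Three binary outcome definitions partition the histology categories:

* **primary** — primary invasive cancer vs benign/normal (or negative
  surveillance).  Borderline tumours, secondary metastatic cancers,
  neoplasms of uncertain behaviour and unresolved reference standards are
  excluded, because they are neither the target condition nor clearly
  disease-free.
* **secondary_any_cancer** — any of {primary invasive, secondary metastatic,
  borderline, uncertain behaviour} vs everything else.  Unresolved records
  count as negative so every participant contributes.
* **secondary_borderline_as_benign** — as above but with borderline grouped
  with benign.

Surveillance resolution: a completed negative 12-month follow-up is a
negative under every definition.  A cancer detected at follow-up without
confirmatory histology cannot be attributed to the ovary and is excluded
under the primary definition (positive under the any-cancer definitions).
Inconclusive cytology is treated as an unresolved (excluded) reference
standard.  FIGO stage is metadata only and never affects labels.

## Menopausal classification

Women are classified by age (<50 vs ≥51) and menstruation in the past 12
months; the perimenopausal band (ages 50–51, unknown menstruation, or
age/menstruation disagreement) is re-categorised by self-reported vaginal
bleeding history: bleeding within 12 months → premenopausal, otherwise
postmenopausal.  The exact cutoffs of the band are a package choice (the
re-categorisation is described in the source analysis without numeric
bounds); the rule table is documented in `classify_menopause` and
exhaustively tested.

## Scorers

Scorers never impute: any missing required predictor yields a
`missing_inputs` result, and missing results are excluded from 2×2 cells.
Dichotomisation is strictly greater-than (a score exactly at the threshold
is negative, matching the `>t` / `<t` row labelling convention of the
published table).  ADNEX's proportion of solid tissue is
`max_solid_diameter / max_lesion_diameter`, clipped to [0, 1] with a warning.
ADNEX with missing CA 125 returns a missing result by default (the
evaluation computed ADNEX from measured CA 125); the CA125-free variant of
the model is available as a policy option.  Natural logarithms are used for
all marker and diameter transforms.

Coefficients are versioned JSON artifacts.  The ROMA predictive indices are
transcribed from the original publication (premenopausal
PI = −12.0 + 2.38·ln HE4 + 0.0626·ln CA125; postmenopausal
PI = −8.09 + 1.04·ln HE4 + 0.732·ln CA125).  The ADNEX and simple-rules-risk
files preserve the published functional forms but carry plausible-magnitude
**synthetic** values (clearly labelled in `version_label` and
`source_citation`): the original numeric coefficients are not reprinted in
the accuracy study and could not be verified here.  All unit tests use
synthetic coefficient sets with known algebra, so the statistical machinery
is correct independent of any particular coefficient file.  The ORADS
mapping is an ordered, documented rule list marked approximate.

## Accuracy statistics

* Proportions use exact Clopper–Pearson 95% CIs by default (Wilson
  available).  This choice was validated by exact replication of the
  published table's intervals (e.g. 20/47 → 28.3–57.8).
* Paired deltas (comparator minus test, on the common conclusive subset) use
  the exact two-sided binomial McNemar test,
  p = min(1, 2·P(X ≤ min(b,c) | b+c, ½)), and a Wald paired-difference CI
  **with** continuity correction 1/n.  The correction is on by default
  because it reproduces the published asymptotic intervals exactly
  (−6.4 [−15.5, 2.7] and 1.1 [0.1, 2.1] for RMI-200 vs RMI-250); it is
  configurable.
* Bonferroni: α = 0.005 for an 11-comparison family (the published rounding
  of 0.05/11), 0.05/n otherwise.
* Inconclusive simple-rules results are excluded from cells by default;
  count-as-positive / count-as-negative policies exist for sensitivity
  analyses only.
* Report percentages are formatted at 1 decimal, rounding half up.

A known inconsistency in the published table: the ROMA row at the 12.5%
threshold prints 164 + 358 = 522 controls against a 702-control margin.  The
printed specificity/PPV/NPV are consistent with the printed counts
(358/522, 37/201, 358/369), so the replication — which works from counts —
reproduces them; the marginal discrepancy is noted, not repaired.

## Discrimination and calibration

The C-index is the midrank Mann–Whitney statistic (ties ½) with a DeLong
structural-components variance; it equals the trapezoidal ROC area to
1e-12 (property-tested against an O(n²) pair-counting oracle).  Calibration
deciles keep tied risks in one group (merged quantile edges), falling back
to quintiles below n=10.  The calibration slope is the coefficient of a
logistic regression of the outcome on logit(risk), risks clipped at 1e-6;
calibration-in-the-large is the intercept of the same regression with the
slope fixed at 1 via an offset.  The slope measures spread
(slope < 1 = predictions too extreme), the intercept direction
(negative = overprediction on average); the two are reported separately
because conflating them invites the over/underprediction ambiguity found in
some figure captions.

## Multiple imputation

Chained equations via statsmodels' MICE engine with predictive mean matching
(defaults m=10, 10 cycles, k=5 donors — the source analysis names the method
but not its settings).  Markers are imputed on the log scale by callers;
derived scores are recomputed per completed dataset, never imputed directly.
Imputation never alters observed cells (asserted at run time) and is
reproducible from a seed.  Accuracy proportions are pooled on the logit
scale with Rubin's rules (total variance = within + (1+1/m)·between,
Barnard–Rubin degrees of freedom), with a 0.5 continuity adjustment for
boundary proportions (flagged).

## Synthetic cohort

The generator states the evaluated world once: 857 pre-protocol-change women
at 5.7% prevalence (mixed surgical/surveillance reference standard) and 354
post-change women at 11.0% (surgery only); ~7% of non-cancer participants
carry reference classes excluded from the primary outcome.  Markers are
class-conditional correlated log-normals chosen so CA 125 > 87 IU/mL lands
near 55% sensitivity / 89% specificity; ultrasound B/M patterns are tuned
once so the simple-rules classifier returns ≈15% inconclusive results
overall (≈31% among cancers); missingness is MAR-on-class with ultrasound
missing far more often among controls (0.16 vs 0.04), emulating
surveillance-managed women who skipped the study scan.  These are emulation
targets, not estimates, and they were frozen before the test suite was run.
A single seed feeds per-stage substreams (demographics, class, markers,
ultrasound, reference, missingness), so adding a stage never perturbs
earlier draws.

What a green synthetic test does *not* establish: the generator draws
features independently within class (no centre clustering, no
symptom/referral structure, no spectrum drift between cohorts beyond
prevalence), so absolute accuracy values on synthetic data — and anything
downstream of the synthetic ADNEX/sRRisk coefficient stand-ins — are not
estimates of the real cohort's values.  The published real-cohort C-index
and calibration results are not recomputable without the individual-level
data; the package instead proves its discrimination/calibration machinery by
oracle equivalence and parameter-recovery simulations with known truth.

## Known limitations

* ADNEX and simple-rules-risk coefficient files are synthetic
  approximations (swappable artifacts, clearly labelled).
* The ORADS mapping is an approximate reconstruction of a lexicon-mapping
  methodology, not a validated table.
* MICE uses PMM for binary features rather than fully Bayesian logistic
  conditionals; no MNAR or multilevel imputation.
* No decision-curve analysis and no likelihood ratios.
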