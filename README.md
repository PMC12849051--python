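# ovarisk

Head-to-head diagnostic accuracy of ovarian cancer risk prediction models in
premenopausal women.

Premenopausal women referred to secondary care with non-specific symptoms and
a raised CA 125 or an abnormal ultrasound have a low (~6%) prevalence of
ovarian cancer, and the standard NHS triage test — the Risk of Malignancy
Index 1 at a threshold of 250 — misses more than half of cancers.  This
package implements the full comparative accuracy analysis used to evaluate
replacement tests: it scores the six candidate index tests, derives outcome
labels from a surgical/surveillance reference standard, and compares every
test against the comparator with paired exact statistics.  It is written for
biostatisticians and clinical epidemiologists working on diagnostic test
evaluation, and is usable entirely from Python (no CLI); see `examples/`.

## Models implemented

* **RMI 1** — `U x M x CA125`, with the ultrasound U-score (0/1/3 from
  multilocular cysts, solid areas, metastases, ascites, bilateral lesions)
  and menopausal multiplier M (1 pre, 3 post); thresholds 200 and 250.
* **ROMA** — menopause-stratified logistic predictive index
  `PI = β₀ + β₁·ln(HE4) + β₂·ln(CA125)`, reported as `100·expit(PI)` %;
  thresholds 7.4, 11.4, 12.5, 13.1%.
* **IOTA simple rules** — ternary classifier from five benign (B1–B5) and
  five malignant (M1–M5) ultrasound features; mixed or absent features give
  an inconclusive result.
* **IOTA simple rules risk** — logistic model on the ten B/M indicators plus
  centre type; thresholds 3% and 10%.
* **IOTA ADNEX** — multinomial logistic model over {benign, borderline,
  stage 1, stage 2–4, secondary metastatic}; total malignancy risk
  `100·(1 − P(benign))`, thresholds 3% and 10%.
* **CA 125** alone at 87 IU/mL, and a post hoc **ORADS** lexicon mapping
  (categories 1–5, positive at 4–5).

ADNEX and simple-rules-risk coefficient files shipped here are labelled
synthetic approximations of the published models (the accuracy analysis this
package replicates does not reprint them); they are versioned JSON artifacts
and can be swapped for faithful transcriptions without code changes.

## Statistics

2×2 tables are built per test/threshold/outcome with explicit policies for
missing and inconclusive results (inconclusives are excluded by default,
never counted positive).  Sensitivity, specificity, PPV and NPV carry exact
Clopper–Pearson 95% CIs.  Paired comparisons use the exact McNemar test on
discordant pairs within cases and within controls, with Wald
paired-difference CIs (continuity-corrected) and Bonferroni adjustment
(α = 0.005 for the 11-comparison family).  Discrimination is the C-index
with a DeLong CI; calibration is a decile table, the logistic recalibration
slope, and calibration-in-the-large.  Missing predictors can be multiply
imputed by chained equations with Rubin-rules pooling on the logit scale.

## Worked example

```python
from ovarisk import replicate_printed_table
diff, pairwise, mismatches = replicate_printed_table()
print(len(mismatches))                       # 0
print(diff.loc["rmi1@250", "sens_computed"]) # 42.6
print(pairwise["delta_sensitivity"])         # {'computed': -6.4, 'printed': -6.4}
```

`replicate_printed_table` recomputes every derivable cell of the published
cohort-1 accuracy table from its printed classification counts: RMI 1 at 250
has sensitivity 42.6% (95% CI 28.3 to 57.8) and specificity 96.5%, while
ADNEX at 10% reaches sensitivity 89.1% at specificity 75.1% — the
sensitivity/specificity trade-off that motivates replacing RMI triage.  The
paired RMI-200-vs-250 sensitivity difference is −6.4 percentage points
(−15.5 to 2.7, exact McNemar P=0.25) on the common n=672.  Zero mismatches
means the package's CI and McNemar machinery reproduces the published table
cell for cell.

`examples/02_synthetic_head_to_head.py` runs the same analysis end to end on
a generated cohort (857 + 354 women, prevalences 5.7%/11.0%) and prints the
full comparison table.

## Acceptance script

```
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

re-runs the printed-table replication (failing loudly on any mismatch) and
the full synthetic pipeline — generate, score, evaluate both outcome
definitions — from the given seed, then writes the results manifest to
`--out`.
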