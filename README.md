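# fairshift

Fairness auditing of clinical prediction model grids under distribution
shift.

Clinical image classifiers can encode demographic attributes (age, sex,
race) in their learned representations and use them as *shortcuts*: the
attribute correlates with the label in the training data, so relying on it
helps in-distribution (ID) performance while producing group-dependent
error rates — and the reliance backfires when the model is deployed in an
environment where the correlation has shifted.  `fairshift` is the audit
toolkit for this problem.  It is written for teams who have a *grid* of
candidate models (algorithms x hyperparameters x seeds), per-sample
prediction tables and frozen embeddings for each, and who need to decide —
using only ID data — which model will stay fair out of distribution (OOD).

## What it measures

For a binary task with score `f(x)`, label `Y`, demographic attribute `A`
and environments `D_src` (ID) and `D_tar` (OOD):

* **Equal-opportunity gaps** — the signed difference between two designated
  groups in one class-conditioned error rate: the FPR gap for a
  healthy-indicator task, the FNR gap for a disease-indicator task
  (underdiagnosis polarity; the overdiagnosis mirror is a flag).  Rates use
  the F1-maximizing threshold chosen on the pooled evaluation set; CIs come
  from a percentile bootstrap over sample rows.  Per-group AUROC and
  expected calibration error (ECE) are reported alongside.
* **Distribution shift** — ID: prevalence shift `P(Y|A)` via total-variation
  distance with a two-proportion z-test, and representation shift `P(X|A)`
  via the unbiased squared maximum mean discrepancy (MMD, RBF kernel,
  median-heuristic bandwidth) with a permutation test.  OOD: label shift
  `P(Y)`, covariate shift `P(X)` and their per-group conditionals between
  environments.  Bonferroni correction within each report.
* **Attribute encoding** — a multinomial logistic probe on frozen
  embeddings, L2 strength swept over `1e-5 .. 10` and selected by validation
  macro-AUROC; the test-set macro-AUROC (and argmax accuracy) quantifies how
  much demographic information the representation carries.
* **The OOD gap decomposition** — the exact identity

  ```
  L(g1,tar) - L(g2,tar) = [L(g1,src) - L(g2,src)]   (ID gap)
                        + [L(g2,src) - L(g2,tar)]   (shift impact on g2)
                        - [L(g1,src) - L(g1,tar)]   (shift impact on g1)
  ```

  for any per-sample-decomposable rate L (FPR, FNR), attributing an unfair
  deployment to the gap the model had at home versus the shift hitting one
  group harder.
* **Grid-level analyses** — fairness-performance Pareto fronts,
  performance-constrained fairness optima, the Pearson correlation (with
  Fisher-z CI) between attribute encoding and fairness gap, and ID-vs-OOD
  transfer correlations of performance and fairness.
* **Fairness-aware model selection** — eight ID-computable selection
  criteria (minimum ID gap, minimum attribute-probe AUROC/accuracy, maximum
  overall / worst-group AUROC, calibration criteria) evaluated by their
  *oracle regret*: the increase in OOD fairness gap over the model an
  OOD-observing oracle would pick, aggregated across settings with a
  bootstrap and compared pairwise by one-tailed Wilcoxon rank-sum tests.

A seeded synthetic cohort generator (`fairshift.synthetic_cohort`) produces
model grids with known Gaussian ground truth — group-conditional prevalence
`P(Y|A)`, attribute separation in representation space, models with a
tunable shortcut-reliance angle — so every statistic in the package can be
checked against closed forms, and the full pipeline can be exercised end to
end without any clinical data.

## Worked example

Generate the shipped two-environment study S2 (a 24-model grid whose
shortcut geometry flips between source and target) and evaluate selection
criteria against the OOD oracle:

```
$ fairshift simulate --scenario S2 --out demo/grid
wrote grid of 24 models to demo/grid

$ fairshift select --grid demo/grid --n-boot 1000 --out demo/select.json
  0.0000  Minimum Fairness Gap
  0.0000  Minimum Worst-Group Error Rate
  0.0275  Minimum Attribute Prediction AUROC
  0.0275  Minimum Attribute Prediction Accuracy
  0.0275  Maximum Worst-Group AUROC
  0.0954  Maximum Overall AUROC
  0.1994  Minimum ECE Gap
  0.2016  Minimum Overall ECE
```

Each line is a criterion's mean oracle regret — the average extra OOD
fairness gap (absolute, on the [0, 1] rate scale) incurred by selecting on
that ID quantity instead of observing the OOD data.  Here selecting on raw
overall AUROC costs ~9.5 points of OOD gap relative to the oracle, while
fairness- and encoding-aware criteria stay within ~3 points.

Decomposing one strong-shortcut model's OOD gap:

```
$ fairshift decompose --grid demo/grid --attribute group \
    --tar-env target --out demo/decomp.json
```

yields, for model `m20` (JSON fields, rates on [0, 1]):

```
term_ood_gap  -0.3047   = term_id_gap  +0.5049
                        + term_shift_g2 -0.3806
                        - term_shift_g1 +0.4291     (residual 0.0)
```

— the model's large ID gap is not merely preserved OOD, it *reverses*,
because the distribution shift moves the two groups' error rates in
opposite directions.  The other subcommands (`audit`, `shift-test`,
`probe`, `pareto`) emit the per-group tables, shift tests, encoding scores
and Pareto fronts the same way; `fairshift <cmd> --help` lists options.

Prediction tables are plain delimited text (`sample_id, score, label,
split, environment, task` + one column per attribute); embeddings are
delimited text or a documented float64 binary; all reports are JSON with a
config echo and seeds, so real model grids can be audited by writing those
files and skipping `simulate`.

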