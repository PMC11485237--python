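# Methods

This note documents the statistical procedures `fairshift` implements, the
synthetic data model used to validate them, the numerical conventions that
make results bit-reproducible, and the design choices made where more than
one reasonable convention exists.

## Metrics and conventions

**Decision rule.** A score is called positive iff `score >= t` (closed on
the left).  The default threshold policy is the F1-maximizing threshold:
candidates are exactly the unique observed scores, ties on F1 break toward
the smallest threshold.  One threshold is chosen per (model, task,
environment) on the pooled evaluation set and shared by all groups, so
groups are compared at a common operating point; re-tuning per group would
conflate threshold choice with the error-rate gap being audited.

**Rates.** TPR = TP/(TP+FN), TNR = TN/(TN+FP), with FNR and FPR their
complements.  A rate whose conditioning class is empty is *undefined* and
propagates as a NaN marker (serialized as `null`), never silently as zero —
small subgroups must surface as missing evidence, not as perfect scores.
AUROC is the Mann-Whitney statistic (ties count one half).

**Gap polarity.** The audited gap is the FPR gap for a healthy-indicator
task and the FNR gap for a disease-indicator task: on a screening task the
costly error is falsely clearing a sick patient, which appears as a false
positive of "healthy" and a false negative of "disease".  The overdiagnosis
mirror (swap the rate) is available by flag; the two obey no fixed
relation, so both can be reported.  Gaps are signed as group_1 minus
group_2 with explicit group names in every report; Pareto and regret
analyses use the absolute gap (a front cannot mix signs), signed values are
retained everywhere else.

**ECE.** Ten equal-width bins on [0, 1] by default (configurable), final
bin right-closed; bin confidence is the *mean score* in the bin, not the
midpoint.  ECE = sum over bins of (bin weight) x |mean score - empirical
positive rate|.

**Bootstrap.** Percentile intervals throughout, resampling the natural unit
with replacement: sample rows for gap CIs (1,000 draws by default, alpha =
0.05), evaluation settings for selection regrets.  A gap resample in which
either group's conditioning class is empty is redrawn and counted.
Coverage of the percentile interval for a mean at n = 100 is verified at
94-95% empirically (acceptance suite).

## Shift testing

ID-setting tests compare demographic groups within one environment;
OOD-setting tests compare a source and a target environment, marginally and
conditioned on each group.  Binary outcome distributions are compared by
total-variation distance (|p1 - p2| for Bernoulli) with the pooled
two-proportion z-test, no continuity correction (Fisher's exact test by
flag).  Representation distributions are compared by the *unbiased* squared
MMD estimator with an RBF kernel whose bandwidth is the median of pooled
pairwise distances; the estimator may be slightly negative and is reported
as-is.  Significance comes from a label-permutation test with the add-one
rule p = (1 + #{permuted >= observed}) / (1 + n_perm), n_perm = 1,000 by
default, each side subsampled to at most 2,000 points (seeded) to bound the
quadratic kernel cost.  The Bonferroni family is all tests within one
emitted report (one dataset pair / attribute / task call) — the multiplicity
unit a reader of that report sees; this convention is deliberate and
documented because no universal family exists.

## Encoding probe

A multinomial logistic regression (lbfgs, 1,000 iterations) on frozen
embedding vectors predicts the group label.  Features are standardized with
train-split mean/SD so a single L2 grid is comparable across embedding
scales; the grid is 7 log-spaced strengths over [1e-5, 10], selected by
macro-averaged one-vs-rest AUROC on the validation split; the reported
encoding measure is the test-split macro AUROC.  Argmax accuracy on the
same split supports accuracy-based selection criteria.  Non-convergence
sets a flag rather than failing.  For a binary attribute, macro AUROC
equals the plain AUROC of the positive-class probability.

## Gap decomposition

For any metric that is an average of a per-sample loss over a group's
conditioning class, the OOD gap decomposes exactly into the ID gap plus the
difference of the per-group shift impacts (see README for the identity).
The decomposition is algebra, not estimation: the residual is reported and
checked below 1e-12 on 1,000 random instances.  The threshold is fixed on
the source environment and reused on the target, so the deployed decision
rule is literally the same model in both domains (a deployed operating
point does not re-tune itself); a re-tune-on-target flag exists for
sensitivity analysis.  Group orientation is explicit: g1 is the first-named
group of the configured pair.

## Model selection evaluation

Candidates are first filtered to those with ID validation AUROC at least
95% of the best reference-algorithm model's (relative reading of a "within
5% of the best" rule; an absolute-margin variant is a flag).  Criterion
scores are computed on ID validation data only; OOD gaps on the target test
split with the threshold re-resolved per environment, mirroring per-dataset
threshold selection.  The oracle picks the minimum *absolute* OOD gap.
Ties anywhere break toward higher ID overall AUROC, then lexical model id,
so selection is deterministic.  Regret = chosen gap - oracle gap >= 0 by
construction.  The shipped registry holds eight criteria; it is
configuration, not a fixed claim — criteria are (name, direction, score
key) triples over the ID score table.  Pairwise criterion comparisons use a
one-tailed Wilcoxon rank-sum test: exact enumeration of all rank
assignments for combined n <= 12 (midranks make ties exact), normal
approximation with tie and continuity correction otherwise.

## Synthetic cohort model

The generator draws, per environment e: group A ~ Categorical(pi_e),
outcome Y|A=a ~ Bernoulli(rho_ea), and representation

    z = Y beta_y u + kappa_e c_a v + eps,   eps ~ N(0, sigma^2 I_d)

with orthonormal disease axis u and attribute axis v, c_a = +-1 for binary
groups (evenly spaced means for more groups).  Defaults d = 16, beta_y =
1.5, sigma = 1 give overall AUROCs around 0.85, a realistic operating
regime for imaging classifiers.  A synthetic model scores along w =
cos(theta) u + sin(theta) v through a logistic link (gamma = 2, intercept
-0.75): theta = 0 ignores the attribute — and therefore has zero
error-rate gap in every environment, the no-shortcut control — while larger
theta trades disease signal for the shortcut.  Because w.z given (Y, A) is
Gaussian, per-group FPR/FNR have Phi closed forms that serve as the binding
oracle for the empirical pipeline (verified within 3 Monte-Carlo SE at n =
20,000 across a theta x kappa sweep).

Each model emits a 2-D embedding [w.z, eta (v.z)] plus N(0, 0.5^2) noise.
The noise floor is deliberate: rescaling a feature changes no information,
so without a nuisance floor any eta > 0 would be equally detectable; with
it, probe AUROC grades smoothly in eta (chance at eta = 0, near-perfect
under strong separation, strictly monotone between).

Shipped studies (all parameters and seeds fixed in
`synthetic_cohort.canned_scenarios`):

* **S1** — one environment, unequal group prevalence (0.15 vs 0.45), kappa
  = 1, 24 models jointly sweeping (theta, eta = 1.5 sin theta): attribute
  encoding and fairness gap rise together, giving the encoding-unfairness
  correlation (r ~ 0.8 above the 0.7 performance floor).
* **S2** — source with an informative shortcut (prevalence 0.1 vs 0.5,
  kappa = 0.8), target with prevalences reversed and kappa = -0.5: overall
  performance transfers (r ~ 0.99) while the signed gap anti-transfers
  (r ~ -0.97), ID-Pareto models drop off the OOD front, and strong-shortcut
  models' gaps reverse sign OOD with large per-group shift impacts.
* **S3** — S2's source plus twelve target environments crossing kappa in
  {-0.8, -0.5, 0.5, 0.8} with three prevalence configurations; the zoo has
  exactly one shortcut-free model (theta = 0) among 24.  Selection on
  minimum probe AUROC reliably finds it; its regret is no worse than the
  minimum-ID-gap criterion's in every run (the two coincide when the ID gap
  estimate is clean, and the probe wins when it is not), while raw-AUROC and
  calibration criteria incur order-of-magnitude larger regrets.

Sample sizes (ID: 2,000 train / 1,000-1,500 val / 2,000 test; OOD: 1,500-
2,000 test per environment) were chosen so binomial noise on a rate is ~1-2
points — small against the constructed effects — while the full pipeline,
including simulation, probing, shift tests and selection, runs in a few
minutes on one CPU.

**What the generator does not emulate.** Real grids violate several of its
idealizations: embeddings are high-dimensional and non-Gaussian; shortcut
reliance is not one scalar angle; per-patient image multiplicity and view
heterogeneity break row i.i.d.-ness (rows are treated as i.i.d.; grouping
is the caller's responsibility); label noise and attribute misclassification
are absent; and environments differ in more than (pi, rho, kappa).  Passing
tests therefore certify the *statistical machinery* — estimators match
closed forms and oracles, tests hold their level, identities hold, and the
pipeline's qualitative conclusions follow from the constructed ground truth
— not that any particular clinical grid will show the same effect sizes.

## Degenerate inputs and edge cases

Single-class AUROC, empty conditioning classes and all-tie score vectors
yield undefined markers; an empty decomposition cell is an error naming the
cell; an infeasible performance constraint reports the best available
performance; a probe facing a single class, or a test class unseen in
training, errors out.  All randomized operations take an explicit seed
(numpy Generator); the CLI's global `--seed` defaults to 0 and is recorded
in every report's provenance block.

## Known limitations

Thresholds are F1-optimal by default, which couples the audited rates to
class balance; threshold-free fairness measures are out of scope.  The MMD
permutation test subsample cap trades power for bounded cost on very large
embedding sets.  The Wilcoxon normal approximation is used above combined
n = 12 even though regret distributions can be heavily tied; exact
enumeration covers the small-n regime where ties matter most.  The
selection evaluation treats settings as exchangeable units in the
bootstrap, ignoring correlation between settings that share an OOD
environment.
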