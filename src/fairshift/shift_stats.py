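"""Quantifying and testing distribution shifts within and across environments.

Within one environment (the ID setting) the audit compares demographic
groups: prevalence shift P(Y|A) via the total-variation distance between the
two Bernoulli outcome distributions, tested with a two-sample binomial
proportion test; representation shift P(X|A) via the squared maximum mean
discrepancy (MMD) between embedding clouds, tested by permutation.

Across environments (the OOD setting, null P_ID(.) = P_OOD(.)) the same two
machines compare source against target: marginally (label shift P(Y),
covariate shift P(X)) and conditioned on each group (prevalence shift
P(Y|A=a), representation shift P(X|A=a)).

All p-values within one emitted report are Bonferroni-adjusted together;
that report-level family is the multiplicity unit.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist, pdist
from scipy.stats import fisher_exact
from statsmodels.stats.proportion import proportions_ztest

from .grid_store import EmbeddingSet, PredictionSet, ValidationError

logger = logging.getLogger("fairshift")


@dataclass
class ShiftReport:
    """One tested shift: a distance plus raw and adjusted p-values."""

    setting: str              # "ID" or "OOD"
    kind: str                 # "prevalence" | "representation" | "label" | "covariate"
    comparison: str           # "a1-vs-a2" or "src-vs-tar[|group]"
    distance: float           # d_TV or squared d_MMD
    p_value: float
    p_adjusted: float = float("nan")
    n_1: int = 0
    n_2: int = 0


# ---------------------------------------------------------------------------
# total variation + proportion test
# ---------------------------------------------------------------------------

def tv_distance_binary(p1: float, p2: float) -> float:
    """Total-variation distance between two Bernoulli distributions: |p1 - p2|."""
    if not (0.0 <= p1 <= 1.0 and 0.0 <= p2 <= 1.0):
        raise ValidationError(f"proportions must be in [0,1], got {p1}, {p2}")
    return abs(p1 - p2)


def binomial_proportion_test(k1: int, n1: int, k2: int, n2: int,
                             exact: bool = False) -> float:
    """Two-sided test of equal success probability in two binomial samples.

    Default is the pooled two-proportion z-test without continuity
    correction; ``exact=True`` switches to Fisher's exact test.
    """
    if n1 < 1 or n2 < 1:
        raise ValidationError("binomial_proportion_test: both sample sizes must be >= 1")
    if not (0 <= k1 <= n1 and 0 <= k2 <= n2):
        raise ValidationError("binomial_proportion_test: counts out of range")
    if exact:
        table = [[k1, n1 - k1], [k2, n2 - k2]]
        return float(fisher_exact(table, alternative="two-sided")[1])
    if k1 + k2 == 0 or k1 + k2 == n1 + n2:
        return 1.0  # pooled variance zero and proportions equal at 0 or 1
    _, p = proportions_ztest([k1, k2], [n1, n2], alternative="two-sided")
    return float(p)


# ---------------------------------------------------------------------------
# MMD + permutation test
# ---------------------------------------------------------------------------

def median_heuristic_bandwidth(x1: np.ndarray, x2: np.ndarray) -> float:
    """RBF bandwidth: median of pooled pairwise Euclidean distances.

    Falls back to 1.0 when all points coincide (median distance zero).
    """
    pooled = np.vstack([x1, x2])
    if pooled.shape[0] > 2000:  # cap the quadratic cost of the heuristic
        pooled = pooled[:2000]
    med = float(np.median(pdist(pooled)))
    return med if med > 0.0 else 1.0


def _rbf_kernel(a: np.ndarray, b: np.ndarray, bandwidth: float) -> np.ndarray:
    d2 = cdist(a, b, metric="sqeuclidean")
    return np.exp(-d2 / (2.0 * bandwidth ** 2))


def mmd2(x1, x2, bandwidth: float | None = None, unbiased: bool = True) -> float:
    """Squared maximum mean discrepancy between two samples, RBF kernel.

    The unbiased estimator omits the diagonal self-similarities and may be
    slightly negative; it is reported as-is.  The biased (V-statistic)
    variant is nonnegative by construction.
    """
    x1 = np.atleast_2d(np.asarray(x1, dtype=float))
    x2 = np.atleast_2d(np.asarray(x2, dtype=float))
    if x1.shape[1] != x2.shape[1]:
        raise ValidationError(
            f"mmd2: dimension mismatch {x1.shape[1]} vs {x2.shape[1]}")
    n1, n2 = x1.shape[0], x2.shape[0]
    if unbiased and (n1 < 2 or n2 < 2):
        raise ValidationError("mmd2: unbiased estimator needs >= 2 points per side")
    if bandwidth is None:
        bandwidth = median_heuristic_bandwidth(x1, x2)
    k11 = _rbf_kernel(x1, x1, bandwidth)
    k22 = _rbf_kernel(x2, x2, bandwidth)
    k12 = _rbf_kernel(x1, x2, bandwidth)
    if unbiased:
        term1 = (k11.sum() - np.trace(k11)) / (n1 * (n1 - 1))
        term2 = (k22.sum() - np.trace(k22)) / (n2 * (n2 - 1))
    else:
        term1 = k11.mean()
        term2 = k22.mean()
    return float(term1 + term2 - 2.0 * k12.mean())


def mmd_permutation_test(x1, x2, n_perm: int = 1000, seed: int = 0,
                         bandwidth: float | None = None,
                         subsample: int | None = 2000) -> tuple[float, float]:
    """Permutation p-value for the MMD two-sample test.

    Pooled labels are reshuffled ``n_perm`` times with a fixed seed and the
    add-one rule ``p = (1 + #{perm stat >= observed}) / (1 + n_perm)`` is
    applied, so p >= 1/(1+n_perm) always.  Each side is optionally capped at
    ``subsample`` points (seeded, without replacement) to bound the quadratic
    kernel cost.  Returns ``(mmd2_observed, p_value)``.
    """
    if n_perm < 1:
        raise ValidationError("mmd_permutation_test: n_perm must be >= 1")
    x1 = np.atleast_2d(np.asarray(x1, dtype=float))
    x2 = np.atleast_2d(np.asarray(x2, dtype=float))
    rng = np.random.default_rng(seed)
    if subsample is not None:
        if x1.shape[0] > subsample:
            x1 = x1[rng.choice(x1.shape[0], subsample, replace=False)]
        if x2.shape[0] > subsample:
            x2 = x2[rng.choice(x2.shape[0], subsample, replace=False)]
    n1, n2 = x1.shape[0], x2.shape[0]
    pooled = np.vstack([x1, x2])
    if bandwidth is None:
        bandwidth = median_heuristic_bandwidth(x1, x2)
    kernel = _rbf_kernel(pooled, pooled, bandwidth)
    diag = np.diag(kernel)

    def stat(mask: np.ndarray) -> float:
        # unbiased MMD^2 from the precomputed pooled kernel matrix
        m = mask.astype(float)
        w = 1.0 - m
        km = kernel @ m
        s11 = m @ km - diag @ m
        s22 = w @ (kernel @ w) - diag @ w
        s12 = w @ km
        a, b = m.sum(), w.sum()
        return float(s11 / (a * (a - 1)) + s22 / (b * (b - 1)) - 2.0 * s12 / (a * b))

    base = np.zeros(n1 + n2, dtype=bool)
    base[:n1] = True
    observed = stat(base)
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(n1 + n2)
        if stat(base[perm]) >= observed:
            count += 1
    return observed, (1 + count) / (1 + n_perm)


# ---------------------------------------------------------------------------
# multiple testing
# ---------------------------------------------------------------------------

def bonferroni(pvals) -> list[float]:
    """Bonferroni adjustment: p -> min(1, m*p) with m = number of tests."""
    pvals = list(pvals)
    m = len(pvals)
    for p in pvals:
        if not 0.0 <= p <= 1.0:
            raise ValidationError(f"p-value out of [0,1]: {p}")
    return [min(1.0, m * p) for p in pvals]


def _adjust(reports: list[ShiftReport]) -> list[ShiftReport]:
    adj = bonferroni([r.p_value for r in reports])
    for r, p in zip(reports, adj):
        r.p_adjusted = p
    return reports


# ---------------------------------------------------------------------------
# report builders
# ---------------------------------------------------------------------------

def shift_report_id(pred: PredictionSet, emb: EmbeddingSet | None,
                    attribute: str, n_perm: int = 1000, seed: int = 0,
                    min_group: int = 2) -> list[ShiftReport]:
    """ID-setting shift tests: one prevalence and one representation test per
    unordered group pair, Bonferroni-adjusted over the whole report."""
    groups = pred.groups(attribute)
    values = pred.group_values(attribute)
    labels = pred.labels
    kept = []
    for g in groups:
        n = int((values == g).sum())
        if n < min_group:
            logger.warning("shift_report_id: group %r excluded (n=%d)", g, n)
        else:
            kept.append(g)
    if len(kept) < 2:
        raise ValidationError("shift_report_id: fewer than 2 usable groups")
    vectors = emb.aligned_to(pred.frame["sample_id"]) if emb is not None else None
    reports: list[ShiftReport] = []
    for i, g1 in enumerate(kept):
        for g2 in kept[i + 1:]:
            m1, m2 = values == g1, values == g2
            k1, n1 = int(labels[m1].sum()), int(m1.sum())
            k2, n2 = int(labels[m2].sum()), int(m2.sum())
            reports.append(ShiftReport(
                "ID", "prevalence", f"{g1}-vs-{g2}",
                tv_distance_binary(k1 / n1, k2 / n2),
                binomial_proportion_test(k1, n1, k2, n2), n_1=n1, n_2=n2))
            if vectors is not None:
                d, p = mmd_permutation_test(vectors[m1], vectors[m2],
                                            n_perm=n_perm, seed=seed)
                reports.append(ShiftReport(
                    "ID", "representation", f"{g1}-vs-{g2}", d, p, n_1=n1, n_2=n2))
    return _adjust(reports)


def shift_report_ood(src_pred: PredictionSet, tar_pred: PredictionSet,
                     attribute: str,
                     src_emb: EmbeddingSet | None = None,
                     tar_emb: EmbeddingSet | None = None,
                     n_perm: int = 1000, seed: int = 0) -> list[ShiftReport]:
    """OOD-setting shift tests between a source and a target environment.

    Emits one label-shift and (if embeddings are given) one covariate-shift
    test, plus a per-group prevalence and representation test for every group
    present in both environments; Bonferroni family = this report.
    """
    y_s, y_t = src_pred.labels, tar_pred.labels
    reports: list[ShiftReport] = [ShiftReport(
        "OOD", "label", "src-vs-tar",
        tv_distance_binary(float(y_s.mean()), float(y_t.mean())),
        binomial_proportion_test(int(y_s.sum()), len(y_s), int(y_t.sum()), len(y_t)),
        n_1=len(y_s), n_2=len(y_t))]
    v_s = src_emb.aligned_to(src_pred.frame["sample_id"]) if src_emb is not None else None
    v_t = tar_emb.aligned_to(tar_pred.frame["sample_id"]) if tar_emb is not None else None
    if v_s is not None and v_t is not None:
        d, p = mmd_permutation_test(v_s, v_t, n_perm=n_perm, seed=seed)
        reports.append(ShiftReport("OOD", "covariate", "src-vs-tar", d, p,
                                   n_1=len(y_s), n_2=len(y_t)))
    a_s = src_pred.group_values(attribute)
    a_t = tar_pred.group_values(attribute)
    shared = sorted(set(a_s) & set(a_t))
    for g in sorted(set(a_s) | set(a_t)):
        if g not in shared:
            logger.warning("shift_report_ood: group %r present in only one "
                           "environment, skipped", g)
    for g in shared:
        m_s, m_t = a_s == g, a_t == g
        n1, n2 = int(m_s.sum()), int(m_t.sum())
        reports.append(ShiftReport(
            "OOD", "prevalence", f"src-vs-tar|{g}",
            tv_distance_binary(float(y_s[m_s].mean()), float(y_t[m_t].mean())),
            binomial_proportion_test(int(y_s[m_s].sum()), n1,
                                     int(y_t[m_t].sum()), n2),
            n_1=n1, n_2=n2))
        if v_s is not None and v_t is not None:
            d, p = mmd_permutation_test(v_s[m_s], v_t[m_t], n_perm=n_perm, seed=seed)
            reports.append(ShiftReport("OOD", "representation", f"src-vs-tar|{g}",
                                       d, p, n_1=n1, n_2=n2))
    return _adjust(reports)
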