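"""Per-group performance, calibration and equal-opportunity gap metrics.

The audit quantifies *equal opportunity* violations: the difference between
two demographic groups in one class-conditioned error rate.  Which rate
depends on the task polarity — for a healthy-indicator task ("No Finding")
underdiagnosis shows up as false positives, so the FPR gap is audited; for a
disease-indicator task it shows up as false negatives, so the FNR gap is
audited.  The mirrored overdiagnosis reading (swap the rate) is available by
flag.

Conventions fixed here so results are bit-reproducible:

* decision rule at a threshold ``t``: predict positive iff ``score >= t``;
* rates conditioned on an empty class are *undefined* and propagate as
  ``NaN`` markers, never silently as zero;
* one threshold per evaluation context, chosen on the pooled (ungrouped)
  set and shared by all groups, so groups are compared at a common
  operating point.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from sklearn.metrics import roc_auc_score

from .grid_store import PredictionSet, ValidationError

logger = logging.getLogger("fairshift")

UNDEFINED = float("nan")


def _as_float(x) -> np.ndarray:
    return np.asarray(x, dtype=float)


def _as_int(x) -> np.ndarray:
    return np.asarray(x, dtype=int)


# ---------------------------------------------------------------------------
# scalar metrics
# ---------------------------------------------------------------------------

def auroc(scores, labels) -> float:
    """Area under the ROC curve; equals P(s+ > s-) + P(s+ = s-)/2.

    Returns the NaN undefined-marker (with a log entry) when only one class
    is present.
    """
    scores, labels = _as_float(scores), _as_int(labels)
    if labels.min(initial=1) == labels.max(initial=0):
        logger.info("auroc undefined: single-class labels")
        return UNDEFINED
    return float(roc_auc_score(labels, scores))


def f1_optimal_threshold(scores, labels) -> float:
    """Smallest observed score maximizing F1 for the rule ``score >= t``.

    Candidate thresholds are exactly the unique observed scores; ties on F1
    break toward the smallest threshold.
    """
    scores, labels = _as_float(scores), _as_int(labels)
    n_pos = int(labels.sum())
    if n_pos == 0:
        raise ValidationError("f1_optimal_threshold: no positive labels, F1 undefined")
    thresholds = np.unique(scores)  # sorted ascending
    # predicted positive at t: scores >= t.  Sort descending once and sweep.
    order = np.argsort(-scores, kind="stable")
    s_sorted = scores[order]
    tp_cum = np.cumsum(labels[order])
    pred_cum = np.arange(1, len(scores) + 1)
    # for each unique threshold, the last index with s_sorted >= t
    idx = np.searchsorted(-s_sorted, -thresholds, side="right") - 1
    tp = tp_cum[idx]
    pred_pos = pred_cum[idx]
    f1 = 2.0 * tp / (pred_pos + n_pos)  # 2TP / (2TP+FP+FN)
    best = np.flatnonzero(f1 == f1.max())
    return float(thresholds[best[0]])


@dataclass
class GroupRates:
    """Confusion-matrix rates plus AUROC/ECE for one group (NaN = undefined)."""

    group: str
    n: int
    n_pos: int
    tpr: float = UNDEFINED
    tnr: float = UNDEFINED
    fpr: float = UNDEFINED
    fnr: float = UNDEFINED
    auroc: float = UNDEFINED
    ece: float = UNDEFINED


def confusion_rates(scores, labels, threshold: float, group: str = "all") -> GroupRates:
    """TPR/TNR/FPR/FNR at a fixed threshold (``score >= t`` is positive)."""
    scores, labels = _as_float(scores), _as_int(labels)
    pred = scores >= threshold
    pos = labels == 1
    n_pos, n_neg = int(pos.sum()), int((~pos).sum())
    r = GroupRates(group=group, n=len(labels), n_pos=n_pos)
    if n_pos:
        r.tpr = float(pred[pos].mean())
        r.fnr = 1.0 - r.tpr
    else:
        logger.info("confusion_rates: no positives, TPR/FNR undefined (%s)", group)
    if n_neg:
        r.fpr = float(pred[~pos].mean())
        r.tnr = 1.0 - r.fpr
    else:
        logger.info("confusion_rates: no negatives, TNR/FPR undefined (%s)", group)
    return r


def ece(scores, labels, n_bins: int = 10) -> float:
    """Expected calibration error over equal-width bins of [0, 1].

    Bin confidence is the *mean score* in the bin (not the midpoint); the
    final bin is right-closed so a score of exactly 1.0 falls in it.
    """
    scores, labels = _as_float(scores), _as_int(labels)
    if len(scores) == 0:
        raise ValidationError("ece: empty input")
    if n_bins < 1:
        raise ValidationError(f"ece: n_bins must be >= 1, got {n_bins}")
    bins = np.minimum((scores * n_bins).astype(int), n_bins - 1)
    total = 0.0
    n = len(scores)
    for b in range(n_bins):
        in_bin = bins == b
        n_b = int(in_bin.sum())
        if n_b == 0:
            continue
        gap = abs(float(scores[in_bin].mean()) - float(labels[in_bin].mean()))
        total += n_b / n * gap
    return total


# ---------------------------------------------------------------------------
# per-group evaluation
# ---------------------------------------------------------------------------

def resolve_threshold(pred: PredictionSet, policy: float | str = "f1") -> float:
    """Resolve a threshold policy on the pooled evaluation set.

    ``policy`` is either an explicit number in [0, 1] or the string ``"f1"``
    (F1-maximizing threshold over the pooled scores).
    """
    if isinstance(policy, str):
        if policy != "f1":
            raise ValidationError(f"unknown threshold policy {policy!r}")
        return f1_optimal_threshold(pred.scores, pred.labels)
    t = float(policy)
    if not 0.0 <= t <= 1.0:
        raise ValidationError(f"threshold must be in [0,1], got {t}")
    return t


def group_metrics(pred: PredictionSet, attribute: str,
                  threshold_policy: float | str = "f1",
                  n_bins: int = 10) -> dict[str, GroupRates]:
    """Confusion rates, AUROC and ECE per demographic group.

    The threshold is chosen once on the full (ungrouped) set and applied to
    every group, so all groups are evaluated at a common operating point.
    """
    threshold = resolve_threshold(pred, threshold_policy)
    values = pred.group_values(attribute)
    scores, labels = pred.scores, pred.labels
    out: dict[str, GroupRates] = {}
    for g in pred.groups(attribute):
        m = values == g
        r = confusion_rates(scores[m], labels[m], threshold, group=g)
        r.auroc = auroc(scores[m], labels[m])
        r.ece = ece(scores[m], labels[m], n_bins) if m.any() else UNDEFINED
        out[g] = r
    return out


def gap_metric_name(polarity: str, overdiagnosis: bool = False) -> str:
    """Which class-conditioned error rate the audited gap uses.

    Underdiagnosis (default): FPR for a healthy-indicator task, FNR for a
    disease-indicator task.  The overdiagnosis flag swaps the rate.
    """
    healthy = polarity == "healthy_indicator"
    if overdiagnosis:
        healthy = not healthy
    return "fpr" if healthy else "fnr"


@dataclass
class GapResult:
    """Signed per-group error-rate gap (group_1 minus group_2)."""

    attribute: str
    group_1: str
    group_2: str
    metric: str
    signed_gap: float
    absolute_gap: float
    threshold: float
    ci_low: float = UNDEFINED
    ci_high: float = UNDEFINED
    significant: bool | None = None
    n_boot: int = 0
    n_redrawn: int = 0
    rates: dict[str, float] = field(default_factory=dict)


def _rate_pair(scores, labels, groups_arr, g1: str, g2: str,
               metric: str, threshold: float) -> tuple[float, float]:
    rates = []
    for g in (g1, g2):
        m = groups_arr == g
        r = confusion_rates(scores[m], labels[m], threshold, group=g)
        rates.append(getattr(r, metric))
    return rates[0], rates[1]


def fairness_gap(pred: PredictionSet, attribute: str,
                 group_pair: tuple[str, str],
                 threshold_policy: float | str = "f1",
                 overdiagnosis: bool = False) -> GapResult:
    """Signed equal-opportunity gap between two designated groups.

    The rate audited follows the task polarity (see :func:`gap_metric_name`).
    If the rate is undefined in either group, the gap is the NaN marker.
    """
    g1, g2 = group_pair
    metric = gap_metric_name(pred.task_polarity, overdiagnosis)
    threshold = resolve_threshold(pred, threshold_policy)
    groups_arr = pred.group_values(attribute)
    r1, r2 = _rate_pair(pred.scores, pred.labels, groups_arr, g1, g2,
                        metric, threshold)
    gap = r1 - r2
    if np.isnan(gap):
        logger.info("fairness_gap undefined for %s (%s vs %s)", attribute, g1, g2)
    return GapResult(attribute=attribute, group_1=g1, group_2=g2, metric=metric,
                     signed_gap=float(gap), absolute_gap=float(abs(gap)),
                     threshold=threshold, rates={g1: r1, g2: r2})


def gap_ci(pred: PredictionSet, attribute: str, group_pair: tuple[str, str],
           threshold_policy: float | str = "f1", n_boot: int = 1000,
           seed: int = 0, alpha: float = 0.05,
           overdiagnosis: bool = False) -> GapResult:
    """Percentile bootstrap CI for the signed gap.

    The resampling unit is the sample row; the threshold is held fixed at the
    value chosen on the original set.  A resample in which either group's
    conditioning class is empty is redrawn (count reported).
    """
    if n_boot < 1:
        raise ValidationError("gap_ci: n_boot must be >= 1")
    result = fairness_gap(pred, attribute, group_pair, threshold_policy,
                          overdiagnosis)
    g1, g2 = group_pair
    rng = np.random.default_rng(seed)
    scores, labels = pred.scores, pred.labels
    groups_arr = pred.group_values(attribute)
    n = len(scores)
    draws = np.empty(n_boot)
    n_redrawn = 0
    for b in range(n_boot):
        for _attempt in range(1000):
            idx = rng.integers(0, n, size=n)
            r1, r2 = _rate_pair(scores[idx], labels[idx], groups_arr[idx],
                                g1, g2, result.metric, result.threshold)
            gap = r1 - r2
            if not np.isnan(gap):
                break
            n_redrawn += 1
        else:
            raise ValidationError("gap_ci: could not draw a non-degenerate resample")
        draws[b] = gap
    lo, hi = np.percentile(draws, [100 * alpha / 2, 100 * (1 - alpha / 2)])
    result.ci_low, result.ci_high = float(lo), float(hi)
    result.significant = bool(lo > 0.0 or hi < 0.0)
    result.n_boot = n_boot
    result.n_redrawn = n_redrawn
    if n_redrawn:
        logger.info("gap_ci: redrew %d degenerate resamples", n_redrawn)
    return result


def bootstrap_mean_ci(values, n_boot: int = 1000, seed: int = 0,
                      alpha: float = 0.05) -> tuple[float, float]:
    """Percentile bootstrap CI for the mean of ``values``.

    Resamples the values with replacement ``n_boot`` times and returns the
    (alpha/2, 1-alpha/2) percentiles of the resampled means.
    """
    values = _as_float(values)
    if values.size == 0:
        raise ValidationError("bootstrap_mean_ci: empty input")
    if n_boot < 1:
        raise ValidationError("bootstrap_mean_ci: n_boot must be >= 1")
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, values.size, size=(n_boot, values.size))
    means = values[idx].mean(axis=1)
    lo, hi = np.percentile(means, [100 * alpha / 2, 100 * (1 - alpha / 2)])
    return float(lo), float(hi)


# ---------------------------------------------------------------------------
# prevalence rebalancing
# ---------------------------------------------------------------------------

def rebalance_eval_set(pred: PredictionSet, attributes: list[str] | tuple[str, ...],
                       seed: int = 0) -> PredictionSet:
    """Subsample so every attribute combination has equal size and prevalence.

    Every (attribute-combination, class) cell is downsampled without
    replacement to the size of the smallest such cell, eliminating prevalence
    shift across cells in the evaluation set.
    """
    frame = pred.frame
    keys = [frame[a].astype(str) for a in attributes]
    cell = keys[0]
    for k in keys[1:]:
        cell = cell + "|" + k
    labels = pred.labels
    cells = sorted(cell.unique())
    sizes: dict[tuple[str, int], np.ndarray] = {}
    for c in cells:
        for y in (0, 1):
            idx = np.flatnonzero((cell == c).to_numpy() & (labels == y))
            if idx.size == 0:
                raise ValidationError(
                    f"rebalance_eval_set: empty cell (combination={c!r}, class={y})")
            sizes[(c, y)] = idx
    m = min(idx.size for idx in sizes.values())
    rng = np.random.default_rng(seed)
    keep: list[np.ndarray] = []
    for c in cells:
        for y in (0, 1):
            idx = sizes[(c, y)]
            keep.append(np.sort(rng.choice(idx, size=m, replace=False)))
    mask = np.zeros(len(frame), dtype=bool)
    mask[np.concatenate(keep)] = True
    return pred.subset(mask=mask)
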