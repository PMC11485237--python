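"""Grid-level analyses: Pareto fronts, constrained optima and correlations.

A model grid induces a cloud of (performance, fairness-gap) points per
evaluation setting.  This module extracts the fairness-performance Pareto
front (higher AUROC better, smaller absolute gap better), the best-fairness
model under a minimum-performance constraint, the correlation between
attribute encoding and fairness gap across models, and the transfer
correlations of performance and fairness between an ID and an OOD
environment.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .grid_store import ModelGrid, ValidationError
from . import fairness_metrics as fm


@dataclass(frozen=True)
class ParetoPoint:
    """One model's position in the fairness-performance plane."""

    model_id: str
    performance: float   # overall (or worst-group) AUROC; higher is better
    fairness_gap: float  # absolute gap; lower is better
    environment: str = ""

    def __post_init__(self) -> None:
        if not (np.isfinite(self.performance) and np.isfinite(self.fairness_gap)):
            raise ValidationError(f"non-finite Pareto point for {self.model_id!r}")


@dataclass
class CorrelationResult:
    """Pearson correlation with two-sided t-test p and Fisher-z 95% CI."""

    r: float
    p_value: float
    ci_low: float
    ci_high: float
    n: int


def pareto_front(points: list[ParetoPoint]) -> list[ParetoPoint]:
    """Points not strictly dominated in (performance up, gap down).

    Dominance is weak with at least one strict coordinate, so exact ties
    stay on the front.  Order-invariant; returned sorted by descending
    performance.
    """
    if not points:
        raise ValidationError("pareto_front: empty point list")
    front = []
    for p in points:
        dominated = any(
            q.performance >= p.performance and q.fairness_gap <= p.fairness_gap
            and (q.performance > p.performance or q.fairness_gap < p.fairness_gap)
            for q in points)
        if not dominated:
            front.append(p)
    return sorted(front, key=lambda p: (-p.performance, p.fairness_gap, p.model_id))


def constrained_best_fairness(points: list[ParetoPoint],
                              min_performance: float) -> ParetoPoint:
    """Smallest-gap point among those meeting the performance constraint.

    Ties break toward higher performance, then lexical model id.
    """
    feasible = [p for p in points if p.performance >= min_performance]
    if not feasible:
        best = max(p.performance for p in points)
        raise ValidationError(
            f"no model meets performance >= {min_performance} "
            f"(best available: {best:.4f})")
    return min(feasible, key=lambda p: (p.fairness_gap, -p.performance, p.model_id))


def pearson_with_ci(x, y, alpha: float = 0.05) -> CorrelationResult:
    """Pearson r with its two-sided t-test p-value and Fisher-z CI."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    if n < 3:
        raise ValidationError("pearson_with_ci: need n >= 3")
    if np.std(x) == 0.0 or np.std(y) == 0.0:
        raise ValidationError("pearson_with_ci: zero variance input")
    r, p = stats.pearsonr(x, y)
    r = float(r)
    if abs(r) >= 1.0:
        lo, hi = r, r
    else:
        z = np.arctanh(r)
        se = 1.0 / np.sqrt(n - 3)
        crit = stats.norm.ppf(1 - alpha / 2)
        lo, hi = np.tanh(z - crit * se), np.tanh(z + crit * se)
    return CorrelationResult(r=r, p_value=float(p), ci_low=float(lo),
                             ci_high=float(hi), n=n)


# ---------------------------------------------------------------------------
# grid-level assembly
# ---------------------------------------------------------------------------

def grid_points(grid: ModelGrid, environment: str, attribute: str,
                group_pair: tuple[str, str], split: str = "test",
                threshold_policy: float | str = "f1",
                performance: str = "overall") -> list[ParetoPoint]:
    """One fairness-performance point per model for one environment/setting.

    ``performance`` selects overall AUROC (default) or ``"worst_group"``
    AUROC.  Models whose gap or AUROC is undefined in this setting are
    skipped.
    """
    points = []
    for model_id in grid.model_ids():
        entry = grid.entries[model_id]
        if environment not in entry.predictions:
            continue
        pred = entry.predictions[environment].subset(split=split)
        gap = fm.fairness_gap(pred, attribute, group_pair, threshold_policy)
        if performance == "overall":
            perf = fm.auroc(pred.scores, pred.labels)
        elif performance == "worst_group":
            per_group = [fm.auroc(pred.scores[pred.group_values(attribute) == g],
                                  pred.labels[pred.group_values(attribute) == g])
                         for g in pred.groups(attribute)]
            per_group = [a for a in per_group if np.isfinite(a)]
            perf = min(per_group) if per_group else float("nan")
        else:
            raise ValidationError(f"unknown performance axis {performance!r}")
        if np.isfinite(perf) and np.isfinite(gap.absolute_gap):
            points.append(ParetoPoint(model_id, float(perf), gap.absolute_gap,
                                      environment))
    return points


def encoding_fairness_correlation(encode_table: dict[str, "object"],
                                  gap_table: dict[str, float],
                                  performance_table: dict[str, float],
                                  performance_floor: float = 0.7,
                                  ) -> CorrelationResult:
    """Correlate attribute-probe AUROC with the absolute fairness gap.

    Models below the overall-AUROC performance floor are excluded before
    correlating (suboptimal models are not deployment candidates).
    """
    shared = sorted(set(encode_table) & set(gap_table) & set(performance_table))
    kept = [m for m in shared if performance_table[m] >= performance_floor]
    if len(kept) < 3:
        raise ValidationError(
            f"encoding_fairness_correlation: only {len(kept)} models above "
            f"the {performance_floor} performance floor")
    enc = [getattr(encode_table[m], "test_macro_auroc", encode_table[m])
           for m in kept]
    gaps = [abs(gap_table[m]) for m in kept]
    return pearson_with_ci(enc, gaps)


def transfer_correlation(grid: ModelGrid, id_env: str, ood_env: str,
                         attribute: str, group_pair: tuple[str, str],
                         quantity: str = "performance", split: str = "test",
                         threshold_policy: float | str = "f1",
                         ) -> CorrelationResult:
    """Correlation across models of the ID vs OOD value of one quantity.

    ``quantity`` is ``"performance"`` (overall AUROC) or ``"fairness"``
    (signed gap).  Only models evaluated in both environments enter.
    """
    xs, ys = [], []
    for model_id in grid.model_ids():
        entry = grid.entries[model_id]
        if id_env not in entry.predictions or ood_env not in entry.predictions:
            continue
        pair = []
        for env in (id_env, ood_env):
            pred = entry.predictions[env].subset(split=split)
            if quantity == "performance":
                val = fm.auroc(pred.scores, pred.labels)
            elif quantity == "fairness":
                val = fm.fairness_gap(pred, attribute, group_pair,
                                      threshold_policy).signed_gap
            else:
                raise ValidationError(f"unknown quantity {quantity!r}")
            pair.append(val)
        if all(np.isfinite(v) for v in pair):
            xs.append(pair[0])
            ys.append(pair[1])
    return pearson_with_ci(xs, ys)


def front_transfer(grid: ModelGrid, id_env: str, ood_env: str, attribute: str,
                   group_pair: tuple[str, str], split: str = "test",
                   threshold_policy: float | str = "f1",
                   performance: str = "overall") -> dict[str, dict[str, bool]]:
    """Per-model Pareto-front membership in the ID and the OOD environment."""
    flags: dict[str, dict[str, bool]] = {}
    for env, key in ((id_env, "on_id_front"), (ood_env, "on_ood_front")):
        pts = grid_points(grid, env, attribute, group_pair, split,
                          threshold_policy, performance)
        members = {p.model_id for p in pareto_front(pts)}
        for p in pts:
            flags.setdefault(p.model_id, {})[key] = p.model_id in members
    return {m: f for m, f in flags.items()
            if "on_id_front" in f and "on_ood_front" in f}
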