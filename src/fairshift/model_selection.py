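"""Fairness-aware model selection evaluated against an OOD oracle.

Given a grid of candidate models, deployment-time selection may only look
at ID data.  This module scores a registry of ID-computable selection
criteria (minimum ID fairness gap, minimum attribute-probe AUROC/accuracy,
maximum overall or worst-group AUROC, calibration-based criteria, ...),
applies each to the grid after a performance cutoff, and measures the
*regret* of each criterion: the increase in OOD fairness gap of its chosen
model over the model an OOD-observing oracle would pick.  Regrets are
aggregated across settings (OOD environment x task x attribute) with a
percentile bootstrap over settings, and criteria are compared pairwise with
a one-tailed Wilcoxon rank-sum test (exact enumeration at small n).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
from scipy.stats import norm, rankdata

from . import fairness_metrics as fm
from .encoding_probe import ProbeResult
from .grid_store import ModelGrid, ValidationError

logger = logging.getLogger("fairshift")


@dataclass(frozen=True)
class SelectionCriterion:
    """An ID-computable selection rule: optimize ``key`` in ``direction``."""

    name: str
    direction: str  # "minimize" or "maximize"
    key: str        # column of the ID score table

    def __post_init__(self) -> None:
        if self.direction not in ("minimize", "maximize"):
            raise ValidationError(f"bad direction {self.direction!r}")


#: the shipped criterion registry (pluggable via config)
BUILTIN_CRITERIA: tuple[SelectionCriterion, ...] = (
    SelectionCriterion("Minimum Fairness Gap", "minimize", "id_gap"),
    SelectionCriterion("Minimum Attribute Prediction AUROC", "minimize", "probe_auroc"),
    SelectionCriterion("Minimum Attribute Prediction Accuracy", "minimize",
                       "probe_accuracy"),
    SelectionCriterion("Maximum Overall AUROC", "maximize", "overall_auroc"),
    SelectionCriterion("Maximum Worst-Group AUROC", "maximize", "worst_group_auroc"),
    SelectionCriterion("Minimum ECE Gap", "minimize", "ece_gap"),
    SelectionCriterion("Minimum Overall ECE", "minimize", "overall_ece"),
    SelectionCriterion("Minimum Worst-Group Error Rate", "minimize",
                       "worst_group_error"),
)


@dataclass
class SelectionReport:
    """Per-criterion choices, regrets and statistical comparisons."""

    criteria: list[str]
    per_setting: dict[str, list[dict]]        # criterion -> one row per setting
    mean_regret: dict[str, float]
    ci_low: dict[str, float]
    ci_high: dict[str, float]
    wilcoxon_p: dict[str, float] = field(default_factory=dict)  # "a<b" -> p
    skipped_settings: list[dict] = field(default_factory=list)
    n_boot: int = 0
    seed: int = 0


# ---------------------------------------------------------------------------
# ID score table
# ---------------------------------------------------------------------------

def id_score_table(grid: ModelGrid, attribute: str, group_pair: tuple[str, str],
                   probe_table: dict[str, ProbeResult] | None = None,
                   split: str = "val", threshold_policy: float | str = "f1",
                   n_bins: int = 10) -> dict[str, dict[str, float]]:
    """All ID-computable criterion inputs, one row per model.

    Computed on the ID environment's ``split`` (validation by default, the
    split a practitioner would select on).  Probe columns are NaN when no
    probe result is supplied for a model.
    """
    env = grid.config.id_environment
    table: dict[str, dict[str, float]] = {}
    for model_id in grid.model_ids():
        pred = grid.entries[model_id].predictions[env].subset(split=split)
        gap = fm.fairness_gap(pred, attribute, group_pair, threshold_policy)
        groups = fm.group_metrics(pred, attribute, threshold_policy, n_bins)
        defined_auroc = [g.auroc for g in groups.values() if np.isfinite(g.auroc)]
        defined_ece = [g.ece for g in groups.values() if np.isfinite(g.ece)]
        rate_name = gap.metric
        defined_rate = [getattr(g, rate_name) for g in groups.values()
                        if np.isfinite(getattr(g, rate_name))]
        probe = probe_table.get(model_id) if probe_table else None
        table[model_id] = {
            "id_gap": gap.absolute_gap,
            "overall_auroc": fm.auroc(pred.scores, pred.labels),
            "worst_group_auroc": min(defined_auroc) if defined_auroc else float("nan"),
            "ece_gap": (max(defined_ece) - min(defined_ece)
                        if len(defined_ece) >= 2 else float("nan")),
            "overall_ece": fm.ece(pred.scores, pred.labels, n_bins),
            "worst_group_error": max(defined_rate) if defined_rate else float("nan"),
            "probe_auroc": probe.test_macro_auroc if probe else float("nan"),
            "probe_accuracy": probe.test_accuracy if probe else float("nan"),
        }
    return table


# ---------------------------------------------------------------------------
# filtering and selection
# ---------------------------------------------------------------------------

def performance_filter(grid: ModelGrid, split: str = "val",
                       rule: str | None = None, margin: float | None = None,
                       reference_algorithm: str | None = None) -> list[str]:
    """Keep models whose ID validation AUROC clears the performance cutoff.

    Default rule: AUROC >= (1 - margin) x the best reference-algorithm
    model's validation AUROC (relative reading of "no less than 5% of the
    best reference model"); ``rule="absolute"`` subtracts the margin instead.
    """
    cfg = grid.config
    rule = rule or cfg.performance_cutoff
    margin = cfg.performance_margin if margin is None else margin
    reference_algorithm = reference_algorithm or cfg.reference_algorithm
    env = cfg.id_environment
    aurocs = {}
    for model_id in grid.model_ids():
        pred = grid.entries[model_id].predictions[env].subset(split=split)
        aurocs[model_id] = fm.auroc(pred.scores, pred.labels)
    ref = [aurocs[m] for m in aurocs
           if grid.entries[m].algorithm == reference_algorithm
           and np.isfinite(aurocs[m])]
    if not ref:
        raise ValidationError(
            f"performance_filter: no model with reference algorithm "
            f"{reference_algorithm!r}")
    best = max(ref)
    cutoff = best * (1.0 - margin) if rule == "relative" else best - margin
    kept = sorted(m for m, a in aurocs.items() if np.isfinite(a) and a >= cutoff)
    if not kept:
        raise ValidationError(
            f"performance_filter: no model clears cutoff {cutoff:.4f}")
    return kept


def _ordered(subset: list[str], scores: dict[str, float],
             tiebreak_auroc: dict[str, float], reverse: bool) -> list[str]:
    sign = -1.0 if reverse else 1.0
    return sorted(subset, key=lambda m: (sign * scores[m],
                                         -tiebreak_auroc.get(m, 0.0), m))


def apply_criterion(subset: list[str], criterion: SelectionCriterion,
                    score_table: dict[str, dict[str, float]]) -> str:
    """Deterministic argmin/argmax of a criterion over the filtered subset.

    Ties break toward higher ID overall AUROC, then lexical model id.
    """
    if not subset:
        raise ValidationError("apply_criterion: empty subset")
    scores = {}
    for m in subset:
        v = score_table[m][criterion.key]
        if not np.isfinite(v):
            raise ValidationError(
                f"criterion {criterion.name!r} input missing for model {m!r}")
        scores[m] = float(v)
    tiebreak = {m: score_table[m]["overall_auroc"] for m in subset}
    return _ordered(subset, scores, tiebreak,
                    reverse=(criterion.direction == "maximize"))[0]


def ood_gaps(grid: ModelGrid, subset: list[str], tar_env: str, attribute: str,
             group_pair: tuple[str, str], split: str = "test",
             threshold_policy: float | str = "f1") -> dict[str, float]:
    """Absolute OOD fairness gap per model (threshold re-resolved per env)."""
    gaps = {}
    for m in subset:
        entry = grid.entries[m]
        if tar_env not in entry.predictions:
            raise ValidationError(f"model {m!r} not evaluated in {tar_env!r}")
        pred = entry.predictions[tar_env].subset(split=split)
        gaps[m] = fm.fairness_gap(pred, attribute, group_pair,
                                  threshold_policy).absolute_gap
    return gaps


def oracle_select(subset: list[str], gaps: dict[str, float],
                  score_table: dict[str, dict[str, float]]) -> str:
    """The model an OOD-observing oracle picks: minimal absolute OOD gap."""
    if not subset:
        raise ValidationError("oracle_select: empty subset")
    tiebreak = {m: score_table[m]["overall_auroc"] for m in subset}
    return _ordered(subset, {m: gaps[m] for m in subset}, tiebreak,
                    reverse=False)[0]


# ---------------------------------------------------------------------------
# rank-sum comparison
# ---------------------------------------------------------------------------

def compare_criteria(regrets_a, regrets_b) -> float:
    """One-tailed Wilcoxon rank-sum p for the alternative "a < b".

    Exact enumeration of all rank assignments for combined n <= 12 (handles
    ties via midranks automatically); normal approximation with tie
    correction and continuity correction otherwise.
    """
    a = np.asarray(regrets_a, dtype=float)
    b = np.asarray(regrets_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValidationError("compare_criteria: empty sample")
    n1, n2 = a.size, b.size
    pooled = np.concatenate([a, b])
    ranks = rankdata(pooled)
    observed = ranks[:n1].sum()
    if n1 + n2 <= 12:
        total = 0
        le = 0
        for combo in combinations(range(n1 + n2), n1):
            total += 1
            if ranks[list(combo)].sum() <= observed + 1e-9:
                le += 1
        return le / total
    mu = n1 * (n2 + n1 + 1) / 2.0
    n = n1 + n2
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = ((counts ** 3 - counts).sum()) / (n * (n - 1))
    sigma2 = n1 * n2 / 12.0 * (n + 1 - tie_term)
    if sigma2 <= 0:
        return 0.5  # all values tied: no evidence either way
    z = (observed - mu + 0.5) / math.sqrt(sigma2)
    return float(norm.cdf(z))


# ---------------------------------------------------------------------------
# the full evaluation
# ---------------------------------------------------------------------------

def evaluate_criteria(grid: ModelGrid, settings: list[dict],
                      criteria: tuple[SelectionCriterion, ...] = BUILTIN_CRITERIA,
                      probe_tables: dict[str, dict[str, ProbeResult]] | None = None,
                      n_boot: int = 1000, seed: int = 0,
                      threshold_policy: float | str = "f1") -> SelectionReport:
    """Regret of every criterion against the oracle across settings.

    Each setting names an OOD environment, attribute and group pair; the
    performance cutoff and criterion scores are computed on ID validation
    data, the oracle and regrets on the OOD test split.  The bootstrap
    resamples *settings* with replacement (the unit being averaged).
    """
    if not settings:
        raise ValidationError("evaluate_criteria: no settings")
    if n_boot < 1:
        raise ValidationError("evaluate_criteria: n_boot must be >= 1")
    names = [c.name for c in criteria]
    per_setting: dict[str, list[dict]] = {n: [] for n in names}
    skipped: list[dict] = []
    for setting in settings:
        attribute = setting["attribute"]
        pair = tuple(setting["group_pair"])
        tar_env = setting["tar_env"]
        probe_table = (probe_tables or {}).get(attribute)
        try:
            subset = performance_filter(grid)
            score_table = id_score_table(grid, attribute, pair, probe_table,
                                         threshold_policy=threshold_policy)
            gaps = ood_gaps(grid, subset, tar_env, attribute, pair,
                            threshold_policy=threshold_policy)
        except ValidationError as exc:
            logger.warning("evaluate_criteria: setting %r skipped (%s)",
                           setting, exc)
            skipped.append(setting)
            continue
        oracle = oracle_select(subset, gaps, score_table)
        for crit in criteria:
            chosen = apply_criterion(subset, crit, score_table)
            per_setting[crit.name].append({
                "setting": dict(setting), "chosen": chosen,
                "chosen_gap": gaps[chosen], "oracle": oracle,
                "oracle_gap": gaps[oracle],
                "regret": gaps[chosen] - gaps[oracle]})
    n_used = len(next(iter(per_setting.values()))) if names else 0
    if n_used == 0:
        raise ValidationError("evaluate_criteria: every setting was skipped")
    regret_matrix = {n: np.array([row["regret"] for row in per_setting[n]])
                     for n in names}
    mean_regret, ci_low, ci_high = {}, {}, {}
    for n in names:
        r = regret_matrix[n]
        mean_regret[n] = float(r.mean())
        ci_low[n], ci_high[n] = fm.bootstrap_mean_ci(r, n_boot=n_boot, seed=seed)
    wilcoxon = {}
    for na, nb in combinations(names, 2):
        wilcoxon[f"{na} < {nb}"] = compare_criteria(regret_matrix[na],
                                                    regret_matrix[nb])
        wilcoxon[f"{nb} < {na}"] = compare_criteria(regret_matrix[nb],
                                                    regret_matrix[na])
    return SelectionReport(criteria=names, per_setting=per_setting,
                           mean_regret=mean_regret, ci_low=ci_low,
                           ci_high=ci_high, wilcoxon_p=wilcoxon,
                           skipped_settings=skipped, n_boot=n_boot, seed=seed)


def per_algorithm_view(grid: ModelGrid, settings: list[dict],
                       probe_tables: dict[str, dict[str, ProbeResult]] | None = None,
                       n_boot: int = 1000, seed: int = 0,
                       threshold_policy: float | str = "f1") -> SelectionReport:
    """Minimum-ID-gap selection within each algorithm family, vs the oracle.

    The performance cutoff is applied globally; within each algorithm the
    surviving model with the smallest ID fairness gap represents the family,
    and its regret is measured against the *global* oracle per setting.
    """
    algorithms = sorted({e.algorithm for e in grid})
    id_gap_crit = SelectionCriterion("Minimum Fairness Gap", "minimize", "id_gap")
    per_setting: dict[str, list[dict]] = {a: [] for a in algorithms}
    skipped: list[dict] = []
    for setting in settings:
        attribute = setting["attribute"]
        pair = tuple(setting["group_pair"])
        tar_env = setting["tar_env"]
        probe_table = (probe_tables or {}).get(attribute)
        try:
            subset = performance_filter(grid)
            score_table = id_score_table(grid, attribute, pair, probe_table,
                                         threshold_policy=threshold_policy)
            gaps = ood_gaps(grid, subset, tar_env, attribute, pair,
                            threshold_policy=threshold_policy)
        except ValidationError as exc:
            logger.warning("per_algorithm_view: setting %r skipped (%s)",
                           setting, exc)
            skipped.append(setting)
            continue
        oracle = oracle_select(subset, gaps, score_table)
        for algo in algorithms:
            family = [m for m in subset if grid.entries[m].algorithm == algo]
            if not family:
                logger.warning("per_algorithm_view: algorithm %r has no "
                               "surviving model", algo)
                continue
            chosen = apply_criterion(family, id_gap_crit, score_table)
            per_setting[algo].append({
                "setting": dict(setting), "chosen": chosen,
                "chosen_gap": gaps[chosen], "oracle": oracle,
                "oracle_gap": gaps[oracle],
                "regret": gaps[chosen] - gaps[oracle]})
    per_setting = {a: rows for a, rows in per_setting.items() if rows}
    if not per_setting:
        raise ValidationError("per_algorithm_view: nothing evaluated")
    mean_regret, ci_low, ci_high = {}, {}, {}
    for a, rows in per_setting.items():
        r = np.array([row["regret"] for row in rows])
        mean_regret[a] = float(r.mean())
        ci_low[a], ci_high[a] = fm.bootstrap_mean_ci(r, n_boot=n_boot, seed=seed)
    wilcoxon = {}
    for na, nb in combinations(sorted(per_setting), 2):
        ra = np.array([row["regret"] for row in per_setting[na]])
        rb = np.array([row["regret"] for row in per_setting[nb]])
        wilcoxon[f"{na} < {nb}"] = compare_criteria(ra, rb)
        wilcoxon[f"{nb} < {na}"] = compare_criteria(rb, ra)
    return SelectionReport(criteria=sorted(per_setting), per_setting=per_setting,
                           mean_regret=mean_regret, ci_low=ci_low,
                           ci_high=ci_high, wilcoxon_p=wilcoxon,
                           skipped_settings=skipped, n_boot=n_boot, seed=seed)
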