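"""Exact decomposition of an OOD fairness gap into ID gap and shift impacts.

For a metric L_f(g, D) that is an average of a per-sample loss over group
g's conditioning class in environment D (FPR and FNR qualify), the OOD gap
between groups g1 and g2 satisfies the algebraic identity

    L(g1, tar) - L(g2, tar) = [L(g1, src) - L(g2, src)]        # ID gap
                            + [L(g2, src) - L(g2, tar)]        # shift impact on g2
                            - [L(g1, src) - L(g1, tar)]        # shift impact on g1

so an unfair deployment can be attributed to the gap the model already had
at home versus the distribution shift hitting one group harder than the
other.  The identity holds to machine precision whenever all four cells are
defined; the residual is reported for verification.

The model's decision threshold is fixed on the source environment and reused
on the target, so the deployed decision rule is literally the same in both
domains (a re-tune-on-target flag exists for sensitivity analysis).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from . import fairness_metrics as fm
from .grid_store import ModelEntry, ModelGrid, PredictionSet, ValidationError

logger = logging.getLogger("fairshift")


@dataclass
class DecompositionResult:
    """Four-term decomposition of one OOD gap; all rates on [0, 1] scale."""

    metric: str
    group_1: str
    group_2: str
    src_env: str
    tar_env: str
    term_ood_gap: float
    term_id_gap: float
    term_shift_g2: float
    term_shift_g1: float
    residual: float
    threshold: float
    dominant_term: str = ""

    def __post_init__(self) -> None:
        contributions = {"id_gap": abs(self.term_id_gap),
                         "shift_g2": abs(self.term_shift_g2),
                         "shift_g1": abs(self.term_shift_g1)}
        self.dominant_term = max(contributions, key=contributions.get)


def per_group_metric(pred: PredictionSet, attribute: str, group: str,
                     metric: str, threshold: float) -> float:
    """Mean per-sample loss over one group's conditioning class.

    FPR is the mean positive-prediction indicator over true negatives; FNR
    the mean negative-prediction indicator over true positives.  Empty
    conditioning class yields the NaN undefined-marker.
    """
    if metric not in ("fpr", "fnr"):
        raise ValidationError(f"metric must be 'fpr' or 'fnr', got {metric!r}")
    mask = pred.group_values(attribute) == group
    rates = fm.confusion_rates(pred.scores[mask], pred.labels[mask],
                               threshold, group=group)
    return getattr(rates, metric)


def decompose_gap(entry: ModelEntry, attribute: str,
                  group_pair: tuple[str, str], src_env: str, tar_env: str,
                  metric: str | None = None, split: str = "test",
                  threshold_policy: float | str = "f1",
                  retune_on_target: bool = False) -> DecompositionResult:
    """Decompose one model's OOD gap between two groups.

    ``metric`` defaults to the rate implied by the task polarity (FPR for a
    healthy-indicator task, FNR otherwise).  Any undefined (group,
    environment) cell is an error naming that cell.
    """
    g1, g2 = group_pair
    for env in (src_env, tar_env):
        if env not in entry.predictions:
            raise ValidationError(f"model {entry.model_id!r} not evaluated in {env!r}")
    src = entry.predictions[src_env].subset(split=split)
    tar = entry.predictions[tar_env].subset(split=split)
    if metric is None:
        metric = fm.gap_metric_name(src.task_polarity)
    threshold = fm.resolve_threshold(src, threshold_policy)
    tar_threshold = (fm.resolve_threshold(tar, threshold_policy)
                     if retune_on_target else threshold)
    cells = {}
    for env_name, pred, t in (("src", src, threshold), ("tar", tar, tar_threshold)):
        for g in (g1, g2):
            val = per_group_metric(pred, attribute, g, metric, t)
            if not np.isfinite(val):
                raise ValidationError(
                    f"undefined {metric} for cell (group={g!r}, env={env_name})")
            cells[(g, env_name)] = val
    ood_gap = cells[(g1, "tar")] - cells[(g2, "tar")]
    id_gap = cells[(g1, "src")] - cells[(g2, "src")]
    shift_g2 = cells[(g2, "src")] - cells[(g2, "tar")]
    shift_g1 = cells[(g1, "src")] - cells[(g1, "tar")]
    residual = ood_gap - (id_gap + shift_g2 - shift_g1)
    return DecompositionResult(metric=metric, group_1=g1, group_2=g2,
                               src_env=src_env, tar_env=tar_env,
                               term_ood_gap=float(ood_gap),
                               term_id_gap=float(id_gap),
                               term_shift_g2=float(shift_g2),
                               term_shift_g1=float(shift_g1),
                               residual=float(residual),
                               threshold=float(threshold))


def decomposition_table(grid: ModelGrid, settings: list[dict],
                        split: str = "test",
                        threshold_policy: float | str = "f1",
                        ) -> list[tuple[str, dict, DecompositionResult]]:
    """Decompose every (model, setting) pair in the grid.

    Each setting is a dict with keys ``attribute``, ``group_pair`` and
    ``tar_env`` (source defaults to the grid's ID environment).  Settings a
    model was not evaluated under are skipped with a warning.
    """
    rows = []
    for model_id in grid.model_ids():
        entry = grid.entries[model_id]
        for setting in settings:
            src = setting.get("src_env", grid.config.id_environment)
            try:
                res = decompose_gap(entry, setting["attribute"],
                                    tuple(setting["group_pair"]), src,
                                    setting["tar_env"],
                                    metric=setting.get("metric"),
                                    split=split,
                                    threshold_policy=threshold_policy)
            except ValidationError as exc:
                logger.warning("decomposition_table: skipped %r / %r (%s)",
                               model_id, setting, exc)
                continue
            rows.append((model_id, setting, res))
    return rows
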