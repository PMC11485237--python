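"""Linear probing of demographic information in frozen model embeddings.

A multinomial logistic-regression probe is fit on frozen representation
vectors to predict the demographic group.  The L2 regularization strength is
swept over a log-spaced grid spanning 1e-5 to 10 and the strength with the
best macro-averaged one-vs-rest AUROC on the validation split is kept; the
reported encoding measure is the macro AUROC of that probe on the test
split.  Attribute prediction *accuracy* (argmax class) on the same test
split is exposed as well, for accuracy-based model-selection criteria.

Features are standardized with train-split mean/SD before fitting so that a
single regularization grid is comparable across embedding scales.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_auc_score

from .grid_store import EmbeddingSet, ModelGrid, ValidationError

logger = logging.getLogger("fairshift")

#: default L2 strength grid: 7 log-spaced points over [1e-5, 10]
DEFAULT_L2_GRID = tuple(float(x) for x in np.logspace(-5, 1, 7))


@dataclass
class ProbeResult:
    """Outcome of one attribute-encoding probe."""

    attribute: str
    l2_strength: float
    val_macro_auroc: float
    test_macro_auroc: float
    test_accuracy: float
    per_class_auroc: dict[str, float] = field(default_factory=dict)
    classes: tuple[str, ...] = ()
    converged: bool = True


@dataclass
class _FittedProbe:
    model: LogisticRegression
    mean: np.ndarray
    std: np.ndarray
    classes: tuple[str, ...]

    def scores(self, x: np.ndarray) -> np.ndarray:
        return self.model.predict_proba((x - self.mean) / self.std)


def _macro_auroc(y: np.ndarray, proba: np.ndarray,
                 classes: tuple[str, ...]) -> tuple[float, dict[str, float]]:
    per_class: dict[str, float] = {}
    for j, c in enumerate(classes):
        target = (y == c).astype(int)
        if target.min() == target.max():
            logger.info("probe: class %r absent or exhaustive in eval split", c)
            continue
        per_class[c] = float(roc_auc_score(target, proba[:, j]))
    if not per_class:
        raise ValidationError("probe: no class with both positives and negatives")
    return float(np.mean(list(per_class.values()))), per_class


def _fit_one(x: np.ndarray, y: np.ndarray, l2: float, seed: int) -> tuple[LogisticRegression, bool]:
    clf = LogisticRegression(C=1.0 / l2 if l2 > 0 else np.inf,
                             solver="lbfgs", max_iter=1000, random_state=seed)
    converged = True
    with warnings.catch_warnings():
        warnings.simplefilter("error", ConvergenceWarning)
        try:
            clf.fit(x, y)
        except ConvergenceWarning:
            converged = False
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", ConvergenceWarning)
                clf.fit(x, y)
    return clf, converged


def fit_probe(train: EmbeddingSet, train_groups, val: EmbeddingSet, val_groups,
              attribute: str = "attribute",
              l2_grid=DEFAULT_L2_GRID, seed: int = 0,
              ) -> tuple[_FittedProbe, ProbeResult]:
    """Fit the probe over the L2 grid and keep the best-validation strength.

    Returns the fitted probe (with its standardization statistics) and a
    :class:`ProbeResult` whose test fields are NaN until
    :func:`probe_auroc` is applied.
    """
    x_tr = train.vectors
    y_tr = np.asarray(train_groups, dtype=str)
    if len(np.unique(y_tr)) < 2:
        raise ValidationError("fit_probe: need at least 2 classes in train")
    if len(val) == 0:
        raise ValidationError("fit_probe: empty validation set")
    y_val = np.asarray(val_groups, dtype=str)
    mean = x_tr.mean(axis=0)
    std = x_tr.std(axis=0)
    std[std == 0.0] = 1.0
    x_trs = (x_tr - mean) / std
    x_vals = (val.vectors - mean) / std
    best: tuple[float, float, LogisticRegression, bool] | None = None
    for l2 in l2_grid:
        clf, converged = _fit_one(x_trs, y_tr, float(l2), seed)
        classes = tuple(clf.classes_)
        macro, _ = _macro_auroc(y_val, clf.predict_proba(x_vals), classes)
        if best is None or macro > best[0]:
            best = (macro, float(l2), clf, converged)
    val_auroc, l2_star, clf, converged = best
    probe = _FittedProbe(clf, mean, std, tuple(clf.classes_))
    result = ProbeResult(attribute=attribute, l2_strength=l2_star,
                         val_macro_auroc=val_auroc,
                         test_macro_auroc=float("nan"),
                         test_accuracy=float("nan"),
                         classes=probe.classes, converged=converged)
    if not converged:
        logger.warning("fit_probe: solver did not converge at l2=%g", l2_star)
    return probe, result


def probe_auroc(probe: _FittedProbe, test: EmbeddingSet, test_groups,
                result: ProbeResult | None = None) -> float:
    """Macro-averaged one-vs-rest AUROC of a fitted probe on a test split."""
    y = np.asarray(test_groups, dtype=str)
    unseen = set(np.unique(y)) - set(probe.classes)
    if unseen:
        raise ValidationError(f"probe_auroc: unseen classes in test: {sorted(unseen)}")
    proba = probe.scores(test.vectors)
    macro, per_class = _macro_auroc(y, proba, probe.classes)
    if result is not None:
        result.test_macro_auroc = macro
        result.per_class_auroc = per_class
        pred = np.asarray(probe.classes)[np.argmax(proba, axis=1)]
        result.test_accuracy = float((pred == y).mean())
    return macro


def encode_grid(grid: ModelGrid, attribute: str, environment: str | None = None,
                l2_grid=DEFAULT_L2_GRID, seed: int = 0,
                ) -> dict[str, ProbeResult]:
    """Probe every model's embeddings for one attribute.

    Embeddings are taken from the given environment (default: the grid's ID
    environment); the probe trains on the ``train`` split, selects L2 on
    ``val`` and reports on ``test``.  Models without embeddings are skipped
    with a warning.
    """
    env = environment or grid.config.id_environment
    table: dict[str, ProbeResult] = {}
    for model_id in grid.model_ids():
        entry = grid.entries[model_id]
        if env not in entry.embeddings:
            logger.warning("encode_grid: model %r has no embeddings for %r, "
                           "skipped", model_id, env)
            continue
        emb = entry.embeddings[env]
        pred = entry.predictions[env]
        frame = pred.frame
        vectors = emb.aligned_to(frame["sample_id"])
        groups = frame[attribute].astype(str).to_numpy()
        splits = {}
        for split in ("train", "val", "test"):
            m = (frame["split"] == split).to_numpy()
            splits[split] = (EmbeddingSet(frame.loc[m, "sample_id"].to_numpy(),
                                          vectors[m]), groups[m])
        probe, result = fit_probe(*splits["train"], *splits["val"],
                                  attribute=attribute, l2_grid=l2_grid, seed=seed)
        probe_auroc(probe, *splits["test"], result=result)
        table[model_id] = result
    return table
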