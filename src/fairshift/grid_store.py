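"""Data model and file I/O for prediction/embedding grids.

The central containers are :class:`PredictionSet` (per-sample scores, binary
labels and demographic attribute labels for one model on one task in one
environment split) and :class:`ModelGrid` (a collection of models, each
evaluated in one designated in-distribution environment and any number of
out-of-distribution environments).

Prediction tables are UTF-8 delimited text with a header row naming the
required columns (``sample_id, score, label, split, environment, task``) plus
one column per demographic attribute.  Embedding matrices are accepted as
delimited text, or as a little-endian float64 row-major binary file with a
two-int64 header ``(n, d)``.  Reports are JSON; ``NaN`` serializes as ``null``
(the undefined-rate marker, see :mod:`fairshift.fairness_metrics`).
"""

from __future__ import annotations

import dataclasses
import json
import logging
import math
import struct
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("fairshift")

REQUIRED_COLUMNS = ("sample_id", "score", "label", "split", "environment", "task")
SPLITS = ("train", "val", "test")
POLARITIES = ("healthy_indicator", "disease_indicator")

#: separator used to build intersectional attribute names and values
INTERSECTION_SEP = "*"


class SchemaError(ValueError):
    """A table is missing required columns or has malformed structure."""


class ValidationError(ValueError):
    """Row-level content violates an invariant (range, uniqueness, alignment)."""


class AlignmentError(ValueError):
    """Embeddings and prediction rows cannot be matched one-to-one."""


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclass
class AuditConfig:
    """Run configuration shared by the audit pipeline.

    Parameters mirror the statistical protocol: significance level ``alpha``,
    number of equal-width calibration bins, permutation and bootstrap
    replicate counts, the designated ID environment and the OOD environments
    to score against, and the per-attribute group pairs whose error-rate gap
    is audited.
    """

    tasks: tuple[str, ...] = ()
    attributes: tuple[str, ...] = ()
    group_pairs: dict[str, tuple[str, str]] = field(default_factory=dict)
    intersections: tuple[tuple[str, ...], ...] = ()
    id_environment: str = "id"
    ood_environments: tuple[str, ...] = ()
    alpha: float = 0.05
    ece_bins: int = 10
    n_permutations: int = 1000
    n_bootstrap: int = 1000
    performance_cutoff: str = "relative"  # or "absolute"
    performance_margin: float = 0.05
    performance_floor: float = 0.7
    reference_algorithm: str = "erm-like"
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise ValidationError(f"alpha must lie in (0,1), got {self.alpha}")
        for name, val in (("ece_bins", self.ece_bins),
                          ("n_permutations", self.n_permutations),
                          ("n_bootstrap", self.n_bootstrap)):
            if int(val) < 1:
                raise ValidationError(f"{name} must be >= 1, got {val}")
        self.tasks = tuple(self.tasks)
        self.attributes = tuple(self.attributes)
        self.ood_environments = tuple(self.ood_environments)
        self.group_pairs = {k: tuple(v) for k, v in self.group_pairs.items()}
        self.intersections = tuple(tuple(i) for i in self.intersections)

    @classmethod
    def from_file(cls, path: str | Path) -> "AuditConfig":
        """Load a YAML or JSON configuration file."""
        path = Path(path)
        text = path.read_text(encoding="utf-8")
        if path.suffix in (".yml", ".yaml"):
            import yaml

            data = yaml.safe_load(text)
        else:
            data = json.loads(text)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise SchemaError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_dict(self) -> dict[str, Any]:
        return dataclasses.asdict(self)


# ---------------------------------------------------------------------------
# domain containers
# ---------------------------------------------------------------------------

@dataclass
class PredictionSet:
    """Per-sample predictions of one model on one task.

    ``frame`` holds one row per sample with the required columns plus one
    column per attribute; invariants (score range, binary labels, id
    uniqueness within (environment, split)) are enforced at construction.
    """

    frame: pd.DataFrame
    attributes: tuple[str, ...]
    task: str
    task_polarity: str = "disease_indicator"
    n_dropped: int = 0

    def __post_init__(self) -> None:
        self.attributes = tuple(self.attributes)
        if self.task_polarity not in POLARITIES:
            raise ValidationError(
                f"task_polarity must be one of {POLARITIES}, got {self.task_polarity!r}")
        missing = [c for c in REQUIRED_COLUMNS if c not in self.frame.columns]
        if missing:
            raise SchemaError(f"prediction table missing required columns: {missing}")
        for attr in self.attributes:
            if attr not in self.frame.columns:
                raise SchemaError(f"attribute column {attr!r} not in table")
        scores = self.frame["score"].to_numpy(dtype=float)
        bad = np.flatnonzero((scores < 0.0) | (scores > 1.0) | ~np.isfinite(scores))
        if bad.size:
            raise ValidationError(
                f"score outside [0,1] at row index {int(bad[0])} "
                f"(value {scores[bad[0]]!r})")
        labels = self.frame["label"].to_numpy()
        if not np.isin(labels, (0, 1)).all():
            raise ValidationError("labels must be binary 0/1")
        dup = self.frame.duplicated(subset=["environment", "split", "sample_id"])
        if dup.any():
            raise ValidationError(
                f"duplicate sample_id within (environment, split): "
                f"{self.frame.loc[dup, 'sample_id'].iloc[0]!r}")

    # -- accessors ---------------------------------------------------------

    def __len__(self) -> int:
        return len(self.frame)

    @property
    def scores(self) -> np.ndarray:
        return self.frame["score"].to_numpy(dtype=float)

    @property
    def labels(self) -> np.ndarray:
        return self.frame["label"].to_numpy(dtype=int)

    def groups(self, attribute: str) -> list[str]:
        if attribute not in self.attributes:
            raise ValidationError(f"unknown attribute {attribute!r}")
        return sorted(self.frame[attribute].astype(str).unique())

    def group_values(self, attribute: str) -> np.ndarray:
        if attribute not in self.attributes:
            raise ValidationError(f"unknown attribute {attribute!r}")
        return self.frame[attribute].astype(str).to_numpy()

    def subset(self, *, split: str | None = None, environment: str | None = None,
               mask: np.ndarray | None = None) -> "PredictionSet":
        frame = self.frame
        if split is not None:
            frame = frame[frame["split"] == split]
        if environment is not None:
            frame = frame[frame["environment"] == environment]
        if mask is not None:
            frame = frame[np.asarray(mask, dtype=bool)]
        return PredictionSet(frame.reset_index(drop=True), self.attributes,
                             self.task, self.task_polarity)

    def with_intersection(self, parts: Sequence[str]) -> "PredictionSet":
        """Derive a cross-product attribute column (e.g. ``sex*race``)."""
        name = INTERSECTION_SEP.join(parts)
        frame = self.frame.copy()
        frame[name] = frame[list(parts)].astype(str).agg(" ".join, axis=1)
        return PredictionSet(frame, self.attributes + (name,), self.task,
                             self.task_polarity, self.n_dropped)


@dataclass
class EmbeddingSet:
    """Fixed-dimension representation vectors aligned to prediction rows."""

    sample_ids: np.ndarray
    vectors: np.ndarray
    meta: pd.DataFrame | None = None  # optional attribute/split/environment tags

    def __post_init__(self) -> None:
        self.sample_ids = np.asarray(self.sample_ids)
        self.vectors = np.asarray(self.vectors, dtype=float)
        if self.vectors.ndim != 2:
            raise ValidationError("embedding matrix must be 2-D")
        if len(self.sample_ids) != self.vectors.shape[0]:
            raise AlignmentError(
                f"{len(self.sample_ids)} ids but {self.vectors.shape[0]} embedding rows")
        if len(set(map(str, self.sample_ids))) != len(self.sample_ids):
            raise ValidationError("duplicate sample_id in embedding set")
        if not np.isfinite(self.vectors).all():
            raise ValidationError("embedding matrix contains non-finite entries")

    def __len__(self) -> int:
        return self.vectors.shape[0]

    @property
    def dim(self) -> int:
        return self.vectors.shape[1]

    def aligned_to(self, ids: Sequence[str]) -> np.ndarray:
        """Return vectors reordered to match ``ids`` exactly."""
        index = {str(s): i for i, s in enumerate(self.sample_ids)}
        try:
            rows = [index[str(s)] for s in ids]
        except KeyError as exc:
            raise AlignmentError(f"sample_id {exc.args[0]!r} has no embedding") from None
        if len(ids) != len(self.sample_ids):
            raise AlignmentError(
                f"id list length {len(ids)} != embedding rows {len(self.sample_ids)}")
        return self.vectors[rows]


@dataclass
class ModelEntry:
    """One model of the grid: tags plus per-environment predictions/embeddings."""

    model_id: str
    algorithm: str = "unknown"
    hparams: str = "default"
    seed: int = 0
    predictions: dict[str, PredictionSet] = field(default_factory=dict)
    embeddings: dict[str, EmbeddingSet] = field(default_factory=dict)


@dataclass
class ModelGrid:
    """A collection of models evaluated over shared environments."""

    entries: dict[str, ModelEntry]
    config: AuditConfig

    def __post_init__(self) -> None:
        for mid, entry in self.entries.items():
            if self.config.id_environment not in entry.predictions:
                raise ValidationError(
                    f"model {mid!r} lacks the ID environment "
                    f"{self.config.id_environment!r}")

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self) -> Iterable[ModelEntry]:
        return iter(self.entries.values())

    def model_ids(self) -> list[str]:
        return sorted(self.entries)

    def by_tags(self) -> dict[tuple[str, str, int], str]:
        return {(e.algorithm, e.hparams, e.seed): e.model_id
                for e in self.entries.values()}


# ---------------------------------------------------------------------------
# loading
# ---------------------------------------------------------------------------

def load_prediction_table(path: str | Path, config: AuditConfig,
                          attributes: Sequence[str] | None = None,
                          task_polarity: str | None = None,
                          delimiter: str = ",") -> PredictionSet:
    """Read and validate a delimited prediction table.

    Rows with a missing value in any attribute column are dropped and
    counted (``n_dropped``); an out-of-range score is a hard error naming the
    offending row.  Intersections configured in ``config.intersections`` are
    derived as cross-product columns at load time.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    attributes = tuple(attributes if attributes is not None else config.attributes)
    frame = pd.read_csv(path, sep=delimiter, dtype={"sample_id": str})
    missing = [c for c in (*REQUIRED_COLUMNS, *attributes) if c not in frame.columns]
    if missing:
        raise SchemaError(f"{path}: missing required columns {missing}")
    n0 = len(frame)
    if attributes:
        frame = frame.dropna(subset=list(attributes))
    n_dropped = n0 - len(frame)
    if n_dropped:
        logger.info("%s: dropped %d rows with missing attribute values", path, n_dropped)
    frame = frame.reset_index(drop=True)
    task = str(frame["task"].iloc[0]) if len(frame) else ""
    if task_polarity is None:
        task_polarity = ("healthy_indicator" if task.lower().replace(" ", "_")
                         in ("no_finding", "nofinding", "healthy") else "disease_indicator")
    pred = PredictionSet(frame, attributes, task, task_polarity, n_dropped)
    for parts in config.intersections:
        if set(parts) <= set(attributes):
            pred = pred.with_intersection(parts)
    return pred


def load_embedding_matrix(path: str | Path, ids: Sequence[str],
                          delimiter: str = ",") -> EmbeddingSet:
    """Read an embedding matrix (text or documented binary) aligned to ``ids``.

    The binary format is two little-endian int64 (n, d) followed by n*d
    little-endian float64, row major.
    """
    path = Path(path)
    if path.suffix == ".bin":
        raw = path.read_bytes()
        n, d = struct.unpack("<2q", raw[:16])
        expect = 16 + 8 * n * d
        if len(raw) != expect:
            raise SchemaError(f"{path}: binary size {len(raw)} != header promise {expect}")
        mat = np.frombuffer(raw, dtype="<f8", offset=16).reshape(n, d)
    else:
        rows = []
        width = None
        with open(path, "r", encoding="utf-8") as fh:
            for lineno, line in enumerate(fh, start=1):
                line = line.strip()
                if not line:
                    continue
                vals = line.split(delimiter)
                if width is None:
                    width = len(vals)
                elif len(vals) != width:
                    raise SchemaError(
                        f"{path}: ragged row at line {lineno} "
                        f"({len(vals)} fields, expected {width})")
                rows.append([float(v) for v in vals])
        mat = np.asarray(rows, dtype=float)
    if mat.shape[0] != len(ids):
        raise AlignmentError(
            f"{path}: {mat.shape[0]} embedding rows for {len(ids)} sample ids")
    if not np.isfinite(mat).all():
        raise ValidationError(f"{path}: embedding matrix contains NaN/inf")
    return EmbeddingSet(np.asarray(list(ids)), mat)


def assemble_grid(entries: Sequence[ModelEntry], config: AuditConfig) -> ModelGrid:
    """Index model entries into a grid, checking coverage and uniqueness."""
    if not entries:
        raise ValidationError("assemble_grid requires at least one entry")
    index: dict[str, ModelEntry] = {}
    for entry in entries:
        if entry.model_id in index:
            raise ValidationError(f"duplicate model_id {entry.model_id!r}")
        index[entry.model_id] = entry
    return ModelGrid(index, config)


# ---------------------------------------------------------------------------
# report serialization
# ---------------------------------------------------------------------------

def _jsonable(obj: Any) -> Any:
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return _jsonable(dataclasses.asdict(obj))
    if isinstance(obj, Mapping):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple, set)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating, float)):
        f = float(obj)
        if math.isnan(f):
            logger.warning("NaN in report serialized as null")
            return None
        return f
    if isinstance(obj, np.ndarray):
        return _jsonable(obj.tolist())
    if isinstance(obj, np.bool_):
        return bool(obj)
    return obj


def write_report(report: Any, path: str | Path, *,
                 config: AuditConfig | None = None,
                 provenance: Mapping[str, Any] | None = None) -> None:
    """Serialize a report (dataclass or mapping) to round-trippable JSON.

    A config echo and a provenance block (seeds etc.) are embedded so a
    report file is self-describing.  NaN values serialize as ``null``.
    """
    body: dict[str, Any] = {"report": _jsonable(report)}
    if config is not None:
        body["config"] = _jsonable(config.to_dict())
    if provenance is not None:
        body["provenance"] = _jsonable(dict(provenance))
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(body, indent=2, sort_keys=True, allow_nan=False) + "\n",
                    encoding="utf-8")


def read_report(path: str | Path) -> dict[str, Any]:
    return json.loads(Path(path).read_text(encoding="utf-8"))
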