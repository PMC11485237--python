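"""Seeded generator of synthetic model grids with known ground truth.

The generator emulates, at desk scale, the statistical structure of a
clinical imaging audit: demographic groups with group-conditional disease
prevalence P(Y|A), group-structured representations P(X|A), a grid of
classifiers varying in how much they rely on the demographic "shortcut",
and multiple environments whose prevalence and representation geometry
shift between training (ID) and deployment (OOD).

The data model is a two-axis Gaussian representation: a unit disease axis
``u`` and an orthogonal unit attribute axis ``v``.  A sample with outcome
``Y`` in group ``a`` has representation

    z = Y * beta_y * u + kappa_e * c_a * v + eps,   eps ~ N(0, sigma^2 I_d)

where ``kappa_e`` (per environment) scales how separated the groups are in
representation space and ``c_a`` is the group's signed coefficient (+-1 for
binary groups).  A synthetic model with shortcut-reliance angle ``theta``
scores along ``w = cos(theta) u + sin(theta) v``:

    score = logistic(gamma * (w . z + b))

so ``theta = 0`` ignores the attribute entirely (its error-rate gaps are
zero in *every* environment, no matter the shift) and ``theta = pi/2`` is a
pure shortcut.  Because ``w . z | (Y, A) ~ N(Y beta cos t + kappa c_a sin t,
sigma^2)``, per-group FPR/FNR at a linear threshold have Gaussian closed
forms (:func:`analytic_group_rates`), which serve as the binding oracle for
the empirical metric pipeline.

Each model also emits a 2-D embedding ``[w . z, eta * (v . z)] + noise``:
``eta`` controls how much attribute information the representation leaks,
which is what the linear probe measures.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm

from .grid_store import (AuditConfig, EmbeddingSet, ModelEntry, ModelGrid,
                         PredictionSet, ValidationError, assemble_grid)


@dataclass
class EnvironmentSpec:
    """One environment: group mix, per-group prevalence, attribute separation."""

    pi: tuple[float, ...]      # group proportions, sums to 1
    rho: tuple[float, ...]     # P(Y=1 | A=a) per group
    kappa: float               # attribute separation along v

    def __post_init__(self) -> None:
        if abs(sum(self.pi) - 1.0) > 1e-9:
            raise ValidationError(f"group proportions must sum to 1, got {self.pi}")
        if not all(0.0 <= r <= 1.0 for r in self.rho):
            raise ValidationError(f"prevalences must be in [0,1], got {self.rho}")


@dataclass
class SyntheticScenario:
    """Full specification of groups, environments and representation geometry."""

    name: str
    groups: tuple[str, ...]
    environments: dict[str, EnvironmentSpec]
    id_environment: str
    attribute: str = "group"
    task: str = "disease"
    task_polarity: str = "disease_indicator"
    d: int = 16
    beta_y: float = 1.5
    sigma: float = 1.0
    attr_coef: dict[str, float] = field(default_factory=dict)
    n_samples: dict[str, dict[str, int]] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise ValidationError("sigma must be positive")
        if self.id_environment not in self.environments:
            raise ValidationError(f"unknown ID environment {self.id_environment!r}")
        if not self.attr_coef:
            if len(self.groups) == 2:
                self.attr_coef = {self.groups[0]: -1.0, self.groups[1]: +1.0}
            else:  # multi-group: evenly spaced attribute means on [-1, 1]
                coords = np.linspace(-1.0, 1.0, len(self.groups))
                self.attr_coef = {g: float(c) for g, c in zip(self.groups, coords)}

    # canonical orthonormal axes: u = e0 (disease), v = e1 (attribute)
    @property
    def u(self) -> np.ndarray:
        vec = np.zeros(self.d)
        vec[0] = 1.0
        return vec

    @property
    def v(self) -> np.ndarray:
        vec = np.zeros(self.d)
        vec[1] = 1.0
        return vec

    def split_sizes(self, environment: str) -> dict[str, int]:
        if environment in self.n_samples:
            return self.n_samples[environment]
        return self.n_samples.get("default", {"test": 2000})


@dataclass
class SyntheticModel:
    """A linear scorer with shortcut-reliance angle theta and leak eta."""

    model_id: str
    theta: float               # in [0, pi/2]
    eta: float = 0.0           # attribute leak into the emitted embedding
    gamma: float = 2.0         # logistic scale
    intercept: float = -0.75   # b, on the linear-score scale
    algorithm: str = "unknown"
    hparams: str = "default"
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.theta <= math.pi / 2 + 1e-12:
            raise ValidationError(f"theta must be in [0, pi/2], got {self.theta}")
        if self.eta < 0:
            raise ValidationError(f"eta must be >= 0, got {self.eta}")

    def direction(self, scenario: SyntheticScenario) -> np.ndarray:
        return math.cos(self.theta) * scenario.u + math.sin(self.theta) * scenario.v

    def probability_threshold(self, linear_t: float) -> float:
        """Probability-scale threshold equivalent to linear ``w.z >= t``."""
        return float(1.0 / (1.0 + np.exp(-self.gamma * (linear_t + self.intercept))))


# ---------------------------------------------------------------------------
# sampling and scoring
# ---------------------------------------------------------------------------

def sample_environment(scenario: SyntheticScenario, environment: str, n: int,
                       seed: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Draw (A, Y, z) for ``n`` samples of one environment; seed-deterministic."""
    if environment not in scenario.environments:
        raise ValidationError(f"unknown environment {environment!r}")
    if n < 1:
        raise ValidationError("n must be >= 1")
    env = scenario.environments[environment]
    rng = np.random.default_rng(seed)
    a_idx = rng.choice(len(scenario.groups), size=n, p=np.asarray(env.pi))
    groups = np.asarray(scenario.groups)[a_idx]
    rho = np.asarray(env.rho)[a_idx]
    y = (rng.random(n) < rho).astype(int)
    coef = np.asarray([scenario.attr_coef[g] for g in groups])
    z = (np.outer(y * scenario.beta_y, scenario.u)
         + np.outer(env.kappa * coef, scenario.v)
         + rng.normal(0.0, scenario.sigma, size=(n, scenario.d)))
    return groups, y, z


def score_model(model: SyntheticModel, scenario: SyntheticScenario,
                z: np.ndarray) -> np.ndarray:
    """Predicted probability: logistic(gamma * (w . z + b))."""
    z = np.atleast_2d(np.asarray(z, dtype=float))
    if z.shape[1] != scenario.d:
        raise ValidationError(f"z has dimension {z.shape[1]}, expected {scenario.d}")
    lin = z @ model.direction(scenario) + model.intercept
    return 1.0 / (1.0 + np.exp(-model.gamma * lin))


def model_embedding(model: SyntheticModel, scenario: SyntheticScenario,
                    z: np.ndarray, seed: int,
                    noise_sd: float = 0.5) -> np.ndarray:
    """The model's emitted 2-D representation: [w.z, eta*(v.z)] + noise.

    The additive noise models non-demographic nuisance variation in the
    representation; the probe's view of the leak is graded by the ratio of
    ``eta`` to this floor rather than saturating at any nonzero ``eta``.
    """
    rng = np.random.default_rng(seed)
    z = np.atleast_2d(np.asarray(z, dtype=float))
    emb = np.column_stack([z @ model.direction(scenario),
                           model.eta * (z @ scenario.v)])
    return emb + rng.normal(0.0, noise_sd, size=emb.shape)


def analytic_group_rates(scenario: SyntheticScenario, environment: str,
                         model: SyntheticModel, linear_threshold: float,
                         ) -> dict[str, dict[str, float]]:
    """Closed-form per-group FPR/FNR at a linear-score threshold.

    With w.z | (Y, A=a) ~ N(Y beta cos(theta) + kappa c_a sin(theta),
    sigma^2):

        FPR_a = Phi((kappa c_a sin(theta) - t) / sigma)
        FNR_a = Phi((t - beta cos(theta) - kappa c_a sin(theta)) / sigma)

    The binding oracle for the empirical confusion-rate pipeline.
    """
    if len(scenario.groups) != 2:
        raise ValidationError("closed forms require binary groups")
    env = scenario.environments[environment]
    s, c = math.sin(model.theta), math.cos(model.theta)
    out = {}
    for g in scenario.groups:
        shift = env.kappa * scenario.attr_coef[g] * s
        fpr = norm.cdf((shift - linear_threshold) / scenario.sigma)
        fnr = norm.cdf((linear_threshold - scenario.beta_y * c - shift)
                       / scenario.sigma)
        out[g] = {"fpr": float(fpr), "fnr": float(fnr)}
    return out


# ---------------------------------------------------------------------------
# zoo assembly
# ---------------------------------------------------------------------------

def make_model_zoo(scenario: SyntheticScenario, models: list[SyntheticModel],
                   seed: int | None = None,
                   embedding_noise: float = 0.5) -> ModelGrid:
    """Build a full ModelGrid: shared environment samples, per-model outputs.

    Every model scores the *same* samples of each environment (as in a real
    audit, where one evaluation set is scored by many models).  The ID
    environment carries train/val/test splits; other environments carry the
    splits configured in the scenario (test only, by default).
    """
    if len(models) < 2:
        raise ValidationError("make_model_zoo: need at least 2 models")
    seed = scenario.seed if seed is None else seed
    config = AuditConfig(
        tasks=(scenario.task,), attributes=(scenario.attribute,),
        group_pairs={scenario.attribute: (scenario.groups[0], scenario.groups[1])},
        id_environment=scenario.id_environment,
        ood_environments=tuple(e for e in scenario.environments
                               if e != scenario.id_environment),
        seed=seed)
    env_names = sorted(scenario.environments)
    samples: dict[tuple[str, str], tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
    for ei, env in enumerate(env_names):
        for si, split in enumerate(("train", "val", "test")):
            n = scenario.split_sizes(env).get(split, 0)
            if n:
                samples[(env, split)] = sample_environment(
                    scenario, env, n, seed=[seed, 11, ei, si])
    entries = []
    for mi, model in enumerate(models):
        predictions: dict[str, PredictionSet] = {}
        embeddings: dict[str, EmbeddingSet] = {}
        for env in env_names:
            frames = []
            vecs = []
            ids = []
            for split in ("train", "val", "test"):
                if (env, split) not in samples:
                    continue
                groups, y, z = samples[(env, split)]
                sample_ids = [f"{env}-{split}-{i}" for i in range(len(y))]
                frames.append(pd.DataFrame({
                    "sample_id": sample_ids,
                    "score": score_model(model, scenario, z),
                    "label": y,
                    "split": split,
                    "environment": env,
                    "task": scenario.task,
                    scenario.attribute: groups}))
                ei, si = env_names.index(env), ("train", "val", "test").index(split)
                vecs.append(model_embedding(model, scenario, z,
                                            seed=[seed, 13, ei, si, mi],
                                            noise_sd=embedding_noise))
                ids.extend(sample_ids)
            if not frames:
                continue
            frame = pd.concat(frames, ignore_index=True)
            predictions[env] = PredictionSet(frame, (scenario.attribute,),
                                             scenario.task, scenario.task_polarity)
            embeddings[env] = EmbeddingSet(np.asarray(ids), np.vstack(vecs))
        entries.append(ModelEntry(model.model_id, model.algorithm, model.hparams,
                                  model.seed, predictions, embeddings))
    return assemble_grid(entries, config)


# ---------------------------------------------------------------------------
# canned scenarios
# ---------------------------------------------------------------------------

@dataclass
class CannedScenario:
    """A ready-to-run study: scenario, model zoo and evaluation settings."""

    scenario: SyntheticScenario
    models: list[SyntheticModel]
    settings: list[dict]

    def build(self, seed: int | None = None) -> ModelGrid:
        return make_model_zoo(self.scenario, self.models, seed=seed)


def _sweep_models(thetas, eta_scale: float, gamma: float, intercept: float,
                  tag_rule) -> list[SyntheticModel]:
    models = []
    for k, theta in enumerate(thetas):
        models.append(SyntheticModel(
            model_id=f"m{k:02d}", theta=float(theta),
            eta=eta_scale * math.sin(float(theta)),
            gamma=gamma, intercept=intercept,
            algorithm=tag_rule(float(theta)), seed=k))
    return models


def canned_scenarios() -> dict[str, CannedScenario]:
    """The three shipped studies.

    S1 (encoding vs unfairness): one environment with unequal per-group
    prevalence and a joint (theta, eta) model sweep; exercises the
    encoding-gap correlation.

    S2 (fairness non-transfer): source environment where the shortcut is
    informative, target environment with the attribute geometry flipped and
    prevalences reversed; exercises transfer correlations, front transfer
    and the gap decomposition.

    S3 (selection): S2's deception sharpened -- the source carries only a
    faint attribute separation (ID gaps are weakly informative) while the
    emitted embeddings leak the attribute strongly, and 12 target
    environments vary prevalence and representation shifts; exercises
    oracle-regret criterion comparison.
    """
    def tag(theta: float) -> str:
        if theta < 0.6:
            return "debiased-like"
        if theta < 1.0:
            return "midline"
        return "erm-like"

    s1 = SyntheticScenario(
        name="S1", groups=("group_a", "group_b"),
        environments={"source": EnvironmentSpec(pi=(0.5, 0.5), rho=(0.15, 0.45),
                                                kappa=1.0)},
        id_environment="source",
        n_samples={"source": {"train": 2000, "val": 1000, "test": 2000}},
        seed=101)
    s1_models = _sweep_models(np.linspace(0.0, 1.2, 24), eta_scale=1.5,
                              gamma=2.0, intercept=-0.75, tag_rule=tag)
    s1_settings = [{"attribute": "group", "group_pair": ("group_a", "group_b"),
                    "tar_env": "source"}]

    s2 = SyntheticScenario(
        name="S2", groups=("group_a", "group_b"),
        environments={
            "source": EnvironmentSpec(pi=(0.5, 0.5), rho=(0.1, 0.5), kappa=0.8),
            "target": EnvironmentSpec(pi=(0.5, 0.5), rho=(0.5, 0.1), kappa=-0.5),
        },
        id_environment="source",
        n_samples={"source": {"train": 2000, "val": 1500, "test": 2000},
                   "default": {"test": 2000}},
        seed=202)
    s2_models = _sweep_models(np.linspace(0.0, 1.4, 24), eta_scale=1.5,
                              gamma=2.0, intercept=-0.75, tag_rule=tag)
    s2_settings = [{"attribute": "group", "group_pair": ("group_a", "group_b"),
                    "tar_env": "target"}]

    # S3 reuses S2's source environment (informative shortcut) and fans out
    # twelve target environments over representation- and prevalence-shift levels
    s3_envs = {"source": EnvironmentSpec(pi=(0.5, 0.5), rho=(0.1, 0.5),
                                         kappa=0.8)}
    s3_settings = []
    i = 0
    for kappa in (-0.8, -0.5, 0.5, 0.8):
        for rho in ((0.15, 0.45), (0.45, 0.15), (0.3, 0.3)):
            name = f"shift_{i:02d}"
            s3_envs[name] = EnvironmentSpec(pi=(0.5, 0.5), rho=rho, kappa=kappa)
            s3_settings.append({"attribute": "group",
                                "group_pair": ("group_a", "group_b"),
                                "tar_env": name})
            i += 1
    s3 = SyntheticScenario(
        name="S3", groups=("group_a", "group_b"), environments=s3_envs,
        id_environment="source",
        n_samples={"source": {"train": 2000, "val": 1500, "test": 2000},
                   "default": {"test": 1500}},
        seed=303)
    # one strictly shortcut-free model; the rest sweep upward from theta=0.35
    s3_thetas = np.concatenate([[0.0], np.linspace(0.35, 1.5, 23)])
    s3_models = _sweep_models(s3_thetas, eta_scale=1.5, gamma=2.0,
                              intercept=-0.75, tag_rule=tag)

    return {"S1": CannedScenario(s1, s1_models, s1_settings),
            "S2": CannedScenario(s2, s2_models, s2_settings),
            "S3": CannedScenario(s3, s3_models, s3_settings)}
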