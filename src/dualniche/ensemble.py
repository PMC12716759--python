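"""Four-member tree ensemble for habitat suitability.

Two random forests and two gradient-boosted tree models, each at a
"simple" (shallow, heavily regularised) and an "intermediate" (deeper,
more estimators) complexity, are fitted to presence / pseudo-absence
tables. The habitat-suitability index of a cell is the mean of the four
members' presence probabilities; across repeated spatial-CV iterations
the per-iteration surfaces are averaged again into the final map.
Categorical soil codes are fed as plain integer features — tree models
split on them directly without one-hot encoding.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from sklearn.ensemble import GradientBoostingClassifier, RandomForestClassifier

from .geodata import EnvStack, OccurrenceSet, RasterGrid, PRESENCE
from .metrics import MetricsReport, boyce_index, evaluate
from .pseudoabs import (environmental_profile_mask, kmeans_eligibility,
                        sample_pseudo_absences)
from .spatialcv import CVPlan

RANDOM_FOREST = "random_forest"
GRADIENT_BOOSTED_TREES = "gradient_boosted_trees"


@dataclass(frozen=True)
class ModelConfig:
    algorithm: str
    complexity: str  # "simple" | "interm"
    trees: int
    max_depth: int | None
    min_leaf: int = 1
    learning_rate: float | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.algorithm not in (RANDOM_FOREST, GRADIENT_BOOSTED_TREES):
            raise ValueError(f"unknown algorithm {self.algorithm!r}")
        if self.algorithm == RANDOM_FOREST and self.learning_rate is not None:
            raise ValueError("learning_rate applies to boosting only")

    @property
    def name(self) -> str:
        prefix = "RF" if self.algorithm == RANDOM_FOREST else "GBDT"
        return f"{prefix}_{self.complexity}"


def default_model_configs(seed: int = 0) -> list[ModelConfig]:
    """The simple-vs-intermediate RF/GBDT quartet."""
    return [
        ModelConfig(RANDOM_FOREST, "simple", trees=100, max_depth=6, min_leaf=10,
                    seed=seed),
        ModelConfig(RANDOM_FOREST, "interm", trees=300, max_depth=None, min_leaf=2,
                    seed=seed + 1),
        ModelConfig(GRADIENT_BOOSTED_TREES, "simple", trees=100, max_depth=2,
                    learning_rate=0.1, seed=seed + 2),
        ModelConfig(GRADIENT_BOOSTED_TREES, "interm", trees=400, max_depth=4,
                    learning_rate=0.05, seed=seed + 3),
    ]


def fit_member(config: ModelConfig, train: pd.DataFrame,
               feature_names: list[str]):
    """Fit one classifier on a labelled sample table (label column holds
    presence / pseudo_absence strings)."""
    y = (train["label"] == PRESENCE).astype(int).to_numpy()
    if y.min() == y.max():
        raise ValueError("training data contains a single class")
    X = train[feature_names].to_numpy(float)
    if config.algorithm == RANDOM_FOREST:
        model = RandomForestClassifier(
            n_estimators=config.trees, max_depth=config.max_depth,
            min_samples_leaf=config.min_leaf, random_state=config.seed, n_jobs=1)
    else:
        model = GradientBoostingClassifier(
            n_estimators=config.trees, max_depth=config.max_depth,
            learning_rate=config.learning_rate or 0.1,
            min_samples_leaf=config.min_leaf, random_state=config.seed)
    model.fit(X, y)
    return model


@dataclass
class FittedEnsemble:
    """Exactly four fitted members sharing one feature set; predictions are
    their mean presence probability."""

    members: list
    feature_names: list[str]
    configs: list[ModelConfig] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(self.members) != 4:
            raise ValueError("ensemble requires exactly 4 members")

    def predict(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, float)
        probs = [m.predict_proba(X)[:, 1] for m in self.members]
        return np.mean(probs, axis=0)

    def member_predict(self, i: int, X: np.ndarray) -> np.ndarray:
        return self.members[i].predict_proba(np.asarray(X, float))[:, 1]


def fit_ensemble(configs: list[ModelConfig], train: pd.DataFrame,
                 feature_names: list[str]) -> FittedEnsemble:
    members = [fit_member(c, train, feature_names) for c in configs]
    return FittedEnsemble(members=members, feature_names=feature_names,
                          configs=list(configs))


def predict_surface(model, stack: EnvStack,
                    feature_names: list[str] | None = None) -> RasterGrid:
    """Predict a [0, 1] suitability surface over the stack's valid cells;
    nodata propagates from any feature layer."""
    if feature_names is None:
        feature_names = getattr(model, "feature_names", None)
        if feature_names is None:
            raise ValueError("feature_names required for bare models")
    missing = [n for n in feature_names if n not in stack]
    if missing:
        raise ValueError(f"stack is missing feature layers: {missing}")
    sub = stack.subset(feature_names)
    valid = ~sub.combined_nodata()
    X = np.column_stack([sub[n].values[valid].astype(float) for n in feature_names])
    if hasattr(model, "predict") and isinstance(model, FittedEnsemble):
        p = model.predict(X)
    elif hasattr(model, "predict_proba"):
        p = model.predict_proba(X)[:, 1]
    else:
        p = np.asarray(model.predict(X), float)
    surface = np.zeros(sub.geometry.shape)
    surface[valid] = p
    return RasterGrid(surface, sub.geometry, nodata_mask=~valid)


@dataclass
class PseudoAbsenceSettings:
    envelope_quantiles: tuple[float, float] = (0.05, 0.95)
    k: int = 8
    runs: int = 5
    presence_poor_quantile: float = 0.25


@dataclass
class IterationResult:
    metrics: MetricsReport
    threshold: float
    ensemble: FittedEnsemble
    surface: RasterGrid


@dataclass
class RunResult:
    mean_surface: RasterGrid
    iterations: list[IterationResult]

    @property
    def thresholds(self) -> list[float]:
        return [it.threshold for it in self.iterations]

    @property
    def mean_threshold(self) -> float:
        return float(np.mean(self.thresholds))

    @property
    def metrics_list(self) -> list[MetricsReport]:
        return [it.metrics for it in self.iterations]

    def metrics_table(self) -> pd.DataFrame:
        rows = []
        for i, it in enumerate(self.iterations):
            m = it.metrics
            rows.append({"iteration": i, "auc": m.auc, "tss": m.tss,
                         "sensitivity": m.sensitivity, "specificity": m.specificity,
                         "precision": m.precision, "boyce": m.boyce,
                         "threshold": m.threshold})
        df = pd.DataFrame(rows)
        summary = df.drop(columns="iteration").agg(["mean", "std"])
        summary.insert(0, "iteration", ["mean", "sd"])
        return pd.concat([df, summary], ignore_index=True)


def _partition_pseudo_absences(masks, profile_only, count, seed, block_ids, blocks,
                               species_id):
    """Balanced draw for one partition: from the dual-filter intersection
    within the partition's blocks, topped up from the envelope-only mask
    there when the intersection is too small (autocorrelated landscapes can
    leave whole block sets without dual-eligible cells)."""
    try:
        return sample_pseudo_absences(masks, count, seed, block_ids=block_ids,
                                      restrict_blocks=blocks, species_id=species_id)
    except ValueError:
        return sample_pseudo_absences([profile_only], count, seed,
                                      block_ids=block_ids, restrict_blocks=blocks,
                                      species_id=species_id)


def run_iterations(stack: EnvStack, presences: OccurrenceSet, cvplan: CVPlan,
                   configs: list[ModelConfig],
                   feature_sets: dict[str, list[str]],
                   pa_settings: PseudoAbsenceSettings | None = None,
                   seed: int = 0, compute_boyce: bool = True
                   ) -> dict[str, RunResult]:
    """Repeated spatially blocked training/prediction.

    Per iteration: draw one balanced presence / pseudo-absence training set
    (pseudo-absence counts equal the presence counts of the training and
    validation block sets, sampled from the dual-filtered eligibility over
    the FULL environmental space), then fit one 4-member ensemble per entry
    of ``feature_sets`` — e.g. a climate model and a soil model — on the
    same points, evaluate each on the validation blocks (AUC, TSS,
    sensitivity, specificity, precision, Boyce on validation presences) and
    record each model's optimal threshold. Final surfaces are cellwise
    means over completed iterations.
    """
    if len(presences.presences()) < 10:
        raise ValueError("need at least 10 presences")
    pa_settings = pa_settings or PseudoAbsenceSettings()
    presences = presences.presences()
    geometry = stack.geometry
    rng = np.random.default_rng(seed)

    profile = environmental_profile_mask(stack, presences,
                                         pa_settings.envelope_quantiles)
    kmask = kmeans_eligibility(stack, presences, k=pa_settings.k,
                               runs=pa_settings.runs,
                               presence_poor_quantile=pa_settings.presence_poor_quantile,
                               seed=int(rng.integers(2**31 - 1)))
    masks = [profile, kmask]

    pr, pc = presences.cell_indices(geometry)
    pres_block = cvplan.block_ids.values[pr, pc]
    sp = str(presences.species_id[0]) if len(presences) else "species"

    results: dict[str, list[IterationResult]] = {k: [] for k in feature_sets}
    surf_sum: dict[str, np.ndarray] = {}
    from .geodata import extract_env  # local import avoids cycle at module load

    for it in cvplan.iterations:
        it_rng = np.random.default_rng(it.seed)
        in_train = np.isin(pres_block, it.train_blocks)
        in_valid = np.isin(pres_block, it.valid_blocks)
        if in_train.sum() < 2 or in_valid.sum() < 2:
            warnings.warn("iteration skipped: too few presences in a partition")
            continue
        try:
            pa_train = _partition_pseudo_absences(
                masks, profile, int(in_train.sum()), int(it_rng.integers(2**31 - 1)),
                cvplan.block_ids, it.train_blocks, sp)
            pa_valid = _partition_pseudo_absences(
                masks, profile, int(in_valid.sum()), int(it_rng.integers(2**31 - 1)),
                cvplan.block_ids, it.valid_blocks, sp)
        except ValueError as exc:
            warnings.warn(f"iteration skipped: {exc}")
            continue

        train_tbl, _ = extract_env(presences.select(in_train).concat(pa_train), stack)
        valid_tbl, _ = extract_env(presences.select(in_valid).concat(pa_valid), stack)
        if train_tbl["label"].nunique() < 2 or valid_tbl["label"].nunique() < 2:
            warnings.warn("iteration skipped: single-class partition")
            continue
        labels = (valid_tbl["label"] == PRESENCE).astype(int).to_numpy()

        for key, feature_names in feature_sets.items():
            fitted = fit_ensemble(configs, train_tbl, feature_names)
            surface = predict_surface(fitted, stack, feature_names)
            scores = fitted.predict(valid_tbl[feature_names].to_numpy(float))
            boyce = None
            if compute_boyce and labels.sum() >= 20:
                boyce = boyce_index(surface, scores[labels == 1])
            report = evaluate(scores, labels, boyce=boyce)
            results[key].append(IterationResult(
                metrics=report, threshold=report.threshold, ensemble=fitted,
                surface=surface))
            surf_sum[key] = (surface.values.copy() if key not in surf_sum
                             else surf_sum[key] + surface.values)

    out: dict[str, RunResult] = {}
    for key in feature_sets:
        if not results[key]:
            raise ValueError("no iteration completed")
        mean_vals = surf_sum[key] / len(results[key])
        mean_surface = RasterGrid(mean_vals, geometry,
                                  nodata_mask=results[key][0].surface.nodata_mask.copy())
        out[key] = RunResult(mean_surface=mean_surface, iterations=results[key])
    return out
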