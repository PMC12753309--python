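"""KNN/RF cross-validation and modern-to-ancient transfer functions.

Models are trained on either the transformed composition matrix (all
features) or a 2-D ordination embedding, using a 60-40 train-test split
with repeated 10-fold cross-validation for hyperparameter tuning inside
the training partition. A transfer function is a model trained only on
the modern samples of a dataset and evaluated on its (degraded) ancient
samples; for ordination features, modern and ancient samples are embedded
jointly so that both acquire coordinates in the same space.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.ensemble import RandomForestClassifier, RandomForestRegressor
from sklearn.metrics import accuracy_score, mean_squared_error
from sklearn.model_selection import (GridSearchCV, RepeatedKFold,
                                     RepeatedStratifiedKFold, train_test_split)
from sklearn.neighbors import KNeighborsClassifier, KNeighborsRegressor
from statsmodels.stats.multicomp import pairwise_tukeyhsd

from .benchmark import GridCombo, compute_distance, default_compatibility
from .datatypes import CommunityDataset
from .degradation import DegradationPlan
from .ordination import OrdinationOptions, ordinate

logger = logging.getLogger(__name__)


@dataclass
class MLConfig:
    algorithm: str = "knn"  # "knn" | "rf"
    task: str = "classification"  # "classification" | "regression"
    feature_space: str = "composition"  # "composition" | "embedding"
    train_fraction: float = 0.60
    cv_folds: int = 10
    cv_repeats: int = 10
    knn_k_grid: tuple[int, ...] = (1, 3, 5, 7, 9, 11)
    rf_trees: int = 500
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.train_fraction < 1:
            raise ValueError("train_fraction must be in (0, 1)")
        if self.cv_folds < 2:
            raise ValueError("cv_folds must be >= 2")
        if self.algorithm not in ("knn", "rf"):
            raise ValueError(f"unknown algorithm {self.algorithm!r}")
        if self.task not in ("classification", "regression"):
            raise ValueError(f"unknown task {self.task!r}")


@dataclass
class TransferRecord:
    dataset_id: str
    combo: str
    algorithm: str
    feature_space: str
    cv_metric_modern: float
    cv_metric_ancient: float
    transfer_by_level: dict[float, float] = field(default_factory=dict)
    transfer_overall: float = float("nan")
    metric: str = "accuracy"
    seed: int = 0


def normalize_gradient(values: np.ndarray | pd.Series | list) -> np.ndarray:
    """Min-max scale a gradient to [0, 1] so RMSE is comparable across
    datasets. Affine-invariant; a constant vector raises."""
    v = np.asarray(values.to_numpy() if isinstance(values, pd.Series) else values,
                   dtype=float)
    if v.size < 2 or np.ptp(v) == 0:
        raise ValueError("gradient needs at least 2 distinct values")
    return (v - v.min()) / np.ptp(v)


def _build_model(config: MLConfig, max_k: int | None = None):
    if config.algorithm == "rf":
        cls = (RandomForestClassifier if config.task == "classification"
               else RandomForestRegressor)
        return cls(n_estimators=config.rf_trees, random_state=config.seed), False
    cls = (KNeighborsClassifier if config.task == "classification"
           else KNeighborsRegressor)
    grid = [k for k in config.knn_k_grid if max_k is None or k <= max_k]
    if not grid:
        grid = [1]
    if config.task == "classification":
        cv = RepeatedStratifiedKFold(n_splits=config.cv_folds,
                                     n_repeats=config.cv_repeats,
                                     random_state=config.seed)
        scoring = "accuracy"
    else:
        cv = RepeatedKFold(n_splits=config.cv_folds,
                           n_repeats=config.cv_repeats,
                           random_state=config.seed)
        scoring = "neg_root_mean_squared_error"
    search = GridSearchCV(cls(), {"n_neighbors": grid}, cv=cv, scoring=scoring)
    return search, True


def _fit(features: np.ndarray, target: np.ndarray, config: MLConfig):
    """Fit the configured model (tuning KNN's k by repeated CV)."""
    if config.task == "classification":
        counts = np.bincount(pd.factorize(target)[0])
        folds_cap = int(counts.min())
    else:
        folds_cap = len(target)
    model, is_search = _build_model(config, max_k=len(target))
    if is_search and config.task == "classification" and folds_cap < config.cv_folds:
        # shrink the inner CV rather than fail on tiny training partitions
        model.cv = RepeatedStratifiedKFold(n_splits=max(2, folds_cap),
                                           n_repeats=config.cv_repeats,
                                           random_state=config.seed)
    model.fit(features, target)
    return model


def _score(model, features: np.ndarray, target: np.ndarray, task: str) -> float:
    pred = model.predict(features)
    if task == "classification":
        return float(accuracy_score(target, pred))
    return float(np.sqrt(mean_squared_error(target, pred)))


def split_train_test(y: np.ndarray, config: MLConfig,
                     ) -> tuple[np.ndarray, np.ndarray]:
    """Train/test indices for the configured split fraction (stratified on
    the labels for classification)."""
    idx = np.arange(len(y))
    stratify = y if config.task == "classification" else None
    train, test = train_test_split(idx, train_size=config.train_fraction,
                                   stratify=stratify,
                                   random_state=config.seed)
    return train, test


def cross_validate(features: np.ndarray | pd.DataFrame,
                   target: np.ndarray | pd.Series,
                   config: MLConfig) -> float:
    """60-40 split with tuned model; returns held-out accuracy or RMSE.

    Classification splits are stratified. Regression targets are
    min-max-normalized to [0, 1] before fitting, so the RMSE is on the
    normalized gradient scale.
    """
    x = np.asarray(features.to_numpy() if isinstance(features, pd.DataFrame)
                   else features, dtype=float)
    y = np.asarray(target.to_numpy() if isinstance(target, pd.Series) else target)
    if config.task == "classification":
        if len(np.unique(y)) < 2:
            raise ValueError("classification needs >= 2 classes")
    else:
        y = normalize_gradient(y)
    train, test = split_train_test(y, config)
    model = _fit(x[train], y[train], config)
    return _score(model, x[test], y[test], config.task)


def stack_datasets(modern: CommunityDataset, ancient: CommunityDataset,
                   seed: int = 0) -> CommunityDataset:
    """One joint dataset with the modern samples first (ids suffixed)."""
    stacked = pd.concat([
        modern.counts.set_index(modern.counts.index + "_modern"),
        ancient.counts.set_index(ancient.counts.index + "_ancient"),
    ])
    return CommunityDataset(
        counts=stacked,
        metadata=pd.Series(0.0 if modern.mode == "path" else "x",
                           index=stacked.index),
        mode=modern.mode, seed=seed, annotations=modern.annotations)


def joint_distance(modern: CommunityDataset, ancient: CommunityDataset,
                   combo: GridCombo, seed: int = 0):
    """Distance matrix over the stacked modern + ancient samples, reusable
    across ordination methods."""
    return compute_distance(stack_datasets(modern, ancient, seed),
                            combo.transform, combo.index, seed=seed)


def _features_for(modern: CommunityDataset, ancient: CommunityDataset,
                  combo: GridCombo, config: MLConfig, seed: int,
                  ordination_options: OrdinationOptions | None = None,
                  precomputed_distance=None) -> tuple[np.ndarray, np.ndarray]:
    """(modern features, ancient features) in a shared feature space.

    Composition: one transform fitted on the stacked modern + ancient
    matrix (mirroring a single matrix per dataset). Embedding: one joint
    ordination over all samples. Features are z-scored per column for the
    distance-based learners.
    """
    joint = stack_datasets(modern, ancient, seed)
    stacked = joint.counts
    n_modern = modern.n_samples
    if config.feature_space == "composition":
        from .transforms import TransformOptions, transform

        sequences = (modern.annotations.sequences
                     if modern.annotations is not None else None)
        tm = transform(stacked, TransformOptions(method=combo.transform,
                                                 seed=seed, sequences=sequences))
        feats = tm.data.to_numpy(dtype=float)
    else:
        dmat = (precomputed_distance if precomputed_distance is not None
                else compute_distance(joint, combo.transform, combo.index,
                                      seed=seed))
        if ordination_options is None:
            ordination_options = OrdinationOptions(method=combo.ordination,
                                                   seed=seed)
        else:
            ordination_options = OrdinationOptions(
                **{**vars(ordination_options), "method": combo.ordination,
                   "seed": seed})
        emb = ordinate(dmat, ordination_options)
        feats = emb.coordinates.to_numpy(dtype=float)
    sd = feats.std(axis=0, ddof=0)
    feats = (feats - feats.mean(axis=0)) / np.where(sd > 0, sd, 1.0)
    return feats[:n_modern], feats[n_modern:]


def transfer_evaluate(modern: CommunityDataset, ancient: CommunityDataset,
                      combo: GridCombo, config: MLConfig,
                      plan: DegradationPlan | None = None,
                      dataset_id: str = "dataset",
                      compatibility: dict[str, tuple[str, ...]] | None = None,
                      ordination_options: OrdinationOptions | None = None,
                      include_cv: bool = True,
                      precomputed_distance=None) -> TransferRecord | None:
    """Cross-validate on modern and ancient data, then evaluate the
    modern-trained transfer function on the ancient samples.

    Returns None (with a log message) for incompatible combos. When a
    degradation plan is supplied the transfer metric is also reported per
    effect level.
    """
    table = compatibility or default_compatibility()
    needs_index = config.feature_space == "embedding"
    if needs_index and combo.transform not in table.get(combo.index, ()):
        logger.info("skipping incompatible combo %s + %s", combo.transform,
                    combo.index)
        return None

    task = "classification" if modern.mode == "cluster" else "regression"
    config = MLConfig(**{**vars(config), "task": task})
    y_modern = modern.metadata.to_numpy()
    y_ancient = ancient.metadata.to_numpy()
    if task == "regression":
        both = normalize_gradient(np.concatenate([y_modern, y_ancient]))
        y_modern, y_ancient = both[: len(y_modern)], both[len(y_modern):]

    f_modern, f_ancient = _features_for(modern, ancient, combo, config,
                                        config.seed,
                                        ordination_options=ordination_options,
                                        precomputed_distance=precomputed_distance)
    cv_modern = cv_ancient = float("nan")
    if include_cv:
        cv_modern = cross_validate(f_modern, modern.metadata, config)
        cv_ancient = cross_validate(f_ancient, ancient.metadata, config)

    model = _fit(f_modern, y_modern, config)
    overall = _score(model, f_ancient, y_ancient, task)
    by_level: dict[float, float] = {}
    if plan is not None:
        levels = plan.levels.reindex(ancient.counts.index)
        for level in sorted(levels.dropna().unique()):
            mask = (levels == level).to_numpy()
            if mask.sum() == 0:
                continue
            by_level[float(level)] = _score(model, f_ancient[mask],
                                            y_ancient[mask], task)

    combo_name = f"{combo.transform}+{combo.index}+{combo.ordination}" \
        if needs_index else combo.transform
    return TransferRecord(
        dataset_id=dataset_id, combo=combo_name, algorithm=config.algorithm,
        feature_space=config.feature_space, cv_metric_modern=cv_modern,
        cv_metric_ancient=cv_ancient, transfer_by_level=by_level,
        transfer_overall=overall,
        metric="accuracy" if task == "classification" else "rmse",
        seed=config.seed)


def records_to_frame(records: list[TransferRecord]) -> pd.DataFrame:
    rows = []
    for r in records:
        if r is None:
            continue
        base = {k: v for k, v in vars(r).items() if k != "transfer_by_level"}
        if r.transfer_by_level:
            for level, value in r.transfer_by_level.items():
                rows.append({**base, "effect_level": level,
                             "transfer_metric": value})
        else:
            rows.append({**base, "effect_level": np.nan,
                         "transfer_metric": r.transfer_overall})
    return pd.DataFrame(rows)


# --- aggregation and Tukey HSD ---------------------------------------------

def _compact_letters(groups: list[str], not_different: set[frozenset]) -> dict[str, str]:
    """Compact letter display: groups sharing a letter are not
    significantly different (insertion-absorption algorithm)."""
    letters: list[set[str]] = []
    for g in groups:
        placed = False
        for letter_set in letters:
            if all(frozenset((g, other)) in not_different for other in letter_set):
                letter_set.add(g)
                placed = True
        if not placed:
            letters.append({g})
    # absorb duplicate letter sets
    unique_sets = []
    for s in letters:
        if not any(s <= other for other in letters if other is not s):
            unique_sets.append(s)
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    out = {g: "" for g in groups}
    for idx, s in enumerate(unique_sets):
        for g in sorted(s):
            out[g] += alphabet[idx % len(alphabet)]
    return {g: "".join(sorted(v)) for g, v in out.items()}


def aggregate_and_compare(records: pd.DataFrame, top_n: int = 5,
                          alpha: float = 0.05) -> pd.DataFrame:
    """Aggregate the top-n combos per (feature space, algorithm) and run
    Tukey HSD across approaches at each effect level.

    ``records`` is the long frame from :func:`records_to_frame`. Lower is
    better for RMSE, higher for accuracy; top-n selection respects the
    metric direction. Returns one row per (effect level, approach) with
    the group mean and its compact-letter grouping.
    """
    if records.empty:
        raise ValueError("no transfer records to aggregate")
    metric = records["metric"].iloc[0]
    ascending = metric == "rmse"
    records = records.dropna(subset=["transfer_metric"]).copy()
    records["approach"] = records["feature_space"] + "_" + records["algorithm"]

    kept = []
    for approach, sub in records.groupby("approach"):
        medians = (sub.groupby("combo")["transfer_metric"].median()
                   .sort_values(ascending=ascending))
        top = set(medians.head(top_n).index)
        kept.append(sub[sub["combo"].isin(top)])
    data = pd.concat(kept)

    rows = []
    levels = sorted(data["effect_level"].dropna().unique())
    groups_iter = ([(lv, data[data["effect_level"] == lv]) for lv in levels]
                   if levels else [(float("nan"), data)])
    for level, sub in groups_iter:
        if sub["approach"].nunique() < 2:
            raise ValueError("need >= 2 approaches for Tukey HSD")
        if (sub.groupby("approach").size() < 2).any():
            raise ValueError("every approach needs >= 2 observations")
        tukey = pairwise_tukeyhsd(sub["transfer_metric"].to_numpy(),
                                  sub["approach"].to_numpy(), alpha=alpha)
        res = pd.DataFrame(tukey.summary().data[1:],
                           columns=tukey.summary().data[0])
        not_diff = {frozenset((a, b))
                    for a, b, rej in zip(res["group1"], res["group2"],
                                         res["reject"]) if not rej}
        approaches = sorted(sub["approach"].unique())
        letters = _compact_letters(approaches, not_diff)
        means = sub.groupby("approach")["transfer_metric"].mean()
        for approach in approaches:
            rows.append({"effect_level": level, "approach": approach,
                         "mean": float(means[approach]),
                         "letters": letters[approach], "metric": metric})
    return pd.DataFrame(rows)
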