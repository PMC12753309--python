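"""Scoring method combinations: PERMANOVA pseudo-F, betadispersion F, and
the full (transform x index x ordination) benchmark grid.

The pseudo-F follows the McArdle-Anderson partition of the Gower-centred
matrix of -d^2/2: the variance explained by a design matrix (group
indicators, or a single continuous regressor) over the residual variance,
with significance by free permutation of sample identities.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from itertools import product

import numpy as np
import pandas as pd
from scipy import stats

from .beta_diversity import DistanceOptions, default_compatibility, distance
from .datatypes import CommunityDataset, DistanceMatrixResult
from .ordination import OrdinationOptions, embedding_distance, ordinate
from .transforms import TransformOptions, transform

logger = logging.getLogger(__name__)


def _gower_center(d: np.ndarray) -> np.ndarray:
    n = d.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    return -0.5 * j @ (d**2) @ j


def _hat_matrix(x: np.ndarray) -> np.ndarray:
    q, _ = np.linalg.qr(x)
    return q @ q.T


def _design(variable: np.ndarray) -> tuple[np.ndarray, int]:
    """Design matrix (with intercept) and model df for the variable."""
    if variable.dtype.kind in "OUSb":
        levels, codes = np.unique(variable, return_inverse=True)
        if len(levels) < 2:
            raise ValueError("categorical variable needs >= 2 levels")
        counts = np.bincount(codes)
        if (counts < 2).any():
            raise ValueError("every group needs >= 2 samples")
        x = np.zeros((len(variable), len(levels)))
        x[np.arange(len(variable)), codes] = 1.0
        return x, len(levels) - 1
    values = variable.astype(float)
    if np.ptp(values) == 0:
        raise ValueError("continuous variable is constant")
    return np.column_stack([np.ones(len(values)), values]), 1


def permanova_f(dist: DistanceMatrixResult | np.ndarray,
                variable: np.ndarray | pd.Series | list,
                n_perm: int = 999, seed: int = 0) -> tuple[float, float]:
    """PERMANOVA pseudo-F and permutation p-value.

    ``variable`` may be categorical labels (one-way design, df = a - 1) or
    a real vector (single regression term, df = 1). The p-value is
    (1 + #{F_perm >= F_obs}) / (1 + n_perm) under free permutations.
    """
    d = dist.data if isinstance(dist, DistanceMatrixResult) else np.asarray(dist)
    variable = np.asarray(variable.to_numpy() if isinstance(variable, pd.Series)
                          else variable)
    n = d.shape[0]
    if n < 4:
        raise ValueError("PERMANOVA requires at least 4 samples")
    if len(variable) != n:
        raise ValueError("variable length does not match distance matrix")
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")

    g = _gower_center(d)
    x, df_model = _design(variable)
    h = _hat_matrix(x)
    df_resid = n - df_model - 1

    def _f(perm: np.ndarray) -> float:
        gp = g[np.ix_(perm, perm)]
        ss_total = np.trace(gp)
        ss_model = np.trace(h @ gp)
        ss_resid = ss_total - ss_model
        if ss_resid <= 0:
            return np.inf
        return (ss_model / df_model) / (ss_resid / df_resid)

    identity = np.arange(n)
    f_obs = _f(identity)
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_perm):
        if _f(rng.permutation(n)) >= f_obs:
            hits += 1
    p = (1 + hits) / (1 + n_perm)
    return float(f_obs), float(p)


def betadisper_f(dist: DistanceMatrixResult | np.ndarray,
                 groups: np.ndarray | pd.Series | list) -> float:
    """One-way ANOVA F on distances to group spatial centroids.

    The distance matrix is embedded by full PCoA; axes with negative
    eigenvalues are kept as imaginary coordinates whose squared
    contributions are subtracted from the centroid distances
    (Anderson's multivariate dispersion construction).
    """
    d = dist.data if isinstance(dist, DistanceMatrixResult) else np.asarray(dist)
    groups = np.asarray(groups.to_numpy() if isinstance(groups, pd.Series)
                        else groups)
    levels, codes = np.unique(groups, return_inverse=True)
    if len(levels) < 2:
        raise ValueError("betadispersion requires >= 2 groups")
    if (np.bincount(codes) < 2).any():
        raise ValueError("every group needs >= 2 samples")

    g = _gower_center(d)
    eigvals, eigvecs = np.linalg.eigh((g + g.T) / 2.0)
    pos = eigvals > 1e-10
    neg = eigvals < -1e-10
    real_axes = eigvecs[:, pos] * np.sqrt(eigvals[pos])
    imag_axes = eigvecs[:, neg] * np.sqrt(-eigvals[neg])

    centroid_dist = np.empty(len(groups))
    for k in range(len(levels)):
        members = codes == k
        cr = real_axes[members].mean(axis=0) if real_axes.size else 0.0
        ci = imag_axes[members].mean(axis=0) if imag_axes.size else 0.0
        sq = np.zeros(int(members.sum()))
        if real_axes.size:
            sq += ((real_axes[members] - cr) ** 2).sum(axis=1)
        if imag_axes.size:
            sq -= ((imag_axes[members] - ci) ** 2).sum(axis=1)
        centroid_dist[members] = np.sqrt(np.clip(sq, 0.0, None))

    if np.allclose(centroid_dist, 0.0):
        warnings.warn("all centroid distances are zero; F set to 0", stacklevel=2)
        return 0.0
    per_group = [centroid_dist[codes == k] for k in range(len(levels))]
    if all(np.ptp(v) == 0 for v in per_group) and len({v[0] for v in per_group}) == 1:
        return 0.0
    f, _ = stats.f_oneway(*per_group)
    return float(f) if np.isfinite(f) else 0.0


# --- grid runner -----------------------------------------------------------

@dataclass
class BenchmarkRecord:
    dataset_id: str
    transform: str
    index: str
    ordination: str  # "none" for distance-level scoring
    target_kind: str  # "cluster" | "gradient"
    dna_status: str  # "modern" | "ancient"
    pseudo_f: float
    p_value: float
    betadisper_f: float | None = None
    seed: int = 0


@dataclass
class GridCombo:
    transform: str
    index: str
    ordination: str = "none"


def _target(dataset: CommunityDataset) -> tuple[np.ndarray, str]:
    if dataset.mode == "cluster":
        return dataset.metadata.to_numpy(dtype=object), "cluster"
    return dataset.metadata.to_numpy(dtype=float), "gradient"


def compute_distance(dataset: CommunityDataset, transform_name: str,
                     index_name: str, seed: int = 0,
                     wrench_groups: pd.Series | None = None,
                     ) -> DistanceMatrixResult:
    """Transform a dataset's counts and compute one dissimilarity matrix."""
    sequences = (dataset.annotations.sequences
                 if dataset.annotations is not None else None)
    tree = dataset.annotations.tree if dataset.annotations is not None else None
    topts = TransformOptions(method=transform_name, seed=seed,
                             sequences=sequences, wrench_groups=wrench_groups)
    tm = transform(dataset.counts, topts)
    dopts = DistanceOptions(index=index_name, tree=tree, seed=seed,
                            raw_counts=dataset.counts)
    return distance(tm, dopts)


def run_benchmark_grid(dataset_pairs: list[tuple[str, CommunityDataset, CommunityDataset]],
                       combos: list[GridCombo], n_perm: int = 999, seed: int = 0,
                       compatibility: dict[str, tuple[str, ...]] | None = None,
                       ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Score every valid combo on every (modern, ancient) dataset pair.

    Combos with ordination "none" are scored on the dissimilarity matrix
    itself; others on Euclidean distances over the 2-D embedding.
    Incompatible (transform, index) pairs are logged and skipped. Returns
    the long-format record table and a rank table ordered by median
    pseudo-F per (target kind, dna status, ordination presence).
    """
    if not combos:
        raise ValueError("empty combination list")
    table = compatibility or default_compatibility()
    records: list[BenchmarkRecord] = []
    for dataset_id, modern, ancient in dataset_pairs:
        for status, dataset in (("modern", modern), ("ancient", ancient)):
            variable, kind = _target(dataset)
            cache: dict[tuple[str, str], DistanceMatrixResult] = {}
            for combo in combos:
                if combo.transform not in table.get(combo.index, ()):
                    logger.info("skipping incompatible combo %s + %s",
                                combo.transform, combo.index)
                    continue
                key = (combo.transform, combo.index)
                try:
                    if key not in cache:
                        cache[key] = compute_distance(dataset, *key, seed=seed)
                    dmat = cache[key]
                    if combo.ordination != "none":
                        emb = ordinate(dmat, OrdinationOptions(
                            method=combo.ordination, seed=seed))
                        dmat = embedding_distance(emb)
                    f, p = permanova_f(dmat, variable, n_perm=n_perm, seed=seed)
                    bdf = (betadisper_f(dmat, variable)
                           if kind == "cluster" else None)
                except ValueError as exc:
                    logger.warning("combo %s failed on %s: %s", combo, dataset_id, exc)
                    continue
                records.append(BenchmarkRecord(
                    dataset_id=dataset_id, transform=combo.transform,
                    index=combo.index, ordination=combo.ordination,
                    target_kind=kind, dna_status=status, pseudo_f=f,
                    p_value=p, betadisper_f=bdf, seed=seed))
    frame = pd.DataFrame([vars(r) for r in records])
    ranks = rank_table(frame) if len(frame) else pd.DataFrame()
    return frame, ranks


def rank_table(records: pd.DataFrame) -> pd.DataFrame:
    """Rank combos by median pseudo-F (ties: mean F, then combo name)."""
    keys = ["target_kind", "dna_status", "ordination"]
    combo_keys = ["transform", "index", "ordination"]
    grouped = (records.groupby(keys[:2] + combo_keys, as_index=False)
               .agg(median_f=("pseudo_f", "median"),
                    mean_f=("pseudo_f", "mean"),
                    n=("pseudo_f", "size")))
    grouped["combo"] = (grouped["transform"] + "+" + grouped["index"]
                        + "+" + grouped["ordination"])
    grouped = grouped.sort_values(
        ["target_kind", "dna_status", "median_f", "mean_f", "combo"],
        ascending=[True, True, False, False, True], kind="stable")
    grouped["rank"] = grouped.groupby(keys[:2]).cumcount() + 1
    return grouped.reset_index(drop=True)


def make_grid(transforms: list[str], indices: list[str],
              ordinations: list[str] | None = None) -> list[GridCombo]:
    """Cartesian combination list; ordinations=None gives distance-level
    combos only."""
    if ordinations is None:
        return [GridCombo(t, i) for t, i in product(transforms, indices)]
    return [GridCombo(t, i, o)
            for t, i, o in product(transforms, indices, ordinations)]
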