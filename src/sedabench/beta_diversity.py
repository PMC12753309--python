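"""Pairwise community dissimilarity indices.

Sixteen indices behind one dispatch function: classical abundance-based
indices (Euclidean, Bray-Curtis, Canberra, Kulczynski, Morisita-Horn,
Gower, alternative Gower, Chao), correlation distances (Pearson,
Spearman), a random-forest proximity distance, interaction-adjusted
indices (TINA/PINA, which weight pairwise taxon association instead of
strict taxon identity), and the abundance-weighted UniFrac family
(weighted, generalized with alpha = 0.5, variance-adjusted weighted).

A compatibility table declares which count transforms can feed which
index (e.g. log-ratio outputs carry negative values and cannot feed
Bray-Curtis or UniFrac; k-mer features are not taxa and cannot feed
tree-aware indices).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from skbio import TreeNode
from sklearn.ensemble import RandomForestClassifier

from .datatypes import ConfigurationError, DistanceMatrixResult, TransformedMatrix

DISTANCE_INDICES = ("euclidean", "bray", "canberra", "kulczynski", "horn",
                    "gower", "alt_gower", "chao", "pearson", "spearman",
                    "rf_proximity", "tina_w", "pina_w", "w_unifrac",
                    "g_unifrac_05", "vaw_unifrac")

_TREE_INDICES = frozenset({"pina_w", "w_unifrac", "g_unifrac_05", "vaw_unifrac"})
_NONNEG_INDICES = frozenset({"bray", "canberra", "kulczynski", "horn", "gower",
                             "alt_gower", "chao", "tina_w"}) | _TREE_INDICES


@dataclass
class DistanceOptions:
    index: str = "bray"
    gunifrac_alpha: float = 0.5
    tree: TreeNode | None = field(default=None, repr=False)
    association: pd.DataFrame | None = field(default=None, repr=False)
    rf_trees: int = 500
    seed: int = 0
    raw_counts: pd.DataFrame | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if self.index not in DISTANCE_INDICES:
            raise ConfigurationError(f"unknown index {self.index!r}")
        if not 0.0 <= self.gunifrac_alpha <= 1.0:
            raise ConfigurationError("gunifrac_alpha must lie in [0, 1]")


# --- compatibility ---------------------------------------------------------

# transforms whose output is nonnegative and keeps taxa as features
_NONNEG_TAXON_TRANSFORMS = ("prop", "rarefy", "hellinger", "chi_square", "css",
                            "wrench", "gmpr")
_ALL_TRANSFORMS = _NONNEG_TAXON_TRANSFORMS + ("clr", "rclr", "vst", "tmm",
                                              "tmmwsp", "kmer")


def default_compatibility() -> dict[str, tuple[str, ...]]:
    """index -> transforms allowed to feed it. Editable config."""
    table: dict[str, tuple[str, ...]] = {}
    for index in ("euclidean", "pearson", "spearman", "rf_proximity"):
        table[index] = _ALL_TRANSFORMS
    for index in ("bray", "canberra", "kulczynski", "horn", "gower", "alt_gower"):
        table[index] = _NONNEG_TAXON_TRANSFORMS + ("kmer",)
    for index in _TREE_INDICES:
        table[index] = _NONNEG_TAXON_TRANSFORMS
    table["tina_w"] = _NONNEG_TAXON_TRANSFORMS
    # Chao needs raw integer counts; it is listed once, after rarefaction
    # (the only transform that keeps integer counts), to avoid running the
    # identical computation under every label.
    table["chao"] = ("rarefy", "prop")
    return table


def is_compatible(transform: str, index: str,
                  table: dict[str, tuple[str, ...]] | None = None) -> bool:
    table = table or default_compatibility()
    return transform in table.get(index, ())


# --- pairwise helpers ------------------------------------------------------

def _pairwise(x: np.ndarray, func) -> np.ndarray:
    n = x.shape[0]
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = func(x[i], x[j])
    return d


def _bray(a: np.ndarray, b: np.ndarray) -> float:
    denom = (a + b).sum()
    return float(np.abs(a - b).sum() / denom) if denom > 0 else 0.0


def _canberra(a: np.ndarray, b: np.ndarray) -> float:
    nz = (a > 0) | (b > 0)
    if not nz.any():
        return 0.0
    s = a[nz] + b[nz]
    return float(np.sum(np.abs(a[nz] - b[nz]) / s) / nz.sum())


def _kulczynski(a: np.ndarray, b: np.ndarray) -> float:
    mins = np.minimum(a, b).sum()
    sa, sb = a.sum(), b.sum()
    if sa == 0 or sb == 0:
        return 1.0
    return float(1.0 - 0.5 * (mins / sa + mins / sb))


def _horn(a: np.ndarray, b: np.ndarray) -> float:
    sa, sb = a.sum(), b.sum()
    if sa == 0 or sb == 0:
        return 1.0
    la = (a**2).sum() / sa**2
    lb = (b**2).sum() / sb**2
    denom = (la + lb) * sa * sb
    if denom == 0:
        return 1.0
    return float(1.0 - 2.0 * (a * b).sum() / denom)


def _alt_gower(a: np.ndarray, b: np.ndarray) -> float:
    nz = (a > 0) | (b > 0)
    if not nz.any():
        return 0.0
    return float(np.abs(a[nz] - b[nz]).sum() / nz.sum())


def _chao_pair(a: np.ndarray, b: np.ndarray) -> float:
    """Abundance-based Jaccard dissimilarity with the unseen-shared-species
    correction of Chao et al. (2005)."""
    shared = (a > 0) & (b > 0)
    if not shared.any():
        return 1.0
    n, m = a.sum(), b.sum()
    u = a[shared].sum() / n
    v = b[shared].sum() / m
    f1_b = int(((b == 1) & shared).sum())
    f2_b = int(((b == 2) & shared).sum())
    f1_a = int(((a == 1) & shared).sum())
    f2_a = int(((a == 2) & shared).sum())
    u += ((m - 1) / m) * (f1_b / (2 * max(f2_b, 1))) * (a[shared & (b == 1)].sum() / n)
    v += ((n - 1) / n) * (f1_a / (2 * max(f2_a, 1))) * (b[shared & (a == 1)].sum() / m)
    u, v = min(u, 1.0), min(v, 1.0)
    denom = u + v - u * v
    if denom <= 0:
        return 1.0
    return float(np.clip(1.0 - u * v / denom, 0.0, 1.0))


def _correlation_distance(x: np.ndarray, method: str) -> np.ndarray:
    data = x
    if method == "spearman":
        data = np.apply_along_axis(rankdata, 1, x)
    centered = data - data.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(centered, axis=1)
    if (norms == 0).any():
        raise ValueError("correlation distance undefined for a constant sample")
    corr = (centered @ centered.T) / np.outer(norms, norms)
    return np.clip(1.0 - corr, 0.0, None)


def _gower(x: np.ndarray) -> np.ndarray:
    # range-standardize columns to [0, 1], then mean absolute difference
    lo = x.min(axis=0)
    rng = x.max(axis=0) - lo
    std = np.where(rng > 0, (x - lo) / np.where(rng > 0, rng, 1.0), 0.0)
    return _pairwise(std, lambda a, b: float(np.abs(a - b).mean()))


def rf_proximity_distance(x: np.ndarray, n_trees: int = 500, seed: int = 0,
                          ) -> np.ndarray:
    """1 - random-forest proximity, from an unsupervised forest.

    The forest separates the real samples from a synthetic copy whose
    columns were permuted independently (destroying taxon co-occurrence),
    so no benchmark label is ever seen. Proximity of two real samples is
    the fraction of trees in which they land in the same leaf.
    """
    rng = np.random.default_rng(seed)
    synth = np.column_stack([rng.permutation(col) for col in x.T])
    features = np.vstack([x, synth])
    labels = np.r_[np.ones(x.shape[0]), np.zeros(x.shape[0])]
    forest = RandomForestClassifier(n_estimators=n_trees,
                                    random_state=int(rng.integers(2**31)))
    forest.fit(features, labels)
    leaves = forest.apply(x)
    prox = (leaves[:, None, :] == leaves[None, :, :]).mean(axis=2)
    d = 1.0 - prox
    np.fill_diagonal(d, 0.0)
    return d


# --- interaction-adjusted (TINA / PINA) ------------------------------------

def taxon_association_matrix(transformed: TransformedMatrix | pd.DataFrame,
                             kind: str = "abundance",
                             tree: TreeNode | None = None) -> pd.DataFrame:
    """Taxon x taxon similarity in [0, 1] with unit diagonal.

    ``abundance``: Spearman correlation of taxa across samples, rescaled
    (rho + 1) / 2; constant taxa get association 0.5 to every other taxon.
    ``phylogenetic``: 1 - cophenetic distance / max cophenetic distance.
    """
    if kind == "abundance":
        data = transformed.data if isinstance(transformed, TransformedMatrix) else transformed
        if data.shape[0] < 3:
            raise ValueError("abundance association needs at least 3 samples")
        x = data.to_numpy(dtype=float)
        ranks = np.apply_along_axis(rankdata, 0, x)
        centered = ranks - ranks.mean(axis=0, keepdims=True)
        norms = np.linalg.norm(centered, axis=0)
        constant = norms == 0
        if constant.any():
            warnings.warn(f"{int(constant.sum())} constant taxa: association "
                          "set to 0.5", stacklevel=2)
        safe = np.where(constant, 1.0, norms)
        rho = (centered.T @ centered) / np.outer(safe, safe)
        rho[constant, :] = 0.0
        rho[:, constant] = 0.0
        assoc = (np.clip(rho, -1.0, 1.0) + 1.0) / 2.0
        np.fill_diagonal(assoc, 1.0)
        return pd.DataFrame(assoc, index=data.columns, columns=data.columns)
    if kind == "phylogenetic":
        if tree is None:
            raise ValueError("phylogenetic association requires a tree")
        dm = tree.tip_tip_distances()
        coph = dm.data
        assoc = 1.0 - coph / coph.max()
        np.fill_diagonal(assoc, 1.0)
        return pd.DataFrame(assoc, index=list(dm.ids), columns=list(dm.ids))
    raise ConfigurationError(f"unknown association kind {kind!r}")


def _interaction_adjusted(x: np.ndarray, assoc: np.ndarray) -> np.ndarray:
    """Weighted interaction-adjusted dissimilarity: the sample similarity is
    the association-kernel cosine of the two (relative) abundance vectors."""
    w = x / x.sum(axis=1, keepdims=True)
    cross = w @ assoc @ w.T
    self_sim = np.sqrt(np.clip(np.diag(cross), 0.0, None))
    denom = np.outer(self_sim, self_sim)
    with np.errstate(divide="ignore", invalid="ignore"):
        sim = np.where(denom > 0, cross / denom, 0.0)
    d = 1.0 - np.clip(sim, 0.0, 1.0)
    np.fill_diagonal(d, 0.0)
    return np.clip((d + d.T) / 2.0, 0.0, None)


# --- UniFrac family --------------------------------------------------------

def _branch_structure(tree: TreeNode, taxon_ids: list[str],
                      ) -> tuple[np.ndarray, np.ndarray]:
    """(branch lengths, branch x taxon incidence) for every non-root branch."""
    tip_index = {t: i for i, t in enumerate(taxon_ids)}
    missing = [t.name for t in tree.tips() if t.name not in tip_index]
    extra = set(taxon_ids) - {t.name for t in tree.tips()}
    if extra:
        raise ValueError(f"tree is missing taxa: {sorted(extra)[:5]}")
    if missing:
        tree = tree.shear(taxon_ids)
    lengths, rows = [], []
    for node in tree.postorder(include_self=False):
        row = np.zeros(len(taxon_ids), dtype=bool)
        if node.is_tip():
            row[tip_index[node.name]] = True
        else:
            for tip in node.tips():
                row[tip_index[tip.name]] = True
        lengths.append(float(node.length or 0.0))
        rows.append(row)
    return np.asarray(lengths), np.asarray(rows)


def unifrac_matrix(x: np.ndarray, taxon_ids: list[str], tree: TreeNode,
                   variant: str = "weighted", alpha: float = 0.5) -> np.ndarray:
    """Abundance-weighted UniFrac family on per-sample relative abundances.

    ``weighted``: normalized weighted UniFrac; ``generalized``: the
    alpha-parameterized family (alpha=1 recovers weighted); ``vaw``:
    variance-adjusted weighted, down-weighting branches whose abundance
    sum is near 0 or 1 (where the variance of the difference is smallest).
    """
    lengths, incidence = _branch_structure(tree, taxon_ids)
    rel = x / x.sum(axis=1, keepdims=True)
    p = rel @ incidence.T  # sample x branch abundance mass
    n = x.shape[0]
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            pa, pb = p[i], p[j]
            s = pa + pb
            diff = np.abs(pa - pb)
            if variant == "weighted":
                denom = (lengths * s).sum()
                val = (lengths * diff).sum() / denom if denom > 0 else 0.0
            elif variant == "generalized":
                nz = s > 0
                w = lengths[nz] * s[nz] ** alpha
                denom = w.sum()
                val = (w * (diff[nz] / s[nz])).sum() / denom if denom > 0 else 0.0
            elif variant == "vaw":
                nz = (s > 0) & (s < 2)
                scale = np.sqrt(s[nz] * (2.0 - s[nz]))
                num = (lengths[nz] * diff[nz] / scale).sum()
                denom = (lengths[nz] * s[nz] / scale).sum()
                val = num / denom if denom > 0 else 0.0
            else:
                raise ConfigurationError(f"unknown UniFrac variant {variant!r}")
            d[i, j] = d[j, i] = float(np.clip(val, 0.0, 1.0))
    return d


# --- dispatch --------------------------------------------------------------

def distance(transformed: TransformedMatrix, options: DistanceOptions,
             ) -> DistanceMatrixResult:
    """Compute one of the sixteen dissimilarity indices on a transformed
    (or raw, for Chao) samples x features matrix."""
    index = options.index
    data = transformed.data
    x = data.to_numpy(dtype=float)
    ids = list(data.index)

    if index in _NONNEG_INDICES and (x < 0).any() and index != "chao":
        raise ValueError(f"{index} requires nonnegative input; transform "
                         f"{transformed.method!r} produced negative values")
    if index in _TREE_INDICES and not transformed.taxon_features:
        raise ValueError(f"{index} requires taxon features, not "
                         f"{transformed.method!r} features")

    if index == "euclidean":
        diff = x[:, None, :] - x[None, :, :]
        d = np.sqrt((diff**2).sum(axis=2))
    elif index == "bray":
        d = _pairwise(x, _bray)
    elif index == "canberra":
        d = _pairwise(x, _canberra)
    elif index == "kulczynski":
        d = _pairwise(x, _kulczynski)
    elif index == "horn":
        d = _pairwise(x, _horn)
    elif index == "gower":
        d = _gower(x)
    elif index == "alt_gower":
        d = _pairwise(x, _alt_gower)
    elif index == "chao":
        raw = options.raw_counts if options.raw_counts is not None else data
        xi = raw.to_numpy()
        if not np.allclose(xi, np.round(xi)):
            raise ValueError("chao requires integer counts; supply raw_counts")
        d = _pairwise(np.round(xi).astype(np.int64), _chao_pair)
    elif index in ("pearson", "spearman"):
        d = _correlation_distance(x, index)
    elif index == "rf_proximity":
        d = rf_proximity_distance(x, n_trees=options.rf_trees, seed=options.seed)
    elif index in ("tina_w", "pina_w"):
        if options.association is not None:
            assoc = options.association
        elif index == "tina_w":
            assoc = taxon_association_matrix(transformed, "abundance")
        else:
            if options.tree is None:
                raise ValueError("pina_w requires a tree or an association matrix")
            assoc = taxon_association_matrix(transformed, "phylogenetic",
                                             tree=options.tree)
        assoc = assoc.loc[data.columns, data.columns]
        d = _interaction_adjusted(x, assoc.to_numpy(dtype=float))
    elif index in _TREE_INDICES:  # UniFrac family
        if options.tree is None:
            raise ValueError(f"{index} requires a tree")
        variant = {"w_unifrac": "weighted", "g_unifrac_05": "generalized",
                   "vaw_unifrac": "vaw"}[index]
        alpha = 0.5 if index == "g_unifrac_05" else options.gunifrac_alpha
        d = unifrac_matrix(x, list(data.columns), options.tree,
                           variant=variant, alpha=alpha)
    else:  # pragma: no cover
        raise ConfigurationError(index)

    return DistanceMatrixResult(data=d, ids=ids, index=index,
                                transform=transformed.method)
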