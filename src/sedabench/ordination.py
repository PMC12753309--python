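"""Two-dimensional ordination of distance matrices.

PCoA (classical metric scaling, no negative-eigenvalue correction) and
NMDS (SMACOF majorization with isotonic regression on Kruskal stress-1)
are implemented here; t-SNE and UMAP are delegated to scikit-learn and
umap-learn with precomputed distances, the contract being seeded
determinism and a 2-D output.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.isotonic import IsotonicRegression

from .datatypes import ConfigurationError, DistanceMatrixResult, Embedding

ORDINATION_METHODS = ("pcoa", "nmds", "tsne", "umap")


@dataclass
class OrdinationOptions:
    method: str = "pcoa"
    seed: int = 0
    nmds_restarts: int = 20
    nmds_max_iter: int = 300
    tsne_perplexity: float | None = None  # default min(30, (n-1)/3)
    umap_n_neighbors: int = 15
    umap_min_dist: float = 0.1

    def __post_init__(self) -> None:
        if self.method not in ORDINATION_METHODS:
            raise ConfigurationError(f"unknown ordination {self.method!r}")
        if self.nmds_restarts < 1:
            raise ConfigurationError("nmds_restarts must be >= 1")


def _pcoa(d: np.ndarray) -> tuple[np.ndarray, dict]:
    n = d.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    g = -0.5 * j @ (d**2) @ j
    eigvals, eigvecs = np.linalg.eigh((g + g.T) / 2.0)
    order = np.argsort(eigvals)[::-1]
    eigvals, eigvecs = eigvals[order], eigvecs[:, order]
    coords = np.zeros((n, 2))
    for axis in range(2):
        if eigvals[axis] > 0:
            coords[:, axis] = eigvecs[:, axis] * np.sqrt(eigvals[axis])
    # deterministic sign convention: largest-magnitude loading positive
    for axis in range(2):
        col = coords[:, axis]
        if col.any() and col[np.argmax(np.abs(col))] < 0:
            coords[:, axis] = -col
    neg_mass = float(-eigvals[eigvals < 0].sum())
    diagnostics = {"eigenvalues": eigvals,
                   "negative_eigenvalue_mass": neg_mass,
                   "explained_2d": float(eigvals[:2].clip(min=0).sum()
                                         / max(eigvals.clip(min=0).sum(), 1e-300))}
    return coords, diagnostics


def stress_1(d: np.ndarray, coords: np.ndarray) -> float:
    """Kruskal stress-1 of a configuration against a distance matrix,
    with disparities from isotonic regression on the upper triangle."""
    iu = np.triu_indices(d.shape[0], k=1)
    diss = d[iu]
    diff = coords[:, None, :] - coords[None, :, :]
    conf = np.sqrt((diff**2).sum(axis=2))[iu]
    order = np.argsort(diss, kind="stable")
    iso = IsotonicRegression()
    disparities = np.empty_like(conf)
    disparities[order] = iso.fit_transform(np.arange(order.size), conf[order])
    denom = (conf**2).sum()
    if denom == 0:
        return 0.0
    return float(np.sqrt(((conf - disparities) ** 2).sum() / denom))


def _nmds_single(d: np.ndarray, rng: np.random.Generator, max_iter: int,
                 tol: float = 1e-7) -> tuple[np.ndarray, float, list[float]]:
    n = d.shape[0]
    iu = np.triu_indices(n, k=1)
    diss = d[iu]
    order = np.argsort(diss, kind="stable")
    coords = rng.normal(size=(n, 2)) * d.max()
    iso = IsotonicRegression()
    trace: list[float] = []
    last = np.inf
    for _ in range(max_iter):
        diff = coords[:, None, :] - coords[None, :, :]
        conf_full = np.sqrt((diff**2).sum(axis=2))
        conf = conf_full[iu]
        disparities = np.empty_like(conf)
        disparities[order] = iso.fit_transform(np.arange(order.size), conf[order])
        denom = (conf**2).sum()
        stress = float(np.sqrt(((conf - disparities) ** 2).sum() / max(denom, 1e-300)))
        trace.append(stress)
        if last - stress < tol:
            break
        last = stress
        # Guttman transform with the disparities as target distances
        dhat = np.zeros((n, n))
        dhat[iu] = disparities
        dhat += dhat.T
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio = np.where(conf_full > 0, dhat / conf_full, 0.0)
        b = -ratio
        np.fill_diagonal(b, ratio.sum(axis=1))
        coords = (b @ coords) / n
    # report the stress of the configuration actually returned
    final = stress_1(d, coords)
    trace.append(final)
    return coords, final, trace


def _nmds(d: np.ndarray, options: OrdinationOptions) -> tuple[np.ndarray, dict]:
    rng = np.random.default_rng(options.seed)
    best_coords, best_stress, best_trace = None, np.inf, []
    for _ in range(options.nmds_restarts):
        coords, stress, trace = _nmds_single(d, rng, options.nmds_max_iter)
        if stress < best_stress:
            best_coords, best_stress, best_trace = coords, stress, trace
    return best_coords, {"stress": best_stress, "stress_trace": best_trace}


def _tsne(d: np.ndarray, options: OrdinationOptions) -> np.ndarray:
    from sklearn.manifold import TSNE

    n = d.shape[0]
    perplexity = options.tsne_perplexity
    default = min(30.0, max(1.0, (n - 1) // 3))
    if perplexity is None:
        perplexity = default
    if perplexity >= n:
        warnings.warn(f"perplexity {perplexity} infeasible for n={n}; "
                      f"using {default}", stacklevel=2)
        perplexity = default
    tsne = TSNE(n_components=2, metric="precomputed", init="random",
                perplexity=perplexity, random_state=options.seed)
    return tsne.fit_transform(d)


def _umap(d: np.ndarray, options: OrdinationOptions) -> np.ndarray:
    from umap import UMAP

    n = d.shape[0]
    n_neighbors = options.umap_n_neighbors
    if n_neighbors >= n:
        warnings.warn(f"n_neighbors {n_neighbors} infeasible for n={n}; "
                      f"using {n - 1}", stacklevel=2)
        n_neighbors = n - 1
    reducer = UMAP(n_components=2, metric="precomputed",
                   n_neighbors=n_neighbors, min_dist=options.umap_min_dist,
                   random_state=options.seed)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return reducer.fit_transform(d)


def ordinate(dist: DistanceMatrixResult, options: OrdinationOptions) -> Embedding:
    """Embed a distance matrix in two dimensions."""
    d = dist.data
    if d.shape[0] < 4:
        raise ValueError("ordination requires at least 4 samples")
    diagnostics: dict = {}
    if options.method == "pcoa":
        coords, diagnostics = _pcoa(d)
    elif options.method == "nmds":
        coords, diagnostics = _nmds(d, options)
    elif options.method == "tsne":
        coords = np.asarray(_tsne(d, options), dtype=float)
    elif options.method == "umap":
        coords = np.asarray(_umap(d, options), dtype=float)
    else:  # pragma: no cover
        raise ConfigurationError(options.method)
    frame = pd.DataFrame(coords, index=dist.ids, columns=["axis_1", "axis_2"])
    return Embedding(coordinates=frame, method=options.method,
                     seed=options.seed, diagnostics=diagnostics)


def embedding_distance(emb: Embedding, standardize: bool = False,
                       ) -> DistanceMatrixResult:
    """Euclidean distances between the 2-D sample coordinates.

    ``standardize`` z-scores each axis first, removing the arbitrary
    global scale differences between ordination methods; it is off by
    default so that PCoA of a Euclidean configuration reproduces the
    input distances exactly.
    """
    coords = emb.coordinates.to_numpy(dtype=float)
    if standardize:
        sd = coords.std(axis=0, ddof=0)
        coords = (coords - coords.mean(axis=0)) / np.where(sd > 0, sd, 1.0)
    diff = coords[:, None, :] - coords[None, :, :]
    d = np.sqrt((diff**2).sum(axis=2))
    return DistanceMatrixResult(data=d, ids=emb.ids,
                                index=f"embedding_{emb.method}")
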