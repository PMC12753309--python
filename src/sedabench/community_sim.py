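"""Synthetic community count matrices for benchmarking sedaDNA workflows.

The generator is a gamma/log-normal -> negative-binomial hierarchy: each
taxon gets a baseline log-mean abundance drawn uniformly; a random subset
of taxa is differentially abundant between clusters (cluster mode) or
log-linearly along a 0-1 gradient (path mode); per-sample library sizes
are log-normal; observed counts are negative-binomial around the expected
relative abundances scaled to the library size.

Per-run scalar parameters (library size, differential fraction, ...) are
themselves drawn from declared uniform ranges so that every simulated
dataset has its own parameter set, mimicking how community simulators are
typically driven in benchmark studies.
"""

from __future__ import annotations

from dataclasses import dataclass, fields, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from skbio import TreeNode

from .datatypes import CommunityDataset, ConfigurationError, TaxonAnnotations

# Uniform meta-ranges for the per-run scalar draws. These define the
# default study conditions; simulate_community additionally draws
# per-taxon quantities from the ranges stored on SimParams.
_LIBRARY_SIZE_MEAN_RANGE = (2e4, 1e5)
_LIBRARY_SIZE_CV_RANGE = (0.1, 0.4)

DEFAULT_BASELINE_LOGMEAN_RANGE = (-2.0, 2.0)
DEFAULT_DE_PROB_RANGE = (0.1, 0.4)
DEFAULT_DE_FACTOR_RANGE = (2.0, 6.0)
DEFAULT_DISPERSION_RANGE = (0.1, 1.0)


@dataclass(frozen=True)
class SimParams:
    """Parameters of one simulation run.

    Scalar fields are the drawn per-run values; ``*_range`` fields are the
    uniform bounds used for the per-taxon draws inside the simulator.
    Dispersion follows the var = mu + phi * mu**2 parameterization.
    """

    n_samples: int = 100
    n_taxa: int = 400
    mode: str = "cluster"
    n_clusters: int = 5
    library_size_mean: float = 5e4
    library_size_cv: float = 0.2
    baseline_logmean_range: tuple[float, float] = DEFAULT_BASELINE_LOGMEAN_RANGE
    de_prob_range: tuple[float, float] = DEFAULT_DE_PROB_RANGE
    de_factor_range: tuple[float, float] = DEFAULT_DE_FACTOR_RANGE
    dispersion_range: tuple[float, float] = DEFAULT_DISPERSION_RANGE
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_samples < 1 or self.n_taxa < 1:
            raise ConfigurationError("n_samples and n_taxa must be positive")
        if self.mode not in ("cluster", "path"):
            raise ConfigurationError(f"unknown mode {self.mode!r}")
        if self.mode == "cluster" and self.n_clusters < 2:
            raise ConfigurationError("cluster mode requires n_clusters >= 2")
        if self.library_size_mean <= 0:
            raise ConfigurationError("library_size_mean must be positive")
        if self.library_size_cv < 0:
            raise ConfigurationError("library_size_cv must be nonnegative")
        for name in ("baseline_logmean_range", "de_prob_range", "de_factor_range",
                     "dispersion_range"):
            lo, hi = getattr(self, name)
            if lo > hi:
                raise ConfigurationError(f"{name}: lower bound exceeds upper bound")
        lo, hi = self.de_prob_range
        if lo < 0 or hi > 1:
            raise ConfigurationError("de_prob_range must lie in [0, 1]")
        if self.de_factor_range[0] <= 0 or self.dispersion_range[0] <= 0:
            raise ConfigurationError("fold factors and dispersions must be positive")


def draw_sim_params(seed: int, mode: str = "cluster",
                    overrides: Mapping[str, object] | None = None) -> SimParams:
    """Draw a per-run parameter set from the default uniform ranges.

    Deterministic under ``seed``. ``overrides`` replaces any SimParams
    field after the draw (unknown keys raise ConfigurationError).
    """
    rng = np.random.default_rng(seed)
    params = SimParams(
        mode=mode,
        library_size_mean=float(rng.uniform(*_LIBRARY_SIZE_MEAN_RANGE)),
        library_size_cv=float(rng.uniform(*_LIBRARY_SIZE_CV_RANGE)),
        seed=int(seed),
    )
    if overrides:
        valid = {f.name for f in fields(SimParams)}
        unknown = set(overrides) - valid
        if unknown:
            raise ConfigurationError(f"unknown SimParams overrides: {sorted(unknown)}")
        params = replace(params, **dict(overrides))
    return params


def _library_sizes(rng: np.random.Generator, params: SimParams) -> np.ndarray:
    mean, cv = params.library_size_mean, params.library_size_cv
    if cv == 0:
        return np.full(params.n_samples, mean)
    sigma2 = np.log1p(cv**2)
    mu = np.log(mean) - sigma2 / 2
    return rng.lognormal(mu, np.sqrt(sigma2), size=params.n_samples)


def simulate_community(params: SimParams) -> CommunityDataset:
    """Simulate one community count matrix under ``params``.

    Cluster mode assigns near-equal cluster sizes (difference <= 1, equal
    when n_samples divides evenly); path mode assigns each sample a
    gradient position drawn Uniform(0, 1). Counts are negative-binomial
    around library-size-scaled relative abundances.
    """
    rng = np.random.default_rng(params.seed)
    n, p = params.n_samples, params.n_taxa

    base_log = rng.uniform(*params.baseline_logmean_range, size=p)
    de_prob = rng.uniform(*params.de_prob_range)
    dispersion = rng.uniform(*params.dispersion_range, size=p)

    # per-sample log-mean profile before library scaling
    log_mu = np.tile(base_log, (n, 1))

    if params.mode == "cluster":
        k = params.n_clusters
        sizes = np.full(k, n // k)
        sizes[: n % k] += 1
        labels = np.repeat(np.arange(k), sizes)
        # each cluster perturbs its own random subset of taxa up or down
        for c in range(k):
            is_de = rng.random(p) < de_prob
            factors = rng.uniform(*params.de_factor_range, size=p)
            signs = rng.choice([-1.0, 1.0], size=p)
            log_mu[labels == c] += np.where(is_de, signs * np.log(factors), 0.0)
        metadata = pd.Series([f"cluster_{c + 1}" for c in labels], name="cluster")
    else:
        positions = rng.uniform(0.0, 1.0, size=n)
        is_de = rng.random(p) < de_prob
        factors = rng.uniform(*params.de_factor_range, size=p)
        signs = rng.choice([-1.0, 1.0], size=p)
        slope = np.where(is_de, signs * np.log(factors), 0.0)
        log_mu += positions[:, None] * slope[None, :]
        metadata = pd.Series(positions, name="gradient")

    rel = np.exp(log_mu)
    rel /= rel.sum(axis=1, keepdims=True)
    libs = _library_sizes(rng, params)
    mu = rel * libs[:, None]
    if not np.all(mu.sum(axis=1) > 0):
        raise ValueError("parameters imply zero expected reads for some sample")

    # NB with var = mu + phi mu^2: shape 1/phi, p = shape/(shape+mu)
    shape = 1.0 / dispersion[None, :]
    counts = rng.negative_binomial(shape, shape / (shape + mu))

    # guard against the (vanishingly rare) all-zero sample
    zero_rows = counts.sum(axis=1) == 0
    if zero_rows.any():
        top = np.argmax(mu, axis=1)
        counts[zero_rows, top[zero_rows]] = 1

    sample_ids = [f"sample_{i + 1}" for i in range(n)]
    taxon_ids = [f"taxon_{j + 1}" for j in range(p)]
    frame = pd.DataFrame(counts, index=sample_ids, columns=taxon_ids)
    metadata.index = frame.index
    return CommunityDataset(counts=frame, metadata=metadata, mode=params.mode,
                            seed=params.seed)


# ---------------------------------------------------------------------------
# synthetic sequences and phylogeny

_BASES = np.array(list("ACGT"))


def _evolve_sequence(parent: np.ndarray, t: float, rate: float,
                     rng: np.random.Generator) -> np.ndarray:
    """Jukes-Cantor evolution of an integer-coded sequence over time t."""
    p_change = 0.75 * (1.0 - np.exp(-4.0 / 3.0 * rate * t))
    hits = rng.random(parent.size) < p_change
    child = parent.copy()
    if hits.any():
        # substitute to one of the three other bases, uniformly
        shift = rng.integers(1, 4, size=int(hits.sum()))
        child[hits] = (child[hits] + shift) % 4
    return child


def simulate_taxa_annotations(n_taxa: int, seq_length: int = 150,
                              seed: int = 0, mutation_rate: float = 0.5,
                              taxon_ids: Sequence[str] | None = None) -> TaxonAnnotations:
    """Random coalescent tree over the taxa plus sequences evolved along it.

    Successive pairwise coalescences with exponential waiting times build a
    rooted binary tree; sequences evolve tip-ward from a random root
    sequence under a uniform (Jukes-Cantor) substitution process at
    ``mutation_rate`` substitutions per site per unit branch length.
    """
    if n_taxa < 2:
        raise ConfigurationError("need at least 2 taxa for annotations")
    if seq_length < 20:
        raise ConfigurationError("seq_length must be >= 20")
    if taxon_ids is None:
        taxon_ids = [f"taxon_{j + 1}" for j in range(n_taxa)]
    elif len(taxon_ids) != n_taxa:
        raise ConfigurationError("taxon_ids length must equal n_taxa")

    rng = np.random.default_rng(seed)

    nodes = [TreeNode(name=tid, length=0.0) for tid in taxon_ids]
    heights = [0.0] * n_taxa
    t = 0.0
    while len(nodes) > 1:
        k = len(nodes)
        t += rng.exponential(1.0 / (k * (k - 1) / 2.0))
        i, j = sorted(rng.choice(k, size=2, replace=False))
        a, b = nodes[j], nodes[i]  # pop higher index first
        ha, hb = heights[j], heights[i]
        del nodes[j], heights[j]
        del nodes[i], heights[i]
        a.length = t - ha
        b.length = t - hb
        parent = TreeNode(children=[b, a], length=0.0)
        nodes.append(parent)
        heights.append(t)
    tree = nodes[0]
    tree.length = None

    root_seq = rng.integers(0, 4, size=seq_length)
    seqs: dict[str, str] = {}

    def _descend(node: TreeNode, seq: np.ndarray) -> None:
        for child in node.children:
            child_seq = _evolve_sequence(seq, child.length or 0.0, mutation_rate, rng)
            if child.is_tip():
                seqs[child.name] = "".join(_BASES[child_seq])
            else:
                _descend(child, child_seq)

    _descend(tree, root_seq)
    seqs = {tid: seqs[tid] for tid in taxon_ids}
    return TaxonAnnotations(sequences=seqs, tree=tree)


def map_sequences_by_rank(dataset: CommunityDataset,
                          external_sequences: Sequence[tuple[str, float]] | Sequence[str],
                          ) -> CommunityDataset:
    """Assign external sequences to taxa by matching abundance ranks.

    The most abundant external sequence goes to the taxon with the largest
    total relative abundance, and so on down the ranks. ``external_sequences``
    is either a list of sequences already ordered from most to least
    abundant, or a list of (sequence, abundance) pairs. Abundance ties among
    taxa are broken by taxon id order.
    """
    if external_sequences and isinstance(external_sequences[0], tuple):
        ordered = [s for s, _ in sorted(external_sequences, key=lambda sa: -sa[1])]
    else:
        ordered = list(external_sequences)  # type: ignore[arg-type]
    if len(ordered) < dataset.n_taxa:
        raise ValueError(
            f"need at least {dataset.n_taxa} sequences, got {len(ordered)}")

    totals = dataset.counts.sum(axis=0)
    ranked = sorted(dataset.taxon_ids, key=lambda tid: (-totals[tid], tid))
    seqs = {tid: ordered[rank] for rank, tid in enumerate(ranked)}
    tree = dataset.annotations.tree if dataset.annotations else None
    return replace(dataset, annotations=TaxonAnnotations(sequences=seqs, tree=tree))
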