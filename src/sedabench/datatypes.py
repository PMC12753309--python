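"""Shared in-memory containers used across the pipeline.

Counts matrices are pandas DataFrames with samples in rows and taxa in
columns; everything downstream (transforms, distances, embeddings) keeps
the sample order of the counts matrix it was derived from.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from skbio import TreeNode


class ConfigurationError(ValueError):
    """Invalid user-supplied parameter or option."""


@dataclass
class TaxonAnnotations:
    """Per-taxon nucleotide sequences and a phylogeny over the taxa.

    ``sequences`` maps taxon id -> ACGT string (uniform length);
    ``tree`` is a rooted tree whose tip names are exactly the taxon ids.
    """

    sequences: Mapping[str, str] | None = None
    tree: TreeNode | None = None

    def validate(self, taxon_ids: Sequence[str]) -> None:
        if self.sequences is not None:
            missing = set(taxon_ids) - set(self.sequences)
            if missing:
                raise ValueError(f"sequences missing for taxa: {sorted(missing)[:5]}")
            lengths = {len(s) for s in self.sequences.values()}
            if len(lengths) > 1:
                raise ValueError("sequences must have uniform length")
            alphabet = set("".join(self.sequences.values()))
            if not alphabet <= set("ACGT"):
                raise ValueError(f"non-ACGT characters in sequences: {alphabet - set('ACGT')}")
        if self.tree is not None:
            tips = [t.name for t in self.tree.tips()]
            if sorted(tips) != sorted(taxon_ids):
                raise ValueError("tree tip set does not match taxon ids")


@dataclass
class CommunityDataset:
    """A samples x taxa integer count matrix with per-sample metadata.

    ``metadata`` holds a categorical cluster label (cluster mode) or a
    real gradient value (path/gradient mode), aligned with the counts rows.
    """

    counts: pd.DataFrame
    metadata: pd.Series
    mode: str  # "cluster" | "path"
    seed: int | None = None
    annotations: TaxonAnnotations | None = None

    def __post_init__(self) -> None:
        if not self.counts.index.equals(self.metadata.index):
            self.metadata = self.metadata.reindex(self.counts.index)
        if self.metadata.isna().any():
            raise ValueError("metadata does not cover every sample")
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("counts must be nonnegative")
        if (self.counts.sum(axis=1) == 0).any():
            raise ValueError("all-zero samples are not allowed")
        if self.mode not in ("cluster", "path"):
            raise ConfigurationError(f"unknown mode {self.mode!r}")
        if self.mode == "path":
            values = self.metadata.to_numpy(dtype=float)
            if not np.all(np.isfinite(values)):
                raise ValueError("gradient values must be finite")
        if self.annotations is not None:
            self.annotations.validate(list(self.counts.columns))

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def taxon_ids(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def n_samples(self) -> int:
        return self.counts.shape[0]

    @property
    def n_taxa(self) -> int:
        return self.counts.shape[1]

    def with_counts(self, counts: pd.DataFrame) -> "CommunityDataset":
        return replace(self, counts=counts)


@dataclass
class TransformedMatrix:
    """Real-valued samples x features matrix produced by a count transform."""

    data: pd.DataFrame
    method: str
    # taxon-space transforms keep feature ids == taxon ids; the k-mer
    # transform replaces them with k-mer strings
    taxon_features: bool = True

    def __post_init__(self) -> None:
        values = self.data.to_numpy(dtype=float)
        if not np.all(np.isfinite(values)):
            raise ValueError(f"{self.method}: non-finite values in transformed matrix")


@dataclass
class DistanceMatrixResult:
    """Symmetric sample x sample dissimilarity matrix with provenance tags."""

    data: np.ndarray
    ids: list[str]
    index: str
    transform: str = ""

    def __post_init__(self) -> None:
        d = np.asarray(self.data, dtype=float)
        if d.ndim != 2 or d.shape[0] != d.shape[1]:
            raise ValueError("distance matrix must be square")
        if not np.all(np.isfinite(d)):
            raise ValueError("distance matrix contains non-finite values")
        if not np.allclose(d, d.T, atol=1e-10):
            raise ValueError("distance matrix must be symmetric")
        d = (d + d.T) / 2.0
        np.fill_diagonal(d, 0.0)
        if (d < -1e-10).any():
            raise ValueError("distance matrix must be nonnegative")
        self.data = np.clip(d, 0.0, None)

    @property
    def n(self) -> int:
        return self.data.shape[0]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.data, index=self.ids, columns=self.ids)


@dataclass
class Embedding:
    """2-D sample coordinates from an ordination, with diagnostics."""

    coordinates: pd.DataFrame  # n x 2, index = sample ids
    method: str
    seed: int | None = None
    diagnostics: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        values = self.coordinates.to_numpy(dtype=float)
        if values.shape[1] != 2:
            raise ValueError("embedding must be two-dimensional")
        if not np.all(np.isfinite(values)):
            raise ValueError("embedding contains non-finite coordinates")

    @property
    def ids(self) -> list[str]:
        return list(self.coordinates.index)
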