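"""Flat-file IO (TSV counts/metadata/distances, FASTA, Newick) and
empirical-dataset preprocessing."""

from __future__ import annotations

import numpy as np
import pandas as pd
from skbio import TreeNode

from .datatypes import CommunityDataset, DistanceMatrixResult


def read_counts(path) -> pd.DataFrame:
    """Counts TSV: sample ids in the first column, taxon ids in the header."""
    frame = pd.read_csv(path, sep="\t", index_col=0)
    if frame.index.duplicated().any():
        dupes = frame.index[frame.index.duplicated()].unique().tolist()
        raise ValueError(f"duplicate sample ids: {dupes[:5]}")
    for col in frame.columns:
        values = pd.to_numeric(frame[col], errors="coerce")
        bad = values.isna() | (values < 0) | (values != values.round())
        if bad.any():
            row = frame.index[bad.to_numpy().argmax()]
            raise ValueError(
                f"invalid count at sample {row!r}, taxon {col!r}: "
                f"{frame.loc[row, col]!r} (nonnegative integers required)")
    return frame.astype(np.int64)


def write_counts(frame: pd.DataFrame, path) -> None:
    frame.to_csv(path, sep="\t", index_label="sample_id")


def read_metadata(path) -> pd.Series:
    frame = pd.read_csv(path, sep="\t", index_col=0)
    if frame.shape[1] < 1:
        raise ValueError("metadata must have at least one value column")
    series = frame.iloc[:, 0]
    numeric = pd.to_numeric(series, errors="coerce")
    return numeric if not numeric.isna().any() else series


def write_metadata(series: pd.Series, path) -> None:
    series.to_frame().to_csv(path, sep="\t", index_label="sample_id")


def read_distance(path) -> DistanceMatrixResult:
    frame = pd.read_csv(path, sep="\t", index_col=0)
    if list(frame.index) != list(frame.columns):
        raise ValueError("distance matrix ids differ between rows and columns")
    data = frame.to_numpy(dtype=float)
    if not np.allclose(data, data.T, atol=1e-8):
        raise ValueError("distance matrix is not symmetric")
    return DistanceMatrixResult(data=data, ids=list(frame.index), index="file")


def write_distance(dmat: DistanceMatrixResult, path) -> None:
    dmat.to_frame().to_csv(path, sep="\t", index_label="sample_id")


def read_fasta(path) -> dict[str, str]:
    sequences: dict[str, str] = {}
    name = None
    chunks: list[str] = []
    with open(path) as handle:
        for line in handle:
            line = line.strip()
            if not line:
                continue
            if line.startswith(">"):
                if name is not None:
                    sequences[name] = "".join(chunks)
                name = line[1:].split()[0]
                chunks = []
            else:
                chunks.append(line.upper())
    if name is not None:
        sequences[name] = "".join(chunks)
    if not sequences:
        raise ValueError(f"no sequences found in {path}")
    return sequences


def write_fasta(sequences: dict[str, str], path) -> None:
    with open(path, "w") as handle:
        for name, seq in sequences.items():
            handle.write(f">{name}\n{seq}\n")


def read_tree(path) -> TreeNode:
    return TreeNode.read(str(path), format="newick")


def write_tree(tree: TreeNode, path) -> None:
    tree.write(str(path), format="newick")


def write_dataset(dataset: CommunityDataset, out_dir) -> None:
    """Write counts + metadata (+ sequences/tree when present) to a directory."""
    from pathlib import Path

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_counts(dataset.counts, out / "counts.tsv")
    write_metadata(dataset.metadata, out / "metadata.tsv")
    if dataset.annotations is not None:
        if dataset.annotations.sequences:
            write_fasta(dataset.annotations.sequences, out / "sequences.fasta")
        if dataset.annotations.tree is not None:
            write_tree(dataset.annotations.tree, out / "tree.nwk")


def read_dataset(in_dir, mode: str) -> CommunityDataset:
    from pathlib import Path

    from .datatypes import TaxonAnnotations

    src = Path(in_dir)
    counts = read_counts(src / "counts.tsv")
    metadata = read_metadata(src / "metadata.tsv")
    annotations = None
    seqs = read_fasta(src / "sequences.fasta") if (src / "sequences.fasta").exists() else None
    tree = read_tree(src / "tree.nwk") if (src / "tree.nwk").exists() else None
    if seqs or tree is not None:
        annotations = TaxonAnnotations(sequences=seqs, tree=tree)
    return CommunityDataset(counts=counts, metadata=metadata, mode=mode,
                            annotations=annotations)


# --- empirical preprocessing ----------------------------------------------

def _taxa_reduction_constant(counts: np.ndarray, target: tuple[int, int]) -> int:
    """Smallest integer c >= 0 whose per-cell subtraction (floored at 0)
    brings the number of surviving taxa into ``target``; found by bisection."""
    def surviving(c: int) -> int:
        return int(((counts - c).clip(min=0).sum(axis=0) > 0).sum())

    lo_t, hi_t = target
    if surviving(0) <= hi_t:
        return 0
    lo, hi = 0, int(counts.max())
    while lo < hi:
        mid = (lo + hi) // 2
        if surviving(mid) > hi_t:
            lo = mid + 1
        else:
            hi = mid
    return lo


def preprocess_empirical(counts: pd.DataFrame, metadata: pd.Series,
                         max_samples: int = 125,
                         taxa_target: tuple[int, int] = (1000, 4000),
                         min_taxa_per_sample: int = 20,
                         balance_classes: bool = True,
                         seed: int = 0) -> CommunityDataset:
    """Standardize an external dataset for the benchmark.

    Steps, in order: (1) balance classes by subsampling each class to the
    smallest class size (categorical metadata only); (2) subsample to at
    most ``max_samples`` samples; (3) reduce taxa by subtracting a single
    per-cell constant (floored at zero) until the surviving taxon count
    falls inside ``taxa_target``; (4) drop samples with fewer than
    ``min_taxa_per_sample`` detected taxa.
    """
    if counts.shape[0] < 4:
        raise ValueError("need at least 4 samples")
    metadata = metadata.reindex(counts.index)
    rng = np.random.default_rng(seed)
    categorical = metadata.dtype.kind in "OUSb"

    if categorical and balance_classes:
        smallest = metadata.value_counts().min()
        keep: list[str] = []
        for cls in pd.unique(metadata):
            members = metadata.index[metadata == cls].to_numpy()
            chosen = rng.choice(members, size=smallest, replace=False)
            keep.extend(chosen.tolist())
        counts = counts.loc[keep]
        metadata = metadata.loc[keep]

    if counts.shape[0] > max_samples:
        chosen = rng.choice(counts.index.to_numpy(), size=max_samples,
                            replace=False)
        counts = counts.loc[chosen]
        metadata = metadata.loc[chosen]

    c = _taxa_reduction_constant(counts.to_numpy(dtype=np.int64), taxa_target)
    reduced = (counts.to_numpy(dtype=np.int64) - c).clip(min=0)
    counts = pd.DataFrame(reduced, index=counts.index, columns=counts.columns)
    counts = counts.loc[:, counts.sum(axis=0) > 0]

    richness = (counts > 0).sum(axis=1)
    keep_mask = richness >= min_taxa_per_sample
    if not keep_mask.any():
        raise ValueError("all samples filtered out by the richness threshold")
    counts = counts.loc[keep_mask]
    metadata = metadata.loc[keep_mask]

    return CommunityDataset(counts=counts, metadata=metadata,
                            mode="cluster" if categorical else "path",
                            seed=seed)
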