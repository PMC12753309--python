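"""Ancient-DNA-style noise injection: per-sample taxon dropout with
depth-preserving read reallocation.

Each sample is assigned one of four effect levels (0, 0.25, 0.50, 0.75):
the target fraction of its detected taxa that becomes false negatives.
Reads removed from the dropped taxa are reallocated to a random subset of
the sample's pre-dropout top-decile taxa, proportionally to their
pre-dropout abundances, so per-sample sequencing depth is preserved
exactly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datatypes import CommunityDataset

EFFECT_LEVELS = (0.0, 0.25, 0.50, 0.75)
DEFAULT_NOISE_HALFWIDTH = 0.03


@dataclass
class DegradationPlan:
    """Per-sample effect level and, once realized, the dropout sets."""

    levels: pd.Series  # sample id -> effect level
    noise_halfwidth: float = DEFAULT_NOISE_HALFWIDTH
    seed: int = 0
    dropped: dict[str, list[str]] = field(default_factory=dict)
    recipients: dict[str, list[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        bad = set(self.levels.unique()) - set(EFFECT_LEVELS)
        if bad:
            raise ValueError(f"unknown effect levels: {sorted(bad)}")
        if self.noise_halfwidth < 0:
            raise ValueError("noise_halfwidth must be nonnegative")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "sample": self.levels.index,
            "level": self.levels.to_numpy(),
            "n_dropped": [len(self.dropped.get(s, [])) for s in self.levels.index],
            "n_recipients": [len(self.recipients.get(s, [])) for s in self.levels.index],
        })


def _round_robin_split(n: int) -> np.ndarray:
    """Level index for n slots: remainder distributed in level order."""
    base = np.full(4, n // 4)
    base[: n % 4] += 1
    return np.repeat(np.arange(4), base)


def assign_effect_levels(metadata: pd.Series, mode: str, seed: int = 0,
                         noise_halfwidth: float = DEFAULT_NOISE_HALFWIDTH,
                         ) -> DegradationPlan:
    """Assign one effect level to every sample, a quarter per level.

    Cluster mode balances the four levels within every class; gradient
    mode assigns levels at random with respect to the gradient. Any
    integer remainder is spread round-robin in the order (0, 0.25, 0.50,
    0.75). Deterministic under ``seed``.
    """
    if mode not in ("cluster", "gradient", "path"):
        raise ValueError(f"unknown mode {mode!r}")
    if len(metadata) < 4:
        raise ValueError("need at least 4 samples to assign four effect levels")

    rng = np.random.default_rng(seed)
    levels = pd.Series(0.0, index=metadata.index, name="effect_level")

    if mode == "cluster":
        for cls in pd.unique(metadata):
            members = metadata.index[metadata == cls].to_numpy()
            if len(members) < 4:
                warnings.warn(
                    f"class {cls!r} has {len(members)} samples (<4); "
                    "best-effort level assignment", stacklevel=2)
            order = rng.permutation(len(members))
            idx = _round_robin_split(len(members))
            levels.loc[members[order]] = np.asarray(EFFECT_LEVELS)[idx]
    else:
        members = metadata.index.to_numpy()
        order = rng.permutation(len(members))
        idx = _round_robin_split(len(members))
        levels.loc[members[order]] = np.asarray(EFFECT_LEVELS)[idx]

    return DegradationPlan(levels=levels, noise_halfwidth=noise_halfwidth, seed=seed)


def _degrade_row(row: np.ndarray, level: float, jitter: float,
                 rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Return (new_row, dropped_idx, recipient_idx) for one sample."""
    detected = np.flatnonzero(row > 0)
    n_det = detected.size
    target = level + rng.uniform(-jitter, jitter)
    target = float(np.clip(target, 1.0 / n_det if n_det else 0.0, 1.0 - 1e-9))
    n_drop = int(round(target * n_det))
    n_drop = max(1, min(n_drop, n_det - 1))  # keep at least one taxon

    # top decile by pre-dropout abundance (ties broken by column order)
    k_top = max(1, n_det // 10)
    order = detected[np.lexsort((detected, -row[detected]))]
    top_decile = order[:k_top]

    dropped = rng.choice(detected, size=n_drop, replace=False)
    dropped_set = set(dropped.tolist())
    pool = np.array([t for t in top_decile if t not in dropped_set], dtype=int)
    if pool.size == 0:
        # every top-decile taxon was dropped: re-draw from surviving taxa
        survivors = np.array([t for t in detected if t not in dropped_set], dtype=int)
        pool = survivors[np.lexsort((survivors, -row[survivors]))][:k_top]

    n_rec = int(rng.integers(1, pool.size + 1))
    recipients = rng.choice(pool, size=n_rec, replace=False)

    removed = int(row[dropped].sum())
    new_row = row.copy()
    new_row[dropped] = 0

    # proportional reallocation with largest-remainder integer rounding
    weights = row[recipients].astype(float)
    shares = removed * weights / weights.sum()
    floors = np.floor(shares).astype(np.int64)
    leftover = removed - int(floors.sum())
    if leftover > 0:
        frac_order = np.argsort(-(shares - floors), kind="stable")
        floors[frac_order[:leftover]] += 1
    new_row[recipients] += floors
    return new_row, dropped, recipients


def degrade_matrix(dataset: CommunityDataset, plan: DegradationPlan,
                   ) -> tuple[CommunityDataset, DegradationPlan]:
    """Apply the dropout plan to a count matrix, preserving row sums exactly.

    Level-0 samples pass through unchanged. Samples with fewer than two
    detected taxa are skipped with a warning.
    """
    missing = set(dataset.sample_ids) - set(plan.levels.index)
    if missing:
        raise ValueError(f"plan does not cover samples: {sorted(missing)[:5]}")

    rng = np.random.default_rng(plan.seed)
    counts = dataset.counts.to_numpy(dtype=np.int64, copy=True)
    dropped: dict[str, list[str]] = {}
    recipients: dict[str, list[str]] = {}
    taxa = np.asarray(dataset.taxon_ids)

    for i, sid in enumerate(dataset.sample_ids):
        level = float(plan.levels[sid])
        if level == 0.0:
            continue
        if (counts[i] > 0).sum() < 2:
            warnings.warn(f"sample {sid!r} has <2 detected taxa; skipped",
                          stacklevel=2)
            continue
        new_row, drop_idx, rec_idx = _degrade_row(
            counts[i], level, plan.noise_halfwidth, rng)
        counts[i] = new_row
        dropped[sid] = taxa[np.sort(drop_idx)].tolist()
        recipients[sid] = taxa[np.sort(rec_idx)].tolist()

    realized = DegradationPlan(levels=plan.levels.copy(),
                               noise_halfwidth=plan.noise_halfwidth,
                               seed=plan.seed, dropped=dropped,
                               recipients=recipients)
    frame = pd.DataFrame(counts, index=dataset.counts.index,
                         columns=dataset.counts.columns)
    degraded = dataset.with_counts(frame)
    return degraded, realized
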