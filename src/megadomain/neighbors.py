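"""Subcompartment block-neighbor permutation testing.

A label track is reduced to maximal same-label runs ("blocks") per
chromosome; unassigned (NA) stretches break adjacency. The observed
statistic is the percent of block boundaries of each unordered label
pair. The null shuffles block order independently within each
chromosome, preserving the multiset of (label, length) blocks exactly,
merging same-label neighbors created by the shuffle before counting.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .subcompartments import NA, LabelTrack

__all__ = [
    "Block",
    "BlockSet",
    "reduce_blocks",
    "boundary_frequencies",
    "permutation_test",
]


@dataclass(frozen=True)
class Block:
    """A maximal same-label run of bins."""

    label: str
    start_bin: int   # global bin index, inclusive
    n_bins: int

    @property
    def end_bin(self) -> int:
        return self.start_bin + self.n_bins


@dataclass
class BlockSet:
    """Per chromosome, the contiguous labeled segments and their blocks.

    ``segments[chrom]`` is a list of segments; each segment is a list of
    adjacent blocks (adjacent blocks always differ in label). Boundaries
    exist only between blocks of the same segment.
    """

    segments: dict[str, list[list[Block]]]

    def all_blocks(self) -> list[Block]:
        return [b for segs in self.segments.values() for seg in segs for b in seg]


def reduce_blocks(labels: LabelTrack) -> BlockSet:
    """Collapse a label track into per-chromosome runs; NA breaks adjacency."""
    layout = labels.layout
    segments: dict[str, list[list[Block]]] = {}
    for ci, chrom in enumerate(layout.chrom_names):
        off = int(layout.chrom_offsets[ci])
        n = int(layout.bins_per_chrom[ci])
        codes = labels.codes[off : off + n]
        segs: list[list[Block]] = []
        current: list[Block] = []
        run_start, run_code = None, None
        for k in range(n + 1):
            code = codes[k] if k < n else NA
            if run_code is not None and code == run_code:
                continue
            if run_code is not None and run_code != NA:
                current.append(
                    Block(labels.names[run_code], off + run_start, k - run_start)
                )
            if code == NA and current:
                segs.append(current)
                current = []
            run_start, run_code = k, int(code)
        if current:
            segs.append(current)
        segments[chrom] = segs
    return BlockSet(segments)


def _pair_key(a: str, b: str) -> str:
    x, y = sorted((a, b))
    return f"{x}-{y}"


def _count_boundaries(blocks: BlockSet) -> Counter:
    counts: Counter = Counter()
    for segs in blocks.segments.values():
        for seg in segs:
            for left, right in zip(seg, seg[1:]):
                counts[_pair_key(left.label, right.label)] += 1
    return counts


def boundary_frequencies(blocks: BlockSet) -> dict[str, float]:
    """Percent of all boundaries per unordered label pair."""
    counts = _count_boundaries(blocks)
    total = sum(counts.values())
    if total == 0:
        raise ValueError("the block set has no boundaries")
    return {pair: 100.0 * c / total for pair, c in counts.items()}


def _shuffle_within_chrom(
    blocks: BlockSet, rng: np.random.Generator
) -> BlockSet:
    """Shuffle block order within each chromosome, keeping the number of
    blocks per segment; merge same-label neighbors that arise."""
    out: dict[str, list[list[Block]]] = {}
    for chrom, segs in blocks.segments.items():
        pool = [b for seg in segs for b in seg]
        order = rng.permutation(len(pool))
        shuffled = [pool[i] for i in order]
        new_segs: list[list[Block]] = []
        pos = 0
        for seg in segs:
            chunk = shuffled[pos : pos + len(seg)]
            pos += len(seg)
            merged: list[Block] = []
            for b in chunk:
                if merged and merged[-1].label == b.label:
                    prev = merged.pop()
                    merged.append(
                        Block(prev.label, prev.start_bin, prev.n_bins + b.n_bins)
                    )
                else:
                    merged.append(b)
            new_segs.append(merged)
        out[chrom] = new_segs
    return BlockSet(out)


def permutation_test(
    blocks: BlockSet,
    n_perm: int = 100,
    seed: int = 0,
) -> pd.DataFrame:
    """Compare observed boundary-pair percents with a within-chromosome
    block-shuffle null.

    Reports, per unordered label pair: observed percent, permuted mean and
    sd, z = (obs - mean)/sd (NaN when sd = 0), and the empirical two-sided
    p-value (1 + #{|perm - mean| >= |obs - mean|}) / (n_perm + 1).
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    observed = boundary_frequencies(blocks)
    rng = np.random.default_rng(seed)
    perm_rows: list[dict[str, float]] = []
    for _ in range(n_perm):
        shuffled = _shuffle_within_chrom(blocks, rng)
        perm_rows.append(boundary_frequencies(shuffled))
    pairs = sorted(set(observed) | {p for row in perm_rows for p in row})
    records = []
    for pair in pairs:
        obs = observed.get(pair, 0.0)
        perm = np.array([row.get(pair, 0.0) for row in perm_rows])
        mean, sd = float(perm.mean()), float(perm.std(ddof=0))
        z = (obs - mean) / sd if sd > 0 else np.nan
        extreme = int(np.sum(np.abs(perm - mean) >= np.abs(obs - mean)))
        p = (1 + extreme) / (n_perm + 1)
        records.append(
            {
                "pair": pair,
                "observed_pct": obs,
                "perm_mean": mean,
                "perm_sd": sd,
                "z": z,
                "p_empirical": p,
                "n_perm": n_perm,
                "seed": seed,
            }
        )
    return pd.DataFrame(records)
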