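"""Genome layout, fixed-width binning, and interval bookkeeping.

Coordinates are 0-based half-open throughout, matching BED. A
:class:`GenomeLayout` fixes an ordered set of chromosomes, their lengths,
and a bin size; every downstream matrix and per-bin track indexes bins by
the global bin number obtained by concatenating chromosomes in layout
order. The terminal bin of a chromosome may be partial and is kept.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "GenomeLayout",
    "GenomicInterval",
    "BinVector",
    "make_bins",
    "count_overlaps",
    "read_bed",
    "write_bed",
    "read_chrom_sizes",
]


@dataclass(frozen=True)
class GenomicInterval:
    """A half-open genomic interval [start, end) with optional BED metadata."""

    chrom: str
    start: int
    end: int
    name: str | None = None
    score: float | None = None
    strand: str = "."

    def __post_init__(self) -> None:
        if not 0 <= self.start < self.end:
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}"
            )
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class GenomeLayout:
    """Ordered chromosomes with lengths and a fixed bin width.

    Parameters
    ----------
    chrom_names
        Chromosome identifiers in the fixed order used for global bin
        numbering.
    chrom_lengths
        Length in bp of each chromosome, parallel to ``chrom_names``.
    bin_size
        Bin width in bp (250 kb for subcompartment work, 1 Mb for the
        differential-contact roll-up).
    """

    chrom_names: tuple[str, ...]
    chrom_lengths: tuple[int, ...]
    bin_size: int

    def __post_init__(self) -> None:
        if len(self.chrom_names) != len(self.chrom_lengths):
            raise ValueError("chrom_names and chrom_lengths differ in length")
        if len(set(self.chrom_names)) != len(self.chrom_names):
            raise ValueError("duplicate chromosome names")
        if self.bin_size <= 0:
            raise ValueError("bin_size must be positive")
        for name, length in zip(self.chrom_names, self.chrom_lengths):
            if length <= 0:
                raise ValueError(f"chromosome {name!r} has non-positive length")

    # -- derived indexing ------------------------------------------------

    @property
    def n_chroms(self) -> int:
        return len(self.chrom_names)

    @property
    def bins_per_chrom(self) -> np.ndarray:
        lengths = np.asarray(self.chrom_lengths, dtype=np.int64)
        return -(-lengths // self.bin_size)  # ceil division

    @property
    def chrom_offsets(self) -> np.ndarray:
        """Global bin index of the first bin of each chromosome."""
        return np.concatenate([[0], np.cumsum(self.bins_per_chrom)[:-1]])

    @property
    def total_bins(self) -> int:
        return int(self.bins_per_chrom.sum())

    def chrom_index(self, chrom: str) -> int:
        try:
            return self.chrom_names.index(chrom)
        except ValueError:
            raise KeyError(f"unknown chromosome {chrom!r}") from None

    def chrom_length(self, chrom: str) -> int:
        return self.chrom_lengths[self.chrom_index(chrom)]

    def bin_index(self, chrom: str, pos: int) -> int:
        """Global bin index containing position ``pos`` on ``chrom``."""
        ci = self.chrom_index(chrom)
        if not 0 <= pos < self.chrom_lengths[ci]:
            raise ValueError(f"position {pos} outside {chrom}")
        return int(self.chrom_offsets[ci] + pos // self.bin_size)

    def bin_chrom_ids(self) -> np.ndarray:
        """Chromosome index of every global bin."""
        return np.repeat(np.arange(self.n_chroms), self.bins_per_chrom)

    def bin_starts(self) -> np.ndarray:
        """Within-chromosome start coordinate of every global bin."""
        out = np.empty(self.total_bins, dtype=np.int64)
        for ci, (n, off) in enumerate(zip(self.bins_per_chrom, self.chrom_offsets)):
            out[off : off + n] = np.arange(n) * self.bin_size
        return out

    def bin_lengths(self) -> np.ndarray:
        """Genomic length (bp) of every bin; terminal bins may be partial."""
        starts = self.bin_starts()
        chrom_len = np.asarray(self.chrom_lengths)[self.bin_chrom_ids()]
        return np.minimum(starts + self.bin_size, chrom_len) - starts

    def subset(self, chroms: Sequence[str]) -> "GenomeLayout":
        """Layout restricted to the given chromosomes (layout order kept)."""
        keep = [c for c in self.chrom_names if c in set(chroms)]
        lengths = tuple(self.chrom_length(c) for c in keep)
        return GenomeLayout(tuple(keep), lengths, self.bin_size)

    def with_bin_size(self, bin_size: int) -> "GenomeLayout":
        return GenomeLayout(self.chrom_names, self.chrom_lengths, bin_size)


@dataclass
class BinVector:
    """One numeric value per global bin of a layout, with a validity mask."""

    layout: GenomeLayout
    values: np.ndarray
    mask: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.shape != (self.layout.total_bins,):
            raise ValueError(
                f"expected {self.layout.total_bins} values, got {self.values.shape}"
            )
        if self.mask is None:
            self.mask = np.ones(self.layout.total_bins, dtype=bool)
        else:
            self.mask = np.asarray(self.mask, dtype=bool)
            if self.mask.shape != self.values.shape:
                raise ValueError("mask shape mismatch")

    def valid_values(self) -> np.ndarray:
        return self.values[self.mask]


def make_bins(layout: GenomeLayout) -> list[GenomicInterval]:
    """Tile every chromosome into fixed-width bins.

    Per chromosome there are ceil(length / bin_size) bins; the final bin is
    truncated at the chromosome end. The returned list is ordered by global
    bin index.
    """
    out: list[GenomicInterval] = []
    for name, length in zip(layout.chrom_names, layout.chrom_lengths):
        for start in range(0, length, layout.bin_size):
            out.append(
                GenomicInterval(name, start, min(start + layout.bin_size, length))
            )
    return out


def _interval_bin_span(layout: GenomeLayout, iv: GenomicInterval) -> tuple[int, int]:
    """Global-bin half-open range [lo, hi) overlapped by an interval."""
    ci = layout.chrom_index(iv.chrom)
    if iv.end > layout.chrom_lengths[ci]:
        raise ValueError(
            f"interval {iv.chrom}:{iv.start}-{iv.end} exceeds chromosome length"
        )
    off = int(layout.chrom_offsets[ci])
    return off + iv.start // layout.bin_size, off + (iv.end - 1) // layout.bin_size + 1


def count_overlaps(
    intervals: Iterable[GenomicInterval], layout: GenomeLayout
) -> BinVector:
    """Count, per bin, how many intervals overlap it by at least 1 bp.

    An interval spanning k bins contributes 1 to each of the k bins
    (countOverlaps semantics, not midpoint assignment).
    """
    counts = np.zeros(layout.total_bins, dtype=np.int64)
    for iv in intervals:
        lo, hi = _interval_bin_span(layout, iv)
        counts[lo:hi] += 1
    return BinVector(layout, counts)


def covered_bins(
    intervals: Iterable[GenomicInterval], layout: GenomeLayout
) -> np.ndarray:
    """Boolean per-bin vector: bin touched by >=1 bp of any interval."""
    return count_overlaps(intervals, layout).values > 0


# -- plain-text I/O ------------------------------------------------------


def read_chrom_sizes(path) -> dict[str, int]:
    """Two-column chromosome-sizes text (name, length)."""
    df = pd.read_csv(path, sep="\t", header=None, names=["chrom", "length"])
    return dict(zip(df["chrom"].astype(str), df["length"].astype(int)))


def read_bed(path) -> list[GenomicInterval]:
    """BED3/BED6 reader (tab-separated, 0-based half-open)."""
    out: list[GenomicInterval] = []
    with open(path) as fh:
        for line_no, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}:{line_no}: fewer than 3 BED columns")
            chrom, start, end = parts[0], int(parts[1]), int(parts[2])
            name = parts[3] if len(parts) > 3 else None
            score = float(parts[4]) if len(parts) > 4 and parts[4] != "." else None
            strand = parts[5] if len(parts) > 5 else "."
            out.append(GenomicInterval(chrom, start, end, name, score, strand))
    return out


def write_bed(intervals: Iterable[GenomicInterval], path) -> None:
    """BED writer; emits 6 columns when any interval carries metadata."""
    ivs = list(intervals)
    rich = any(iv.name is not None or iv.score is not None or iv.strand != "." for iv in ivs)
    with open(path, "w") as fh:
        for iv in ivs:
            if rich:
                score = "." if iv.score is None else f"{iv.score:g}"
                fh.write(
                    f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.name or '.'}\t{score}\t{iv.strand}\n"
                )
            else:
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\n")
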