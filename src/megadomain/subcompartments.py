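"""Subcompartment calling by interchromosomal k-means.

Odd-chromosome bins are clustered on their trans contact profiles against
even-chromosome bins (k=6 by default), even-chromosome bins on the
transposed stitched matrix (k=5). Within each set, clusters spanning less
than 5% of that set's genome are discarded; the survivors are ordered by
decreasing genomic size and merged rank-by-rank into genome-wide clusters.
Clusters are then named A (minority LAD concordance) or B (majority) and
numbered within class by decreasing size.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from sklearn.cluster import KMeans

from .genome import GenomeLayout, GenomicInterval, covered_bins
from .matrix import StitchedMatrix

__all__ = [
    "ClusterParams",
    "LabelTrack",
    "cluster_loci",
    "filter_and_merge",
    "assign_names",
    "match_to_reference",
    "overlap_matrix",
    "k_scan",
    "track_from_intervals",
]

NA = -1  # sentinel cluster/label code for unassigned bins


@dataclass(frozen=True)
class ClusterParams:
    """k-means parameters for the odd/even clustering."""

    k_odd: int = 6
    k_even: int = 5
    min_genome_frac: float = 0.05
    seed: int = 0
    n_restarts: int = 10
    max_masked_frac: float = 0.3
    log_transform: bool = False

    def __post_init__(self) -> None:
        if self.k_odd < 2 or self.k_even < 2:
            raise ValueError("cluster counts must be >= 2")
        if not 0 <= self.min_genome_frac < 1:
            raise ValueError("min_genome_frac must be in [0, 1)")


@dataclass
class LabelTrack:
    """Per-bin subcompartment labels on a layout.

    ``codes`` holds an integer per global bin: an index into ``names`` or
    ``NA`` (-1) for masked/discarded bins.
    """

    layout: GenomeLayout
    codes: np.ndarray
    names: tuple[str, ...]
    provenance: str = ""

    def __post_init__(self) -> None:
        self.codes = np.asarray(self.codes, dtype=np.int64)
        if self.codes.shape != (self.layout.total_bins,):
            raise ValueError("label codes do not match layout bin count")
        if self.codes.size and self.codes.max() >= len(self.names):
            raise ValueError("label code exceeds name table")

    @property
    def labels(self) -> np.ndarray:
        """Per-bin label strings, 'NA' where unassigned."""
        out = np.array(list(self.names) + ["NA"], dtype=object)
        return out[self.codes]

    def code_of(self, name: str) -> int:
        try:
            return self.names.index(name)
        except ValueError:
            raise KeyError(f"label {name!r} not in track") from None

    def bins_with(self, name: str) -> np.ndarray:
        return np.flatnonzero(self.codes == self.code_of(name))

    def size_bp(self, name: str) -> int:
        """Genomic extent (bp) carrying the given label."""
        return int(self.layout.bin_lengths()[self.codes == self.code_of(name)].sum())

    def sizes_bp(self) -> dict[str, int]:
        return {name: self.size_bp(name) for name in self.names}

    def to_intervals(self) -> list[GenomicInterval]:
        """Labeled bins as BED-style intervals (label in the name field)."""
        chrom_ids = self.layout.bin_chrom_ids()
        starts = self.layout.bin_starts()
        lengths = self.layout.bin_lengths()
        out = []
        for b in np.flatnonzero(self.codes != NA):
            out.append(
                GenomicInterval(
                    self.layout.chrom_names[chrom_ids[b]],
                    int(starts[b]),
                    int(starts[b] + lengths[b]),
                    name=self.names[self.codes[b]],
                )
            )
        return out


def track_from_intervals(
    layout: GenomeLayout,
    intervals: Sequence[GenomicInterval],
    provenance: str = "",
) -> LabelTrack:
    """Build a LabelTrack from labeled intervals (label in the name field);
    each bin takes the label of the interval covering its start."""
    names = tuple(sorted({iv.name for iv in intervals if iv.name}))
    codes = np.full(layout.total_bins, NA)
    for iv in intervals:
        if not iv.name:
            continue
        ci = layout.chrom_index(iv.chrom)
        off = int(layout.chrom_offsets[ci])
        lo = off + iv.start // layout.bin_size
        hi = off + (iv.end - 1) // layout.bin_size + 1
        codes[lo:hi] = names.index(iv.name)
    return LabelTrack(layout, codes, names, provenance)


def _prepare_rows(values: np.ndarray, max_masked_frac: float):
    """Drop rows with too many masked entries; impute the rest with column
    means. Returns (imputed matrix, indices of kept rows)."""
    nan_frac = np.isnan(values).mean(axis=1)
    keep = np.flatnonzero(nan_frac <= max_masked_frac)
    sub = values[keep].copy()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN columns
        col_mean = np.nanmean(sub, axis=0, keepdims=True)
    col_mean = np.where(np.isnan(col_mean), 0.0, col_mean)
    idx = np.isnan(sub)
    sub[idx] = np.broadcast_to(col_mean, sub.shape)[idx]
    return sub, keep


def _kmeans_rows(
    data: np.ndarray, k: int, seed: int, n_restarts: int
) -> np.ndarray:
    if k > data.shape[0]:
        raise ValueError(f"k={k} exceeds number of valid rows ({data.shape[0]})")
    km = KMeans(n_clusters=k, n_init=n_restarts, random_state=seed)
    return km.fit_predict(data)


def cluster_loci(
    stitched: StitchedMatrix, params: ClusterParams
) -> tuple[np.ndarray, np.ndarray]:
    """k-means on stitched-matrix rows (odd bins) and on columns of the
    transpose (even bins).

    Returns per-row and per-column cluster codes aligned with
    ``stitched.row_bins`` / ``stitched.col_bins``; rows or columns with more
    than ``max_masked_frac`` masked entries get NA.
    """
    values = stitched.values
    if params.log_transform:
        values = np.log2(values + 1e-9)
    row_data, row_keep = _prepare_rows(values, params.max_masked_frac)
    col_data, col_keep = _prepare_rows(values.T, params.max_masked_frac)
    row_clusters = np.full(values.shape[0], NA)
    col_clusters = np.full(values.shape[1], NA)
    row_clusters[row_keep] = _kmeans_rows(
        row_data, params.k_odd, params.seed, params.n_restarts
    )
    col_clusters[col_keep] = _kmeans_rows(
        col_data, params.k_even, params.seed, params.n_restarts
    )
    return row_clusters, col_clusters


def k_scan(
    stitched: StitchedMatrix,
    params: ClusterParams,
    k_range: Iterable[int] = range(2, 11),
) -> dict[int, float]:
    """Report k-means inertia per k on the odd rows (no automated choice)."""
    values = stitched.values
    if params.log_transform:
        values = np.log2(values + 1e-9)
    data, _ = _prepare_rows(values, params.max_masked_frac)
    out = {}
    for k in k_range:
        km = KMeans(n_clusters=k, n_init=params.n_restarts, random_state=params.seed)
        km.fit(data)
        out[k] = float(km.inertia_)
    return out


def _cluster_sizes_bp(
    clusters: np.ndarray, bins: np.ndarray, layout: GenomeLayout
) -> dict[int, int]:
    lengths = layout.bin_lengths()
    sizes: dict[int, int] = {}
    for c in np.unique(clusters[clusters != NA]):
        sizes[int(c)] = int(lengths[bins[clusters == c]].sum())
    return sizes


def filter_and_merge(
    row_clusters: np.ndarray,
    col_clusters: np.ndarray,
    stitched: StitchedMatrix,
    params: ClusterParams,
) -> tuple[np.ndarray, int]:
    """Discard small clusters and merge odd/even cluster sets by size rank.

    Within the odd and the even set independently, clusters spanning less
    than ``min_genome_frac`` of that set's genomic extent become NA. The
    survivors on each side are ordered by decreasing genomic size and
    merged by rank (largest odd with largest even, and so on).

    Returns (genome-wide cluster codes per global bin, number of merged
    clusters). Unequal surviving counts on the two sides are a hard error.
    """
    layout = stitched.layout
    merged = np.full(layout.total_bins, NA)

    surviving: list[list[tuple[int, int]]] = []  # per side: (cluster, size) by rank
    for clusters, bins in (
        (row_clusters, stitched.row_bins),
        (col_clusters, stitched.col_bins),
    ):
        extent = layout.bin_lengths()[bins].sum()
        sizes = _cluster_sizes_bp(clusters, bins, layout)
        kept = {c: s for c, s in sizes.items() if s / extent >= params.min_genome_frac}
        surviving.append(
            sorted(kept.items(), key=lambda cs: (-cs[1], cs[0]))
        )
    n_odd, n_even = len(surviving[0]), len(surviving[1])
    if n_odd != n_even:
        raise ValueError(
            f"surviving cluster counts differ between odd ({n_odd}) and even "
            f"({n_even}) chromosome sets; cannot merge by size rank"
        )
    for rank, ((c_odd, _), (c_even, _)) in enumerate(zip(*surviving)):
        merged[stitched.row_bins[row_clusters == c_odd]] = rank
        merged[stitched.col_bins[col_clusters == c_even]] = rank
    return merged, n_odd


def assign_names(
    merged: np.ndarray,
    lad_intervals: Sequence[GenomicInterval],
    layout: GenomeLayout,
    provenance: str = "",
) -> LabelTrack:
    """Name clusters A/B by LAD concordance, then number by decreasing size.

    A cluster whose fraction of bins overlapping a LAD is below 0.5 is
    class A, otherwise class B (a fraction of exactly 0.5 is B). Within
    each class clusters are numbered 1, 2, ... by decreasing genomic size.
    """
    clusters = np.unique(merged[merged != NA])
    if clusters.size == 0:
        raise ValueError("no clusters to name")
    if len(lad_intervals) == 0:
        warnings.warn("empty LAD set: all clusters will be class A")
        lad_cover = np.zeros(layout.total_bins, dtype=bool)
    else:
        lad_cover = covered_bins(lad_intervals, layout)
    lengths = layout.bin_lengths()

    records = []
    for c in clusters:
        in_c = merged == c
        frac = lad_cover[in_c].mean()
        records.append((int(c), "B" if frac >= 0.5 else "A", int(lengths[in_c].sum())))

    names: dict[int, str] = {}
    ordered: list[str] = []
    for klass in ("A", "B"):
        members = [r for r in records if r[1] == klass]
        members.sort(key=lambda r: (-r[2], r[0]))
        for i, (c, _, _) in enumerate(members, 1):
            names[c] = f"{klass}{i}"
    ordered = sorted(names.values())

    codes = np.full(layout.total_bins, NA)
    for c, nm in names.items():
        codes[merged == c] = ordered.index(nm)
    return LabelTrack(layout, codes, tuple(ordered), provenance)


def match_to_reference(
    query: LabelTrack, reference: LabelTrack
) -> tuple[dict[str, str], np.ndarray, LabelTrack]:
    """Relabel a query track to best match a reference labeling.

    Builds the bin-count contingency of query x reference labels, computes
    Pearson residuals (obs - exp)/sqrt(exp) under the independence model,
    and picks the bijection maximizing the summed matched-cell residuals
    over all assignments.

    Returns (mapping query->reference, residual matrix, relabeled track).
    """
    if query.layout.total_bins != reference.layout.total_bins:
        raise ValueError("tracks are on different layouts")
    both = (query.codes != NA) & (reference.codes != NA)
    if not both.any():
        raise ValueError("no co-labeled bins between query and reference")
    nq, nr = len(query.names), len(reference.names)
    table = np.zeros((nq, nr))
    for qc, rc in zip(query.codes[both], reference.codes[both]):
        table[qc, rc] += 1
    total = table.sum()
    exp = np.outer(table.sum(axis=1), table.sum(axis=0)) / total
    with np.errstate(divide="ignore", invalid="ignore"):
        resid = np.where(exp > 0, (table - exp) / np.sqrt(exp), 0.0)

    if nq != nr:
        raise ValueError("query and reference have different label counts")
    best_perm, best_score = None, -np.inf
    for perm in itertools.permutations(range(nr)):
        score = sum(resid[q, perm[q]] for q in range(nq))
        if score > best_score:
            best_perm, best_score = perm, score
    mapping = {
        query.names[q]: reference.names[best_perm[q]] for q in range(nq)
    }
    # relabel query codes into the reference name table
    new_codes = np.full_like(query.codes, NA)
    for q in range(nq):
        new_codes[query.codes == q] = best_perm[q]
    relabeled = LabelTrack(
        query.layout, new_codes, reference.names, provenance=query.provenance
    )
    return mapping, resid, relabeled


def overlap_matrix(track_a: LabelTrack, track_b: LabelTrack) -> np.ndarray:
    """Percent overlap: entry (x, y) is the percent of a's label-x bins that
    carry label y in b; rows sum to 100 over b-labeled bins."""
    if track_a.layout.total_bins != track_b.layout.total_bins:
        raise ValueError("tracks are on different layouts")
    na, nb = len(track_a.names), len(track_b.names)
    out = np.zeros((na, nb))
    for x in range(na):
        in_x = track_a.codes == x
        co = track_b.codes[in_x]
        co = co[co != NA]
        if co.size == 0:
            warnings.warn(
                f"label {track_a.names[x]} shares no labeled bins with the "
                "other track; row left at zero"
            )
            continue
        for y in range(nb):
            out[x, y] = 100.0 * np.sum(co == y) / co.size
    return out
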