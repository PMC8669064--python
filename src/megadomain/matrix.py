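"""Contact-matrix container, matrix balancing, observed/expected transforms,
and the stitched odd-by-even interchromosomal matrix used for clustering.

The expected model is per-chromosome-pair mean for trans entries and
per-distance mean for cis entries; after the transform the mean of valid
entries within each expected stratum is 1 by construction. The cis
diagonal (distance 0) is excluded.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .genome import GenomeLayout

__all__ = [
    "ContactMatrix",
    "BalanceResult",
    "OEMatrix",
    "StitchedMatrix",
    "load_contacts",
    "read_triplets",
    "write_triplets",
    "balance_ice",
    "observed_expected",
    "stitch_interchromosomal",
    "default_odd_even_split",
]


@dataclass
class ContactMatrix:
    """Symmetric genome-wide binned contact counts with a validity mask."""

    layout: GenomeLayout
    counts: np.ndarray
    mask: np.ndarray

    def __post_init__(self) -> None:
        n = self.layout.total_bins
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.shape != (n, n):
            raise ValueError(f"expected {n}x{n} matrix, got {self.counts.shape}")
        if not np.allclose(self.counts, self.counts.T, rtol=1e-9, atol=1e-6):
            raise ValueError("contact matrix is not symmetric")
        self.mask = np.asarray(self.mask, dtype=bool)

    @property
    def n_bins(self) -> int:
        return self.layout.total_bins


@dataclass
class BalanceResult:
    """Iterative-correction output: bias vector and balanced matrix."""

    bias: np.ndarray          # b_i per bin; NaN on masked bins
    balanced: np.ndarray      # K_ij = C_ij / (b_i b_j)
    mask: np.ndarray
    converged: bool
    n_iter: int


@dataclass
class OEMatrix:
    """Observed/expected matrix plus the expected-model descriptor."""

    layout: GenomeLayout
    values: np.ndarray
    mask: np.ndarray
    expected_model: str  # "trans_pair_mean", "cis_distance_mean", or "both"


@dataclass
class StitchedMatrix:
    """Trans O/E with odd-chromosome bins as rows, even bins as columns."""

    values: np.ndarray            # masked entries are NaN
    row_bins: np.ndarray          # global bin indices of rows
    col_bins: np.ndarray
    row_chroms: tuple[str, ...]
    col_chroms: tuple[str, ...]
    layout: GenomeLayout


def _mask_low_coverage(counts: np.ndarray, quantile: float) -> np.ndarray:
    """Mask bins whose marginal is zero or below the given quantile of
    nonzero marginals."""
    marg = counts.sum(axis=0)
    mask = marg > 0
    nonzero = marg[mask]
    if nonzero.size and quantile > 0:
        thr = np.quantile(nonzero, quantile)
        mask &= marg >= thr
    return mask


def load_contacts(
    records: Iterable[tuple[str, int, str, int, float]],
    layout: GenomeLayout,
    mask_quantile: float = 0.01,
) -> ContactMatrix:
    """Accumulate (chrom1, start1, chrom2, start2, count) records into a
    symmetric matrix.

    Each record adds its count to both (i, j) and (j, i); duplicate records
    for the same pair sum. Bins with marginal coverage below
    ``mask_quantile`` of nonzero marginals are masked.
    """
    n = layout.total_bins
    counts = np.zeros((n, n))
    for rec_no, (c1, p1, c2, p2, c) in enumerate(records, 1):
        if c < 0:
            raise ValueError(f"record {rec_no}: negative count {c}")
        i = layout.bin_index(c1, p1)
        j = layout.bin_index(c2, p2)
        counts[i, j] += c
        if i != j:
            counts[j, i] += c
    return ContactMatrix(layout, counts, _mask_low_coverage(counts, mask_quantile))


def read_triplets(path, layout: GenomeLayout, mask_quantile: float = 0.01) -> ContactMatrix:
    """Read tab-separated (chrom1, start1, chrom2, start2, count) triplets."""

    def gen():
        with open(path) as fh:
            for line_no, line in enumerate(fh, 1):
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                parts = line.split("\t")
                if len(parts) != 5:
                    raise ValueError(f"{path}:{line_no}: expected 5 columns")
                try:
                    yield parts[0], int(parts[1]), parts[2], int(parts[3]), float(parts[4])
                except ValueError as exc:
                    raise ValueError(f"{path}:{line_no}: {exc}") from None

    return load_contacts(gen(), layout, mask_quantile)


def write_triplets(mat: ContactMatrix, path) -> None:
    """Dump the upper triangle (incl. diagonal) as text triplets.

    Integer counts round-trip exactly through :func:`read_triplets`.
    """
    layout = mat.layout
    chrom_ids = layout.bin_chrom_ids()
    starts = layout.bin_starts()
    with open(path, "w") as fh:
        fh.write("#chrom1\tstart1\tchrom2\tstart2\tcount\n")
        ii, jj = np.nonzero(np.triu(mat.counts))
        for i, j in zip(ii, jj):
            c = mat.counts[i, j]
            c_str = f"{int(c)}" if float(c).is_integer() else f"{c!r}"
            fh.write(
                f"{layout.chrom_names[chrom_ids[i]]}\t{starts[i]}\t"
                f"{layout.chrom_names[chrom_ids[j]]}\t{starts[j]}\t{c_str}\n"
            )


def balance_ice(
    mat: ContactMatrix,
    tol: float = 1e-8,
    max_iter: int = 500,
) -> BalanceResult:
    """Iterative correction to equal row sums over valid bins.

    Repeats ``b_i <- b_i * rowsum_i / mean(rowsum)`` on the corrected
    matrix until the maximum relative row-sum deviation drops below
    ``tol``. Non-convergence is flagged, never silently ignored.
    """
    mask = mat.mask.copy()
    valid = np.flatnonzero(mask)
    if valid.size < 2:
        raise ValueError("balancing requires at least 2 valid bins")
    sub = mat.counts[np.ix_(valid, valid)].astype(float)
    b = np.ones(valid.size)
    converged = False
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        k = sub / np.outer(b, b)
        rowsum = k.sum(axis=1)
        mean = rowsum.mean()
        if mean == 0:
            break
        dev = np.max(np.abs(rowsum / mean - 1.0))
        if dev < tol:
            converged = True
            break
        b *= rowsum / mean
    n = mat.n_bins
    bias = np.full(n, np.nan)
    bias[valid] = b
    balanced = np.zeros((n, n))
    balanced[np.ix_(valid, valid)] = sub / np.outer(b, b)
    return BalanceResult(bias, balanced, mask, converged, n_iter)


def observed_expected(
    balanced: np.ndarray,
    mask: np.ndarray,
    layout: GenomeLayout,
    mode: str = "both",
    trans_expected: str = "pair_mean",
) -> OEMatrix:
    """Divide a balanced matrix by its expected model.

    trans expected: mean of valid entries of each chromosome-pair block
    (``trans_expected='global'`` uses one genome-wide trans mean); cis
    expected: mean of valid entries at each bin distance within the same
    chromosome. Distance 0 (the diagonal) is always masked. Entries in a
    stratum whose expected value is 0 (or fully masked) are masked with a
    warning.
    """
    if mode not in ("both", "trans_pair_mean", "cis_distance_mean"):
        raise ValueError(f"unknown mode {mode!r}")
    n = layout.total_bins
    chrom_ids = layout.bin_chrom_ids()
    oe = np.full((n, n), np.nan)
    pair_mask = np.outer(mask, mask)
    np.fill_diagonal(pair_mask, False)

    do_trans = mode in ("both", "trans_pair_mean")
    do_cis = mode in ("both", "cis_distance_mean")

    if do_trans:
        if trans_expected == "global":
            trans_sel = pair_mask & (chrom_ids[:, None] != chrom_ids[None, :])
            exp = balanced[trans_sel].mean() if trans_sel.any() else 0.0
            if exp > 0:
                oe[trans_sel] = balanced[trans_sel] / exp
            elif trans_sel.any():
                warnings.warn("genome-wide trans stratum has zero expected value")
        else:
            for a in range(layout.n_chroms):
                ia = chrom_ids == a
                for bchr in range(a + 1, layout.n_chroms):
                    ib = chrom_ids == bchr
                    block_sel = pair_mask & np.outer(ia, ib)
                    if not block_sel.any():
                        continue
                    exp = balanced[block_sel].mean()
                    if exp == 0:
                        warnings.warn(
                            f"trans stratum ({layout.chrom_names[a]},"
                            f"{layout.chrom_names[bchr]}) fully empty; masked"
                        )
                        continue
                    vals = balanced[block_sel] / exp
                    oe[block_sel] = vals
                    oe.T[block_sel] = vals

    if do_cis:
        n_zero_strata = 0
        for a in range(layout.n_chroms):
            idx = np.flatnonzero(chrom_ids == a)
            sub = balanced[np.ix_(idx, idx)]
            submask = pair_mask[np.ix_(idx, idx)]
            m = idx.size
            sub_oe = np.full((m, m), np.nan)
            for d in range(1, m):
                di, dj = np.arange(m - d), np.arange(d, m)
                sel = submask[di, dj]
                if not sel.any():
                    continue
                exp = sub[di, dj][sel].mean()
                if exp == 0:
                    n_zero_strata += 1
                    continue
                vals = np.where(sel, sub[di, dj] / exp, np.nan)
                sub_oe[di, dj] = vals
                sub_oe[dj, di] = vals
            oe[np.ix_(idx, idx)] = sub_oe
        if n_zero_strata:
            warnings.warn(
                f"{n_zero_strata} cis distance strata had zero expected value "
                "and were masked"
            )

    model = {
        "both": "both",
        "trans_pair_mean": f"trans_{trans_expected}",
        "cis_distance_mean": "cis_distance_mean",
    }[mode]
    return OEMatrix(layout, oe, mask.copy(), model)


def _chrom_number(name: str) -> int | None:
    digits = "".join(ch for ch in name if ch.isdigit())
    return int(digits) if digits else None


def default_odd_even_split(layout: GenomeLayout) -> tuple[list[str], list[str]]:
    """Split autosomes by chromosome-number parity (chr1, chr3, ... vs
    chr2, chr4, ...); falls back to layout-position parity for unnumbered
    names."""
    odd, even = [], []
    for pos, name in enumerate(layout.chrom_names):
        num = _chrom_number(name)
        if num is None:
            num = pos + 1
        (odd if num % 2 == 1 else even).append(name)
    return odd, even


def stitch_interchromosomal(
    oe: OEMatrix,
    odd_set: Sequence[str] | None = None,
    even_set: Sequence[str] | None = None,
) -> StitchedMatrix:
    """Rectangular trans O/E matrix: odd-chromosome bins serially as rows,
    even-chromosome bins serially as columns."""
    layout = oe.layout
    if odd_set is None or even_set is None:
        odd_set, even_set = default_odd_even_split(layout)
    odd_set, even_set = list(odd_set), list(even_set)
    if set(odd_set) & set(even_set):
        raise ValueError("odd and even chromosome sets overlap")
    chrom_ids = layout.bin_chrom_ids()
    odd_ids = [layout.chrom_index(c) for c in odd_set]
    even_ids = [layout.chrom_index(c) for c in even_set]
    row_bins = np.concatenate([np.flatnonzero(chrom_ids == c) for c in odd_ids])
    col_bins = np.concatenate([np.flatnonzero(chrom_ids == c) for c in even_ids])
    values = oe.values[np.ix_(row_bins, col_bins)].copy()
    values[~oe.mask[row_bins], :] = np.nan
    values[:, ~oe.mask[col_bins]] = np.nan
    return StitchedMatrix(
        values, row_bins, col_bins, tuple(odd_set), tuple(even_set), layout
    )
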