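"""Strain comparison and differential-contact summaries.

The strain comparison restricts O/E matrices to repeat hotspot bins,
sums replicates per condition, and applies a paired two-sided Wilcoxon
signed-rank test over the matched entries. Differential-contact tables
(an upstream negative-binomial engine's output) are rolled up to 1-Mb
subcompartment labels and summarized as Pearson residuals against a
label-size expected model, separately for increased and decreased
contacts; the reported statistic is the per-pair difference of residuals.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .genome import BinVector, GenomeLayout
from .matrix import OEMatrix
from .subcompartments import NA, LabelTrack

__all__ = [
    "ReducedMatrix",
    "hotspot_submatrix",
    "paired_matrix_test",
    "rollup_labels",
    "residual_summary",
    "contacts_per_window",
    "read_differential_contacts",
]


@dataclass
class ReducedMatrix:
    """O/E entries over hotspot bins only, optionally summed replicates."""

    values: np.ndarray       # square, NaN where masked
    bin_ids: np.ndarray      # global bin indices of rows/columns
    layout: GenomeLayout
    meta: str = ""
    summed_replicates: bool = False

    @property
    def n(self) -> int:
        return self.bin_ids.size


def hotspot_submatrix(
    samples: Sequence[OEMatrix] | OEMatrix,
    hot: BinVector,
    meta: str = "",
) -> ReducedMatrix:
    """Restrict O/E matrices to hotspot bins; multiple samples are summed
    entrywise (replicates combined by cell type and strain)."""
    if isinstance(samples, OEMatrix):
        samples = [samples]
    if not samples:
        raise ValueError("no samples given")
    hot_idx = np.flatnonzero(hot.values.astype(bool) & hot.mask)
    if hot_idx.size == 0:
        raise ValueError("zero hotspot bins")
    acc = None
    for oe in samples:
        sub = oe.values[np.ix_(hot_idx, hot_idx)]
        acc = sub.copy() if acc is None else acc + sub
    return ReducedMatrix(
        acc, hot_idx, samples[0].layout, meta, summed_replicates=len(samples) > 1
    )


def paired_matrix_test(
    a: ReducedMatrix,
    b: ReducedMatrix,
    trans_only: bool = False,
) -> dict:
    """Paired two-sided Wilcoxon signed-rank test over matched entries.

    Pairs are the unordered off-diagonal entries (i < j) valid in both
    matrices; with ``trans_only`` restricted to inter-chromosomal pairs.
    Zero differences are dropped (Wilcoxon convention). Exact null
    distribution for n <= 25 informative pairs, normal approximation with
    continuity correction above.
    """
    if a.n != b.n or not np.array_equal(a.bin_ids, b.bin_ids):
        raise ValueError("reduced matrices cover different bin sets")
    iu, ju = np.triu_indices(a.n, k=1)
    if trans_only:
        chrom = a.layout.bin_chrom_ids()[a.bin_ids]
        keep = chrom[iu] != chrom[ju]
        iu, ju = iu[keep], ju[keep]
    va, vb = a.values[iu, ju], b.values[iu, ju]
    ok = ~np.isnan(va) & ~np.isnan(vb)
    va, vb = va[ok], vb[ok]
    diffs = va - vb
    n_pairs = diffs.size
    nz = diffs[diffs != 0]
    if n_pairs < 5:
        warnings.warn(f"only {n_pairs} valid pairs; test is underpowered")
    if nz.size == 0:
        warnings.warn("all paired differences are zero; test is degenerate")
        return {
            "p_value": 1.0,
            "statistic": np.nan,
            "n_pairs": n_pairs,
            "n_nonzero": 0,
            "median_diff": 0.0,
        }
    method = "exact" if nz.size <= 25 else "approx"
    res = stats.wilcoxon(
        nz,
        alternative="two-sided",
        method=method,
        correction=(method == "approx"),
    )
    return {
        "p_value": float(res.pvalue),
        "statistic": float(res.statistic),
        "n_pairs": n_pairs,
        "n_nonzero": int(nz.size),
        "median_diff": float(np.median(diffs)),
    }


def rollup_labels(labels: LabelTrack, target_bin: int) -> LabelTrack:
    """Re-label a track at a coarser bin size (250 kb -> 1 Mb).

    Each coarse window takes the label covering the largest fraction of
    its labeled extent; ties go to the label with the smallest genome-wide
    size. Windows with no labeled source bins are NA.
    """
    src = labels.layout
    if target_bin % src.bin_size != 0:
        raise ValueError("target bin size must be a multiple of the source")
    ratio = target_bin // src.bin_size
    coarse = src.with_bin_size(target_bin)
    sizes = labels.sizes_bp()
    src_lengths = src.bin_lengths()
    out = np.full(coarse.total_bins, NA)
    for ci in range(src.n_chroms):
        src_off = int(src.chrom_offsets[ci])
        src_n = int(src.bins_per_chrom[ci])
        coarse_off = int(coarse.chrom_offsets[ci])
        coarse_n = int(coarse.bins_per_chrom[ci])
        for w in range(coarse_n):
            lo = src_off + w * ratio
            hi = min(src_off + (w + 1) * ratio, src_off + src_n)
            window_codes = labels.codes[lo:hi]
            window_len = src_lengths[lo:hi]
            cov: dict[int, int] = {}
            for code, length in zip(window_codes, window_len):
                if code != NA:
                    cov[int(code)] = cov.get(int(code), 0) + int(length)
            if not cov:
                continue
            best = min(
                cov.items(),
                key=lambda cl: (-cl[1], sizes[labels.names[cl[0]]]),
            )
            out[coarse_off + w] = best[0]
    return LabelTrack(coarse, out, labels.names, labels.provenance)


def read_differential_contacts(path) -> pd.DataFrame:
    """Differential contacts TSV: chrom1, start1, chrom2, start2, log2FC,
    padj, direction (header lines start with '#')."""
    cols = ["chrom1", "start1", "chrom2", "start2", "log2fc", "padj", "direction"]
    with open(path) as fh:
        first = next(
            (ln for ln in fh if ln.strip() and not ln.startswith("#")), ""
        )
    header = 0 if first.split("\t")[0].strip() == "chrom1" else None
    df = pd.read_csv(path, sep="\t", comment="#", header=header, names=cols)
    if not df["direction"].isin(["up", "down"]).all():
        raise ValueError("direction must be 'up' or 'down'")
    if not df["padj"].between(0, 1).all():
        raise ValueError("padj outside [0, 1]")
    return df


def _label_pairs(names: Sequence[str]) -> list[tuple[str, str]]:
    return [
        (names[i], names[j])
        for i in range(len(names))
        for j in range(i, len(names))
    ]


def annotate_contacts(
    diffs: pd.DataFrame, labels_1mb: LabelTrack
) -> pd.DataFrame:
    """Attach the 1-Mb subcompartment label pair to each contact; contacts
    with an NA endpoint are dropped."""
    layout = labels_1mb.layout
    lab = labels_1mb.labels
    rows = []
    for rec in diffs.itertuples(index=False):
        b1 = layout.bin_index(rec.chrom1, rec.start1)
        b2 = layout.bin_index(rec.chrom2, rec.start2)
        l1, l2 = lab[b1], lab[b2]
        if l1 == "NA" or l2 == "NA":
            continue
        pair = tuple(sorted((l1, l2)))
        rows.append({**rec._asdict(), "label1": pair[0], "label2": pair[1]})
    return pd.DataFrame(rows)


def residual_summary(
    diffs: pd.DataFrame,
    labels_1mb: LabelTrack,
    expected_model: str = "quadratic",
) -> pd.DataFrame:
    """Pearson residuals of differential-contact label pairs against a
    label-size expected model, and the up-minus-down residual difference.

    For each direction with N contacts, the expected count of pair (X, Y)
    is ``N * 2 p_X p_Y`` for X != Y and ``N * p_X^2`` for X == Y, where
    p is the genome fraction of the label over the labeled extent
    (``expected_model='linear'`` instead splits each contact's two
    endpoints by label marginals). r = (obs - exp)/sqrt(exp);
    r_diff = r_up - r_down.
    """
    ann = annotate_contacts(diffs, labels_1mb)
    sizes = labels_1mb.sizes_bp()
    total = sum(sizes.values())
    if total == 0:
        raise ValueError("label track has no labeled extent")
    p = {name: sizes[name] / total for name in labels_1mb.names}
    if abs(sum(p.values()) - 1.0) > 1e-9:
        raise ValueError("label fractions do not sum to 1 over the labeled genome")
    pairs = _label_pairs(labels_1mb.names)

    stats_rows: dict[tuple[str, str], dict] = {
        pair: {"pair": f"{pair[0]}-{pair[1]}", "label1": pair[0], "label2": pair[1]}
        for pair in pairs
    }
    for direction in ("up", "down"):
        sub = ann[ann["direction"] == direction] if len(ann) else ann
        n_dir = len(sub)
        counts = {pair: 0 for pair in pairs}
        for rec in sub.itertuples(index=False):
            counts[(rec.label1, rec.label2)] += 1
        for x, y in pairs:
            if expected_model == "quadratic":
                prob = 2 * p[x] * p[y] if x != y else p[x] ** 2
            elif expected_model == "linear":
                prob = (p[x] + p[y]) / 2 if x != y else p[x] / 2
            else:
                raise ValueError(f"unknown expected model {expected_model!r}")
            exp = n_dir * prob
            obs = counts[(x, y)]
            r = (obs - exp) / np.sqrt(exp) if exp > 0 else np.nan
            row = stats_rows[(x, y)]
            row[f"obs_{direction}"] = obs
            row[f"exp_{direction}"] = exp
            row[f"r_{direction}"] = r
    df = pd.DataFrame(stats_rows.values())
    df["r_diff"] = df["r_up"] - df["r_down"]
    df["r_diff_abs"] = df["r_diff"].abs()
    return df


def contacts_per_window(
    diffs: pd.DataFrame,
    labels_1mb: LabelTrack,
    pair: tuple[str, str],
    window: int = 10_000_000,
) -> float:
    """Contact density: count of contacts with the given label pair per
    ``window`` of the anchor label's genomic extent.

    The anchor is ``pair[0]``; density = count / (extent(anchor)/window).
    """
    x, y = pair
    extent = labels_1mb.size_bp(x)  # KeyError for unknown labels
    if extent == 0:
        raise ValueError(f"label {x!r} has zero genomic extent")
    ann = annotate_contacts(diffs, labels_1mb)
    want = tuple(sorted((x, y)))
    if len(ann) == 0:
        n = 0
    else:
        n = int(((ann["label1"] == want[0]) & (ann["label2"] == want[1])).sum())
    return n / (extent / window)
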