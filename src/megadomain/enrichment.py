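"""Binned feature association statistics.

Hotspot bins are those whose feature count strictly exceeds the
nearest-rank 99th percentile across valid autosomal bins; the RNA variant
flags any bin with a nonzero count. Per (subcompartment, feature) pair a
one-sided Fisher 2x2 exact test asks whether high bins are enriched in
that subcompartment. Raw p-values are reported; Benjamini-Hochberg is
available behind a flag.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .genome import BinVector, GenomicInterval, covered_bins
from .subcompartments import NA, LabelTrack

__all__ = [
    "HotspotParams",
    "AssociationResult",
    "hotspot_bins",
    "fisher_association",
    "association_scan",
    "concordance_profile",
    "nearest_rank_percentile",
]


@dataclass(frozen=True)
class HotspotParams:
    """High/low thresholding for association testing.

    ``mode='hotspot'``: high iff count strictly exceeds the nearest-rank
    q-th percentile of valid-bin counts. ``mode='any_nonzero'``: high iff
    count > 0 (the RNA-association rule).
    """

    q: float = 99.0
    mode: str = "hotspot"

    def __post_init__(self) -> None:
        if not 0 < self.q < 100:
            raise ValueError("percentile must be in (0, 100)")
        if self.mode not in ("hotspot", "any_nonzero"):
            raise ValueError(f"unknown mode {self.mode!r}")


@dataclass
class AssociationResult:
    """2x2 table and one-sided Fisher outcome for one (label, feature)."""

    label: str
    feature: str
    n_label_high: int
    n_label_low: int
    n_other_high: int
    n_other_low: int
    odds_ratio: float
    p_value: float

    @property
    def neg_log10_p(self) -> float:
        return -math.log10(self.p_value)


def nearest_rank_percentile(values: np.ndarray, q: float) -> float:
    """Nearest-rank percentile: the value at 1-based rank ceil(q/100 * n)
    of the ascending-sorted sample."""
    values = np.sort(np.asarray(values))
    n = values.size
    if n == 0:
        raise ValueError("empty sample")
    rank = max(1, math.ceil(q / 100.0 * n))
    return float(values[rank - 1])


def hotspot_bins(counts: BinVector, params: HotspotParams = HotspotParams()) -> BinVector:
    """Boolean per-bin vector of 'high' bins under the chosen rule.

    Masked bins are never high. The percentile is taken over all valid
    bins (zeros included).
    """
    if not counts.mask.any():
        raise ValueError("all bins are masked")
    high = np.zeros(counts.values.shape, dtype=bool)
    if params.mode == "any_nonzero":
        high[counts.mask] = counts.values[counts.mask] > 0
    else:
        thr = nearest_rank_percentile(counts.valid_values(), params.q)
        high[counts.mask] = counts.values[counts.mask] > thr
    return BinVector(counts.layout, high, counts.mask.copy())


def _odds_ratio(a: int, b: int, c: int, d: int) -> float:
    """Sample odds ratio with a Haldane 0.5 correction when any cell is 0."""
    if min(a, b, c, d) == 0:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    return (a * d) / (b * c)


def fisher_association(
    labels: LabelTrack,
    high: BinVector,
    label: str,
    feature: str = "",
) -> AssociationResult:
    """One-sided Fisher 2x2 exact test of 'high' enrichment in a label.

    The p-value is the upper hypergeometric tail: the probability, with
    margins fixed, of at least the observed number of high bins carrying
    the label.
    """
    code = labels.code_of(label)  # raises KeyError for unknown labels
    valid = high.mask & (labels.codes != NA)
    if not valid.any():
        raise ValueError("no valid labeled bins")
    is_label = labels.codes[valid] == code
    if not is_label.any():
        raise ValueError(f"label {label!r} absent from the valid bins")
    is_high = high.values[valid].astype(bool)
    a = int(np.sum(is_label & is_high))
    b = int(np.sum(is_label & ~is_high))
    c = int(np.sum(~is_label & is_high))
    d = int(np.sum(~is_label & ~is_high))
    _, p = stats.fisher_exact([[a, b], [c, d]], alternative="greater")
    return AssociationResult(
        label, feature, a, b, c, d, _odds_ratio(a, b, c, d), float(min(p, 1.0))
    )


def association_scan(
    labels: LabelTrack,
    feature_tracks: Mapping[str, BinVector],
    params: HotspotParams = HotspotParams(),
    bh_correct: bool = False,
) -> pd.DataFrame:
    """Full label x feature grid of one-sided Fisher tests.

    Returns a tidy frame with the 2x2 counts, odds ratio, raw p, and
    -log10 p per (label, feature); optionally adds a Benjamini-Hochberg
    adjusted column.
    """
    if not feature_tracks:
        raise ValueError("at least one feature track is required")
    rows = []
    for feature, counts in feature_tracks.items():
        high = hotspot_bins(counts, params)
        for label in labels.names:
            r = fisher_association(labels, high, label, feature)
            rows.append(
                {
                    "label": r.label,
                    "feature": r.feature,
                    "n_label_high": r.n_label_high,
                    "n_label_low": r.n_label_low,
                    "n_other_high": r.n_other_high,
                    "n_other_low": r.n_other_low,
                    "odds_ratio": r.odds_ratio,
                    "p_value": r.p_value,
                    "neg_log10_p": r.neg_log10_p,
                }
            )
    df = pd.DataFrame(rows)
    if bh_correct:
        from statsmodels.stats.multitest import multipletests

        df["p_adj_bh"] = multipletests(df["p_value"], method="fdr_bh")[1]
    return df


def concordance_profile(
    labels: LabelTrack,
    tracks: Mapping[str, Sequence[GenomicInterval]],
) -> pd.DataFrame:
    """Fraction of each label's bins overlapped (>=1 bp) by each track."""
    cover = {
        name: covered_bins(ivs, labels.layout) for name, ivs in tracks.items()
    }
    rows = []
    for label in labels.names:
        bins = labels.bins_with(label)
        for name, cov in cover.items():
            frac = float(cov[bins].mean()) if bins.size else 0.0
            rows.append({"label": label, "track": name, "fraction": frac})
    return pd.DataFrame(rows)
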