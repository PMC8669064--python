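"""Long-read de novo retroelement insertion calling.

Each circular-consensus read is matched against the internal element
consensus (6481 bp for the IAPEzi model) with the local aligner; reads
without a confident consensus hit are dropped. The read's flanks are
anchored to the genome through MAPQ-filtered flank alignments (exact
MAPQ 60 by default); anchored coordinates overlapping annotated element
sites are classed as annotated, and the rest are arbitrated by comparing
bit scores of the read against the consensus versus the element-masked
reference: strictly higher consensus bits means de novo. A call is
full-length when its matched consensus length reaches the smallest
integer exceeding 90% of the consensus length (5833 bp).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .align import Scoring, build_kmer_index, local_align
from .genome import GenomicInterval
from .subcompartments import NA, LabelTrack

__all__ = [
    "ConsensusModel",
    "ConsensusHit",
    "FlankAlignment",
    "InsertionCall",
    "match_consensus",
    "anchor_to_genome",
    "classify_insertion",
    "flag_full_length",
    "classify_reads",
    "compartment_enrichment",
]


@dataclass
class ConsensusModel:
    """An internal-element consensus and its full-length rule."""

    name: str
    sequence: str
    full_length_frac: float = 0.9
    scoring: Scoring = field(default_factory=Scoring)

    def __post_init__(self) -> None:
        if not 0 < self.full_length_frac <= 1:
            raise ValueError("full_length_frac must be in (0, 1]")
        self._index = None

    @property
    def length(self) -> int:
        return len(self.sequence)

    @property
    def full_length_cutoff(self) -> int:
        """Smallest integer matched length strictly exceeding
        full_length_frac * consensus length."""
        return math.floor(self.full_length_frac * self.length) + 1

    def kmer_index(self) -> dict:
        if self._index is None:
            from .align import encode_seq

            self._index = build_kmer_index(encode_seq(self.sequence))
        return self._index


@dataclass(frozen=True)
class ConsensusHit:
    """A read's best local alignment against the consensus."""

    read_id: str
    span: tuple[int, int]      # half-open span on the consensus
    matched_length: int        # consensus bases aligned to read bases
    score: int
    bit_score: float
    strand: str
    read_span: tuple[int, int]


@dataclass(frozen=True)
class FlankAlignment:
    """A genomic alignment of the read portion outside the consensus match."""

    read_id: str
    side: str        # "left" or "right" of the consensus match in the read
    chrom: str
    start: int
    end: int
    mapq: int


@dataclass
class InsertionCall:
    read_id: str
    sample_id: str
    chrom: str | None
    pos: int | None
    call_class: str            # annotated_element / annotated_other / de_novo / unresolved
    full_length: bool
    flank_mapq: int | None
    bit_consensus: float
    bit_masked_ref: float | None
    label: str = "NA"


def match_consensus(
    read_seq: str,
    model: ConsensusModel,
    min_bits: float = 50.0,
    read_id: str = "",
) -> ConsensusHit | None:
    """Best both-strand local alignment of a read to the consensus; hits
    below ``min_bits`` are discarded."""
    if not read_seq:
        raise ValueError("empty read sequence")
    res = local_align(
        read_seq,
        model.sequence,
        model.scoring,
        both_strands=True,
        target_index=model.kmer_index(),
    )
    if res is None:
        return None
    bits = res.bits(model.scoring)
    if bits < min_bits:
        return None
    return ConsensusHit(
        read_id,
        (res.t_start, res.t_end),
        res.matched_length,
        res.score,
        bits,
        res.strand,
        (res.q_start, res.q_end),
    )


def flag_full_length(hit: ConsensusHit, model: ConsensusModel) -> bool:
    """True iff the matched consensus length reaches the full-length cutoff."""
    return hit.matched_length >= model.full_length_cutoff


def anchor_to_genome(
    flanks: Sequence[FlankAlignment],
    mapq_min: int = 60,
    mapq_exact: bool = True,
    concordance_bp: int = 50,
) -> tuple[str, int] | None | str:
    """Insertion coordinate from MAPQ-filtered flank alignments.

    Keeps alignments with MAPQ equal to ``mapq_min`` (or >= with
    ``mapq_exact=False``). A left flank places the insertion at its end,
    a right flank at its start; two passing flanks must agree within
    ``concordance_bp`` on the same chromosome, else the read is
    "unresolved". No passing flank returns None (unanchored).
    """
    passing = [
        f
        for f in flanks
        if (f.mapq == mapq_min if mapq_exact else f.mapq >= mapq_min)
    ]
    if not passing:
        return None
    coords: list[tuple[str, int]] = []
    for f in passing:
        if f.side == "left":
            coords.append((f.chrom, f.end))
        elif f.side == "right":
            coords.append((f.chrom, f.start))
        else:
            raise ValueError(f"unknown flank side {f.side!r}")
    if len(coords) == 1:
        return coords[0]
    (c1, p1), (c2, p2) = coords[:2]
    if c1 != c2 or abs(p1 - p2) > concordance_bp:
        return "unresolved"
    return c1, (p1 + p2) // 2


def _overlaps(chrom: str, pos: int, iv: GenomicInterval) -> bool:
    return iv.chrom == chrom and iv.start <= pos < iv.end


def classify_insertion(
    coordinate: tuple[str, int],
    known_sites: Sequence[GenomicInterval],
    target_family: str,
    bit_consensus: float,
    bit_masked_ref: float,
) -> str:
    """Arbitrate a call: annotated sites take precedence over bit scores.

    A coordinate inside a known site of the target family is
    ``annotated_element``; inside any other family's site,
    ``annotated_other``. Otherwise the call is ``de_novo`` iff the
    consensus bit score strictly exceeds the masked-reference bit score;
    ties are conservatively ``unresolved``.
    """
    chrom, pos = coordinate
    for iv in known_sites:
        if _overlaps(chrom, pos, iv):
            family = iv.name or target_family
            return (
                "annotated_element" if family == target_family else "annotated_other"
            )
    if bit_consensus > bit_masked_ref:
        return "de_novo"
    return "unresolved"


def classify_reads(
    reads: Mapping[str, str],
    model: ConsensusModel,
    flank_alignments: Mapping[str, Sequence[FlankAlignment]],
    known_sites: Sequence[GenomicInterval],
    masked_ref_window: Callable[[str, int], str | None],
    sample_id: str = "",
    min_bits: float = 50.0,
    mapq_min: int = 60,
    mapq_exact: bool = True,
) -> pd.DataFrame:
    """End-to-end calling over a read set.

    ``masked_ref_window`` maps an anchored coordinate to the
    element-masked reference sequence around it (None when unavailable);
    the read is aligned against that window for the bit-score
    arbitration. Reads without a consensus hit or without an anchor are
    omitted from the output table.
    """
    rows = []
    for read_id, seq in reads.items():
        hit = match_consensus(seq, model, min_bits=min_bits, read_id=read_id)
        if hit is None:
            continue
        anchor = anchor_to_genome(
            flank_alignments.get(read_id, ()), mapq_min, mapq_exact
        )
        if anchor is None:
            continue
        full = flag_full_length(hit, model)
        if anchor == "unresolved":
            rows.append(
                InsertionCall(
                    read_id, sample_id, None, None, "unresolved", full,
                    None, hit.bit_score, None,
                )
            )
            continue
        chrom, pos = anchor
        mapqs = [
            f.mapq
            for f in flank_alignments.get(read_id, ())
            if (f.mapq == mapq_min if mapq_exact else f.mapq >= mapq_min)
        ]
        bit_masked = None
        on_known = any(_overlaps(chrom, pos, iv) for iv in known_sites)
        if not on_known:
            window = masked_ref_window(chrom, pos)
            if window:
                ref_res = local_align(
                    seq, window, model.scoring, both_strands=True
                )
                bit_masked = (
                    ref_res.bits(model.scoring) if ref_res is not None else 0.0
                )
            else:
                bit_masked = 0.0
        call = classify_insertion(
            (chrom, pos), known_sites, model.name, hit.bit_score,
            bit_masked if bit_masked is not None else np.inf,
        )
        rows.append(
            InsertionCall(
                read_id, sample_id, chrom, pos, call, full,
                max(mapqs) if mapqs else None, hit.bit_score, bit_masked,
            )
        )
    return pd.DataFrame([vars(c) for c in rows])


def _assign_labels(calls: pd.DataFrame, labels: LabelTrack) -> pd.DataFrame:
    out = calls.copy()
    lab = labels.labels
    assigned = []
    for rec in out.itertuples(index=False):
        if rec.chrom is None or rec.chrom not in labels.layout.chrom_names:
            assigned.append("NA")
            continue
        try:
            assigned.append(lab[labels.layout.bin_index(rec.chrom, rec.pos)])
        except ValueError:
            assigned.append("NA")
    out["label"] = assigned
    return out


def compartment_enrichment(
    calls_per_sample: Mapping[str, pd.DataFrame],
    labels: LabelTrack,
    subset: str = "all",
    classes: Sequence[str] = ("de_novo",),
) -> pd.DataFrame:
    """Per-sample observed/expected of insertion calls per subcompartment.

    ``subset='full'`` keeps only full-length calls. Expected counts are
    proportional to label genome fractions over the labeled extent; O/E
    is masked (NaN) for labels with zero extent.
    """
    if subset not in ("all", "full"):
        raise ValueError(f"unknown subset {subset!r}")
    sizes = labels.sizes_bp()
    total = sum(sizes.values())
    rows = []
    for sample, calls in calls_per_sample.items():
        if len(calls) == 0:
            raise ValueError(f"sample {sample!r} has no calls")
        sub = calls[calls["call_class"].isin(classes)]
        if subset == "full":
            sub = sub[sub["full_length"]]
        sub = _assign_labels(sub, labels)
        sub = sub[sub["label"] != "NA"]
        n = len(sub)
        for name in labels.names:
            frac = sizes[name] / total if total else 0.0
            obs = int((sub["label"] == name).sum())
            exp = n * frac
            rows.append(
                {
                    "sample": sample,
                    "label": name,
                    "subset": subset,
                    "observed": obs,
                    "expected": exp,
                    "oe": obs / exp if exp > 0 else np.nan,
                }
            )
    return pd.DataFrame(rows)


def paired_all_vs_full_test(
    all_oe: pd.DataFrame, full_oe: pd.DataFrame, label: str
) -> dict:
    """Paired two-sided Wilcoxon of all-call vs full-length-call O/E for
    one subcompartment across samples."""
    a = all_oe[all_oe["label"] == label].set_index("sample")["oe"]
    f = full_oe[full_oe["label"] == label].set_index("sample")["oe"]
    common = a.index.intersection(f.index)
    d = (a[common] - f[common]).dropna()
    d = d[d != 0]
    if len(d) == 0:
        return {"p_value": 1.0, "n": 0}
    res = stats.wilcoxon(d, alternative="two-sided", method="exact" if len(d) <= 25 else "approx")
    return {"p_value": float(res.pvalue), "n": int(len(d))}
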