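"""Seeded synthetic-data generator with planted truth.

Every analysis stage gets a download-free test surface: a block-structured
subcompartment genome, compartment-patterned Poisson contact maps with
distance decay, repeat annotations with a planted family-by-compartment
enrichment, LAD tracks with tunable concordance, two-strain contact pairs
with a dosage factor at repeat hotspots, and long reads carrying an
element consensus with genomic flanks.

All generators are deterministic per (config, seed). The generator states
the simulated conditions; it makes no claim about the generative process
of real Hi-C or SMRT data.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from .enrichment import HotspotParams, hotspot_bins
from .genome import BinVector, GenomeLayout, GenomicInterval
from .matrix import ContactMatrix, _mask_low_coverage
from .subcompartments import LabelTrack

__all__ = [
    "SimulationConfig",
    "SyntheticTruth",
    "ReadSimulation",
    "simulate_genome_labels",
    "simulate_contacts",
    "simulate_annotations",
    "simulate_strain_pair",
    "simulate_reads",
    "simulate_truth",
]

LABELS = ("A1", "A2", "B1", "B2")
SIM_CLASSES = ("A1", "A2", "B1", "B2", "M1", "M2")


@dataclass
class SimulationConfig:
    """Generator parameters; defaults are the package's standard test bed.

    The genome is 8 chromosomes x 20 Mb at 250-kb bins. Subcompartment
    proportions decrease A1 > A2 = B1 > B2 with B2 the smallest;
    same-label trans contact affinity is 2.5x the cross-label baseline
    (3x for B2-B2), i.e. a contrast of at least 2. Repeat families are
    planted with a 3-fold density boost in one compartment each, the
    ERV2-like family in B2.
    """

    n_chrom: int = 8
    chrom_length: int = 20_000_000
    bin_size: int = 250_000
    proportions: dict = field(
        default_factory=lambda: {"A1": 0.42, "A2": 0.28, "B1": 0.18, "B2": 0.12}
    )
    mean_block_bp: dict = field(
        default_factory=lambda: {
            "A1": 4_000_000,
            "A2": 3_000_000,
            "B1": 3_000_000,
            "B2": 2_000_000,
        }
    )
    self_affinity: float = 2.5
    b2_affinity: float = 3.0
    cross_affinity: float = 1.0
    micro1_bins_per_chrom: int = 2   # sub-5% satellite cluster, all chromosomes
    micro2_bins_per_odd_chrom: int = 3  # satellite present only on odd chromosomes
    cis_decay_alpha: float = 1.0
    trans_depth: float = 50.0
    cis_depth: float = 200.0
    repeat_base_rate: float = 3.0
    repeat_fold: float = 3.0
    repeat_families: dict = field(
        default_factory=lambda: {
            "ERV2": "B2",
            "LINE": "B1",
            "SINE": "A2",
            "ERV3": "A1",
        }
    )
    repeat_length: int = 500
    lad_sensitivity: float = 0.95
    lad_specificity: float = 0.95
    strain_dosage: float = 1.5
    hotspot_percentile: float = 99.0
    # long-read generation
    consensus_length: int = 6481
    flank_length: int = 1000
    n_reads: int = 200
    read_error_rate: float = 0.001
    read_mix: dict = field(
        default_factory=lambda: {
            "annotated_element": 0.35,
            "annotated_other": 0.10,
            "de_novo": 0.40,
            "ref_present": 0.05,
            "decoy": 0.10,
        }
    )
    de_novo_full_frac: float = 0.5
    min_fragment: int = 2000
    de_novo_b2_bias: float = 4.0
    n_known_sites: int = 30
    seed: int = 0

    def __post_init__(self) -> None:
        total = sum(self.proportions.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError("label proportions must sum to 1")
        if any(v <= 0 for v in self.proportions.values()):
            raise ValueError("label proportions must be positive")
        if self.cis_decay_alpha <= 0:
            raise ValueError("cis decay exponent must be positive")

    def layout(self) -> GenomeLayout:
        names = tuple(f"chr{i + 1}" for i in range(self.n_chrom))
        return GenomeLayout(names, (self.chrom_length,) * self.n_chrom, self.bin_size)

    def affinity_matrix(self) -> np.ndarray:
        """Contact propensity per simulated-class pair.

        Classes are the four subcompartments plus two small satellite
        classes (emulating the minor clusters real maps produce, which
        the <5% filter discards; the second exists only on odd
        chromosomes, mirroring the odd/even cluster-count asymmetry).
        """
        n = len(SIM_CLASSES)
        a = np.full((n, n), self.cross_affinity)
        for i, lab in enumerate(LABELS):
            a[i, i] = self.b2_affinity if lab == "B2" else self.self_affinity
        m1, m2 = SIM_CLASSES.index("M1"), SIM_CLASSES.index("M2")
        a[m1, :] = a[:, m1] = 0.8
        a[m1, m1] = 5.0
        a[m2, :] = a[:, m2] = 0.5
        a[m2, 0] = a[0, m2] = 2.2
        a[m2, m2] = 4.0
        return a

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)


@dataclass
class SyntheticTruth:
    """Planted ground truth for a simulated genome.

    ``labels`` carries the four subcompartments with NA on satellite
    bins; ``sim_codes`` is the full simulated class per bin (including
    the satellites) used to parameterize contact intensities.
    """

    config: SimulationConfig
    labels: LabelTrack
    sim_codes: np.ndarray = None  # type: ignore[assignment]
    repeats: dict = field(default_factory=dict)        # family -> intervals
    repeat_counts: dict = field(default_factory=dict)  # family -> BinVector
    lads: list = field(default_factory=list)


@dataclass
class ReadSimulation:
    """One simulated long-read sample with planted insertion truth."""

    sample_id: str
    reads: dict                      # read_id -> sequence
    consensus: str
    known_sites: list                # GenomicInterval with family names
    flank_alignments: dict           # read_id -> [FlankAlignment]
    ref_windows: dict                # (chrom, pos) -> masked-reference window
    truth: pd.DataFrame


def _rng(seed: int) -> np.random.Generator:
    return np.random.default_rng(seed)


def simulate_genome_labels(
    config: SimulationConfig, seed: int | None = None
) -> SyntheticTruth:
    """Plant label blocks with geometric lengths and quota-balanced totals.

    Per-label bin quotas are fixed from the target proportions, so the
    realized genome-wide fractions land within about +/-2% of the targets;
    block lengths are geometric around the per-label mean (B2 blocks are
    the 1-12 Mb scale islands).
    """
    rng = _rng(config.seed if seed is None else seed)
    layout = config.layout()
    sim_codes = np.empty(layout.total_bins, dtype=np.int64)
    for ci in range(layout.n_chroms):
        off = int(layout.chrom_offsets[ci])
        n = int(layout.bins_per_chrom[ci])
        quota = {
            lab: int(round(config.proportions[lab] * n)) for lab in LABELS
        }
        quota[max(quota, key=quota.get)] += n - sum(quota.values())
        if min(quota.values()) < 1:
            raise ValueError("proportions infeasible for this genome size")
        pos, prev = 0, None
        while pos < n:
            avail = [lab for lab in LABELS if quota[lab] > 0 and lab != prev]
            if not avail:
                avail = [lab for lab in LABELS if quota[lab] > 0] or list(LABELS)
            weights = np.array([max(quota[lab], 0) + 1e-9 for lab in avail])
            lab = avail[rng.choice(len(avail), p=weights / weights.sum())]
            mean_bins = max(1, config.mean_block_bp[lab] // config.bin_size)
            length = int(rng.geometric(1.0 / mean_bins))
            length = min(length, n - pos, max(quota[lab], 1))
            sim_codes[off + pos : off + pos + length] = LABELS.index(lab)
            quota[lab] -= length
            pos += length
            prev = lab
        # satellite classes: small blocks that real maps also produce and
        # the <5% cluster filter is meant to discard
        m1 = SIM_CLASSES.index("M1")
        m2 = SIM_CLASSES.index("M2")
        if config.micro1_bins_per_chrom > 0:
            start = int(rng.integers(0, n - config.micro1_bins_per_chrom + 1))
            sim_codes[off + start : off + start + config.micro1_bins_per_chrom] = m1
        if config.micro2_bins_per_odd_chrom > 0 and ci % 2 == 0:
            width = config.micro2_bins_per_odd_chrom
            while True:
                start = int(rng.integers(0, n - width + 1))
                if not np.any(sim_codes[off + start : off + start + width] == m1):
                    break
            sim_codes[off + start : off + start + width] = m2

    label_codes = np.where(sim_codes < len(LABELS), sim_codes, -1)
    track = LabelTrack(layout, label_codes, LABELS, provenance="synthetic")
    return SyntheticTruth(config, track, sim_codes=sim_codes)


def _lambda_matrix(truth: SyntheticTruth) -> np.ndarray:
    config = truth.config
    layout = truth.labels.layout
    codes = (
        truth.sim_codes if truth.sim_codes is not None else truth.labels.codes
    )
    n = layout.total_bins
    aff = config.affinity_matrix()
    a = aff[np.ix_(codes, codes)]
    chrom_ids = layout.bin_chrom_ids()
    same = chrom_ids[:, None] == chrom_ids[None, :]
    idx = np.arange(n)
    dist = np.abs(idx[:, None] - idx[None, :]).astype(float)
    np.fill_diagonal(dist, 1.0)
    lam = np.where(
        same,
        config.cis_depth * a * dist ** (-config.cis_decay_alpha),
        config.trans_depth * a,
    )
    return lam


def _poisson_symmetric(
    lam: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    n = lam.shape[0]
    iu = np.triu_indices(n)
    counts = np.zeros((n, n))
    draws = rng.poisson(lam[iu])
    counts[iu] = draws
    counts.T[iu] = draws
    return counts


def simulate_contacts(
    truth: SyntheticTruth, seed: int | None = None, mask_quantile: float = 0.01
) -> ContactMatrix:
    """Poisson contact counts: cis lambda ~ depth * affinity * d^-alpha,
    trans lambda ~ depth * affinity; symmetric, seeded."""
    config = truth.config
    rng = _rng(config.seed + 1 if seed is None else seed)
    counts = _poisson_symmetric(_lambda_matrix(truth), rng)
    layout = truth.labels.layout
    return ContactMatrix(layout, counts, _mask_low_coverage(counts, mask_quantile))


def simulate_annotations(
    truth: SyntheticTruth, seed: int | None = None
) -> SyntheticTruth:
    """Plant repeat intervals per family and a LAD track.

    Per family, per-bin element counts are Poisson(base * fold) in the
    family's target compartment and Poisson(base) elsewhere; intervals
    are placed uniformly within their bin. LAD intervals cover B-labeled
    bins with the configured sensitivity and A-labeled bins at one minus
    the specificity.
    """
    config = truth.config
    rng = _rng(config.seed + 2 if seed is None else seed)
    layout = truth.labels.layout
    codes = truth.labels.codes
    starts = layout.bin_starts()
    lengths = layout.bin_lengths()
    chrom_ids = layout.bin_chrom_ids()

    for family, target in config.repeat_families.items():
        target_code = LABELS.index(target)
        lam = np.where(
            codes == target_code,
            config.repeat_base_rate * config.repeat_fold,
            config.repeat_base_rate,
        )
        counts = rng.poisson(lam)
        intervals = []
        for b in np.flatnonzero(counts):
            chrom = layout.chrom_names[chrom_ids[b]]
            for _ in range(counts[b]):
                span = min(config.repeat_length, int(lengths[b]))
                lo = int(starts[b] + rng.integers(0, max(1, lengths[b] - span + 1)))
                intervals.append(GenomicInterval(chrom, lo, lo + span, name=family))
        truth.repeats[family] = intervals
        truth.repeat_counts[family] = BinVector(layout, counts)

    is_b = np.isin(codes, [LABELS.index("B1"), LABELS.index("B2")])
    covered = np.where(
        is_b,
        rng.random(layout.total_bins) < config.lad_sensitivity,
        rng.random(layout.total_bins) < 1.0 - config.lad_specificity,
    )
    lads = [
        GenomicInterval(
            layout.chrom_names[chrom_ids[b]],
            int(starts[b]),
            int(starts[b] + lengths[b]),
            name="LAD",
        )
        for b in np.flatnonzero(covered)
    ]
    truth.lads = lads
    return truth


def simulate_strain_pair(
    truth: SyntheticTruth,
    seed: int | None = None,
    hot: BinVector | None = None,
    dosage: float | None = None,
    mask_quantile: float = 0.01,
) -> tuple[ContactMatrix, ContactMatrix, BinVector]:
    """Two strains differing only by a dosage factor at hotspot pairs.

    Strain 1 uses the base contact intensities; strain 2 multiplies the
    intensity of hotspot-by-hotspot bin pairs by the dosage factor
    (non-hotspot pairs are identically distributed between strains).
    Hotspots default to the planted ERV2-like family at the configured
    percentile.
    """
    config = truth.config
    rng = _rng(config.seed + 3 if seed is None else seed)
    if hot is None:
        if "ERV2" not in truth.repeat_counts:
            raise ValueError("repeat annotations missing; run simulate_annotations")
        hot = hotspot_bins(
            truth.repeat_counts["ERV2"], HotspotParams(q=config.hotspot_percentile)
        )
    dosage = config.strain_dosage if dosage is None else dosage
    lam = _lambda_matrix(truth)
    hot_vec = hot.values.astype(bool)
    lam2 = lam * np.where(np.outer(hot_vec, hot_vec), dosage, 1.0)
    layout = truth.labels.layout
    c1 = _poisson_symmetric(lam, rng)
    c2 = _poisson_symmetric(lam2, rng)
    m1 = ContactMatrix(layout, c1, _mask_low_coverage(c1, mask_quantile))
    m2 = ContactMatrix(layout, c2, _mask_low_coverage(c2, mask_quantile))
    return m1, m2, hot


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, length)])


def _mutate(seq: str, rate: float, rng: np.random.Generator) -> str:
    if rate <= 0:
        return seq
    arr = np.array(list(seq))
    hits = np.flatnonzero(rng.random(arr.size) < rate)
    for h in hits:
        others = [b for b in "ACGT" if b != arr[h]]
        arr[h] = others[rng.integers(0, 3)]
    return "".join(arr)


def simulate_reads(
    truth: SyntheticTruth,
    sample_id: str = "S1",
    seed: int | None = None,
    n_reads: int | None = None,
    error_rate: float | None = None,
) -> ReadSimulation:
    """Simulate one capture-sequencing sample with planted insertion truth.

    Reads are left flank + consensus fragment + right flank with per-base
    substitution errors. Categories: reads at annotated element sites
    (target family or another family, both in the known-sites BED), de
    novo insertions at novel coordinates (biased toward B2 bins), reads
    whose insert is present in the unmasked reference (arbitrated to not
    de novo), and solo-LTR-like decoys carrying no internal-consensus
    homology. The masked-reference windows around each planted site are
    returned for bit-score arbitration.
    """
    from .insertions import FlankAlignment

    config = truth.config
    rng = _rng(config.seed + 4 if seed is None else seed)
    layout = truth.labels.layout
    codes = truth.labels.codes
    starts = layout.bin_starts()
    chrom_ids = layout.bin_chrom_ids()
    n_reads = config.n_reads if n_reads is None else n_reads
    error_rate = config.read_error_rate if error_rate is None else error_rate

    consensus = _random_seq(rng, config.consensus_length)
    ltr_like = _random_seq(rng, 350)
    cutoff = int(np.floor(0.9 * config.consensus_length)) + 1

    # known annotated sites: ~2/3 target family, rest another IAP family
    known_sites: list[GenomicInterval] = []
    used_bins: set[int] = set()
    for k in range(config.n_known_sites):
        b = int(rng.integers(0, layout.total_bins))
        pos = int(starts[b] + 2000 + rng.integers(0, config.bin_size - 11000))
        family = "IAPEzi" if k % 3 != 2 else "IAP_other"
        chrom = layout.chrom_names[chrom_ids[b]]
        known_sites.append(GenomicInterval(chrom, pos, pos + 7000, name=family))
        used_bins.add(b)
        used_bins.add(layout.bin_index(chrom, pos + 7000))

    # novel-coordinate sampler with B2 bias, avoiding known-site bins
    b2 = LABELS.index("B2")
    weights = np.where(codes == b2, config.de_novo_b2_bias, 1.0)
    weights[list(used_bins)] = 0.0
    weights = weights / weights.sum()

    def novel_coord() -> tuple[str, int]:
        b = int(rng.choice(layout.total_bins, p=weights))
        pos = int(starts[b] + rng.integers(fl, config.bin_size - fl))
        return layout.chrom_names[chrom_ids[b]], pos

    categories = list(config.read_mix)
    probs = np.array([config.read_mix[c] for c in categories])
    probs = probs / probs.sum()

    reads: dict[str, str] = {}
    flank_alignments: dict[str, list] = {}
    ref_windows: dict[tuple[str, int], str] = {}
    truth_rows = []
    fl = config.flank_length
    for r in range(n_reads):
        rid = f"{sample_id}_read{r:04d}"
        category = categories[int(rng.choice(len(categories), p=probs))]
        left = _random_seq(rng, fl)
        right = _random_seq(rng, fl)

        if category == "decoy":
            seq = left + ltr_like + right
            reads[rid] = _mutate(seq, error_rate, rng)
            truth_rows.append(
                {
                    "read_id": rid, "sample": sample_id, "chrom": None,
                    "pos": None, "category": category, "full_length": False,
                    "fragment_length": 0,
                }
            )
            continue

        if category in ("annotated_element", "annotated_other"):
            family = "IAPEzi" if category == "annotated_element" else "IAP_other"
            options = [s for s in known_sites if s.name == family]
            site = options[int(rng.integers(0, len(options)))]
            chrom, pos = site.chrom, int(site.start + 100)
        else:
            chrom, pos = novel_coord()

        if category == "de_novo" and rng.random() < config.de_novo_full_frac:
            frag_len = config.consensus_length
        elif category == "de_novo" and rng.random() < 0.15:
            # exercise the cutoff boundary explicitly
            frag_len = cutoff - 1 + int(rng.integers(0, 2))
        else:
            lo = min(config.min_fragment, config.consensus_length)
            frag_len = int(rng.integers(lo, config.consensus_length + 1))
        fragment = consensus[:frag_len]
        if frag_len < config.consensus_length:
            # force the junction to mismatch the consensus continuation so
            # the aligned consensus span equals the planted fragment length
            right = list(right)
            for i in range(min(6, config.consensus_length - frag_len, len(right))):
                choices = [b for b in "ACGT" if b != consensus[frag_len + i]]
                right[i] = choices[int(rng.integers(0, 3))]
            right = "".join(right)

        if category == "ref_present":
            # insert also present (unmasked) in the reference window
            ref_windows[(chrom, pos)] = left + fragment + right
        else:
            ref_windows[(chrom, pos)] = left + right

        seq = left + fragment + right
        reads[rid] = _mutate(seq, error_rate, rng)
        mapq = 60
        flank_alignments[rid] = [
            FlankAlignment(rid, "left", chrom, pos - fl, pos, mapq),
            FlankAlignment(rid, "right", chrom, pos, pos + fl, mapq),
        ]
        truth_rows.append(
            {
                "read_id": rid, "sample": sample_id, "chrom": chrom, "pos": pos,
                "category": category,
                "full_length": frag_len >= cutoff and category == "de_novo",
                "fragment_length": frag_len,
            }
        )

    return ReadSimulation(
        sample_id,
        reads,
        consensus,
        known_sites,
        flank_alignments,
        ref_windows,
        pd.DataFrame(truth_rows),
    )


def window_lookup(ref_windows: Mapping[tuple[str, int], str], tolerance: int = 200):
    """Closure mapping an anchored coordinate to the nearest simulated
    masked-reference window within ``tolerance`` bp."""

    def lookup(chrom: str, pos: int) -> str | None:
        best, best_d = None, tolerance + 1
        for (c, p), seq in ref_windows.items():
            if c == chrom and abs(p - pos) < best_d:
                best, best_d = seq, abs(p - pos)
        return best

    return lookup


def simulate_differential_contacts(
    labels_1mb: LabelTrack,
    n_up: int = 100,
    n_down: int = 150,
    seed: int = 0,
    down_pair: tuple[str, str] = ("B2", "B2"),
    up_pair: tuple[str, str] = ("B1", "B2"),
    bias: float = 4.0,
) -> pd.DataFrame:
    """A demo differential-contact table with planted label-pair biases.

    Stands in for the upstream negative-binomial engine's output: trans
    bin pairs with decreased contacts enriched for one label pair and
    increased contacts for another.
    """
    rng = _rng(seed)
    layout = labels_1mb.layout
    lab = labels_1mb.labels
    chrom_ids = layout.bin_chrom_ids()
    starts = layout.bin_starts()
    rows = []
    for direction, n, pair in (("up", n_up, up_pair), ("down", n_down, down_pair)):
        want = tuple(sorted(pair))
        for _ in range(n):
            while True:
                i, j = rng.integers(0, layout.total_bins, 2)
                if i == j or chrom_ids[i] == chrom_ids[j]:
                    continue
                got = tuple(sorted((lab[i], lab[j])))
                if "NA" in got:
                    continue
                if got == want or rng.random() < 1.0 / bias:
                    break
            rows.append(
                {
                    "chrom1": layout.chrom_names[chrom_ids[i]],
                    "start1": int(starts[i]),
                    "chrom2": layout.chrom_names[chrom_ids[j]],
                    "start2": int(starts[j]),
                    "log2fc": float(rng.normal(1.0 if direction == "up" else -1.0, 0.3)),
                    "padj": float(rng.uniform(0.0, 0.05)),
                    "direction": direction,
                }
            )
    return pd.DataFrame(rows)


def simulate_truth(
    config: SimulationConfig | None = None, seed: int | None = None
) -> SyntheticTruth:
    """Convenience: labels + annotations in one call."""
    config = config or SimulationConfig()
    if seed is not None:
        config = SimulationConfig(**{**asdict(config), "seed": seed})
    truth = simulate_genome_labels(config)
    return simulate_annotations(truth)
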