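import numpy as np
import pytest

from megadomain.align import Scoring, local_align, revcomp
from megadomain.genome import GenomeLayout, GenomicInterval
from megadomain.insertions import (
    ConsensusModel,
    FlankAlignment,
    anchor_to_genome,
    classify_insertion,
    classify_reads,
    compartment_enrichment,
    flag_full_length,
    match_consensus,
)
from megadomain.simulate import simulate_reads, simulate_truth, window_lookup
from megadomain.subcompartments import LabelTrack


def dp_oracle(q, t, match=1, mismatch=-2, go=5, ge=2):
    """Plain full-matrix affine local alignment (Gotoh), best score only."""
    n, m = len(q), len(t)
    NEG = -(10**9)
    H = [[0] * (m + 1) for _ in range(n + 1)]
    E = [[NEG] * (m + 1) for _ in range(n + 1)]
    F = [[NEG] * (m + 1) for _ in range(n + 1)]
    best = 0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            E[i][j] = max(H[i][j - 1] - go, E[i][j - 1] - ge)
            F[i][j] = max(H[i - 1][j] - go, F[i - 1][j] - ge)
            s = match if q[i - 1] == t[j - 1] else mismatch
            H[i][j] = max(0, H[i - 1][j - 1] + s, E[i][j], F[i][j])
            best = max(best, H[i][j])
    return best


class TestLocalAligner:
    def test_matches_dp_oracle_on_short_pairs(self, rng):
        bases = np.array(list("ACGT"))
        for _ in range(500):
            q = "".join(bases[rng.integers(0, 4, int(rng.integers(1, 13)))])
            t = "".join(bases[rng.integers(0, 4, int(rng.integers(1, 13)))])
            res = local_align(q, t)
            got = res.score if res else 0
            assert got == dp_oracle(q, t), (q, t)

    def test_toy_exact_pair(self):
        res = local_align("ACGTACGT", "ACGTACGT")
        assert res.score == 8
        assert (res.t_start, res.t_end) == (0, 8)
        assert res.matched_length == 8

    def test_reverse_complement_strand(self):
        target = "ACGTTGCAACGGATCCTAGG"
        res = local_align(revcomp(target), target, both_strands=True)
        assert res.strand == "-"
        assert (res.t_start, res.t_end) == (0, len(target))

    def test_non_iupac_rejected(self):
        with pytest.raises(ValueError, match="non-IUPAC"):
            local_align("ACGT!", "ACGT")


class TestConsensusModel:
    def test_printed_cutoff(self):
        model = ConsensusModel("IAPEzi", "A" * 6481)
        assert model.full_length_cutoff == 5833

    def test_cutoff_is_smallest_integer_exceeding_fraction(self):
        assert ConsensusModel("x", "A" * 10, 0.5).full_length_cutoff == 6
        assert ConsensusModel("x", "A" * 100, 0.95).full_length_cutoff == 96

    @pytest.mark.parametrize(
        "matched,expected", [(5832, False), (5833, True), (6481, True)]
    )
    def test_full_length_flag_flips_at_cutoff(self, matched, expected):
        from megadomain.insertions import ConsensusHit

        model = ConsensusModel("IAPEzi", "A" * 6481)
        hit = ConsensusHit("r", (0, matched), matched, matched, 99.0, "+", (0, matched))
        assert flag_full_length(hit, model) is expected


class TestMatchConsensus:
    def test_exact_consensus_read_is_full_length(self, rng):
        bases = np.array(list("ACGT"))
        seq = "".join(bases[rng.integers(0, 4, 800)])
        model = ConsensusModel("x", seq)
        hit = match_consensus(seq, model, read_id="r1")
        assert hit.span == (0, 800)
        assert hit.matched_length == 800
        assert flag_full_length(hit, model)

    def test_reverse_complement_same_span(self, rng):
        bases = np.array(list("ACGT"))
        seq = "".join(bases[rng.integers(0, 4, 600)])
        model = ConsensusModel("x", seq)
        hit = match_consensus(revcomp(seq), model)
        assert hit.span == (0, 600)
        assert hit.strand == "-"

    def test_unrelated_read_yields_none(self, rng):
        bases = np.array(list("ACGT"))
        cons = "".join(bases[rng.integers(0, 4, 6481)])
        decoy = "".join(bases[rng.integers(0, 4, 2000)])
        model = ConsensusModel("x", cons)
        assert match_consensus(decoy, model) is None

    def test_bit_score_scale_invariance(self):
        """Scaling lambda identically for both competitors never flips
        the de-novo comparison."""
        for lam in (0.5, 1.28, 3.0):
            s = Scoring(lam=lam)
            raw_cons, raw_ref = 4000, 2500
            assert s.bits(raw_cons) > s.bits(raw_ref)


class TestAnchorToGenome:
    def test_mapq_59_rejected(self):
        flanks = [FlankAlignment("r", "left", "chr1", 1_000_000, 1_005_000, 59)]
        assert anchor_to_genome(flanks) is None

    def test_left_flank_junction_rule(self):
        flanks = [FlankAlignment("r", "left", "chr1", 1_000_000, 1_005_000, 60)]
        assert anchor_to_genome(flanks) == ("chr1", 1_005_000)

    def test_right_flank_junction_rule(self):
        flanks = [FlankAlignment("r", "right", "chr2", 2_000_000, 2_001_000, 60)]
        assert anchor_to_genome(flanks) == ("chr2", 2_000_000)

    def test_discordant_flanks_unresolved(self):
        flanks = [
            FlankAlignment("r", "left", "chr1", 990_000, 1_000_000, 60),
            FlankAlignment("r", "right", "chr1", 1_010_000, 1_020_000, 60),
        ]
        assert anchor_to_genome(flanks) == "unresolved"

    def test_concordant_flanks_average(self):
        flanks = [
            FlankAlignment("r", "left", "chr1", 990_000, 1_000_000, 60),
            FlankAlignment("r", "right", "chr1", 1_000_010, 1_002_000, 60),
        ]
        assert anchor_to_genome(flanks) == ("chr1", 1_000_005)

    def test_mapq_ge_mode(self):
        flanks = [FlankAlignment("r", "left", "chr1", 0, 1000, 60)]
        higher = [FlankAlignment("r", "left", "chr1", 0, 1000, 60)]
        assert anchor_to_genome(higher, mapq_min=30, mapq_exact=False) == ("chr1", 1000)
        assert anchor_to_genome(flanks, mapq_min=30, mapq_exact=True) is None


class TestClassifyInsertion:
    sites = [
        GenomicInterval("chr1", 1_000_000, 1_007_000, name="IAPEzi"),
        GenomicInterval("chr1", 5_000_000, 5_007_000, name="IAP_other"),
    ]

    def test_known_site_precedence_over_scores(self):
        call = classify_insertion(("chr1", 1_000_500), self.sites, "IAPEzi", 10, 999)
        assert call == "annotated_element"

    def test_other_family_site(self):
        call = classify_insertion(("chr1", 5_000_500), self.sites, "IAPEzi", 999, 10)
        assert call == "annotated_other"

    def test_novel_coordinate_bit_rule(self):
        assert (
            classify_insertion(("chr2", 42), self.sites, "IAPEzi", 120, 80)
            == "de_novo"
        )
        assert (
            classify_insertion(("chr2", 42), self.sites, "IAPEzi", 80, 120)
            == "unresolved"
        )

    def test_tie_is_unresolved(self):
        assert (
            classify_insertion(("chr2", 42), self.sites, "IAPEzi", 100, 100)
            == "unresolved"
        )


@pytest.fixture(scope="module")
def noiseless():
    truth = simulate_truth(seed=11)
    sim = simulate_reads(truth, seed=13, error_rate=0.0)
    model = ConsensusModel("IAPEzi", sim.consensus)
    calls = classify_reads(
        sim.reads,
        model,
        sim.flank_alignments,
        sim.known_sites,
        window_lookup(sim.ref_windows),
        sample_id="S1",
    )
    return truth, sim, calls


class TestEndToEndClassification:

    def test_perfect_precision_and_recall_on_noiseless_reads(self, noiseless):
        _, sim, calls = noiseless
        truth = sim.truth.set_index("read_id")
        predicted = set(calls[calls["call_class"] == "de_novo"]["read_id"])
        planted = set(truth[truth["category"] == "de_novo"].index)
        assert predicted == planted
        assert len(planted) > 20

    def test_planted_categories_recovered(self, noiseless):
        _, sim, calls = noiseless
        merged = calls.set_index("read_id").join(
            sim.truth.set_index("read_id"), rsuffix="_true"
        )
        for category, expected in [
            ("annotated_element", "annotated_element"),
            ("annotated_other", "annotated_other"),
            ("ref_present", "unresolved"),
        ]:
            sub = merged[merged["category"] == category]
            assert (sub["call_class"] == expected).all()

    def test_decoys_produce_no_calls(self, noiseless):
        _, sim, calls = noiseless
        decoys = set(sim.truth[sim.truth["category"] == "decoy"]["read_id"])
        assert decoys
        assert decoys.isdisjoint(set(calls["read_id"]))

    def test_full_length_flags_match_planted_truth(self, noiseless):
        _, sim, calls = noiseless
        merged = calls.set_index("read_id").join(
            sim.truth.set_index("read_id"), rsuffix="_true"
        )
        dn = merged[merged["category"] == "de_novo"]
        assert (dn["full_length"] == dn["full_length_true"]).all()


class TestCompartmentEnrichment:
    def _calls(self, chroms, positions, classes=None, full=None):
        import pandas as pd

        n = len(positions)
        return pd.DataFrame(
            {
                "read_id": [f"r{i}" for i in range(n)],
                "sample_id": "S",
                "chrom": chroms,
                "pos": positions,
                "call_class": classes or ["de_novo"] * n,
                "full_length": full or [False] * n,
            }
        )

    def test_worked_oe_arithmetic(self):
        layout = GenomeLayout(("chr1",), (10 * 250_000,), 250_000)
        labels = LabelTrack(layout, [3] * 1 + [0] * 9, ("A1", "A2", "B1", "B2"))
        # 20 calls, 6 in the 10%-of-genome label: O/E = 3.0
        positions = [100] * 6 + [300_000 + 1000 * i for i in range(14)]
        calls = self._calls(["chr1"] * 20, positions)
        table = compartment_enrichment({"S": calls}, labels)
        row = table[(table["label"] == "B2")].iloc[0]
        assert row["oe"] == pytest.approx(3.0)

    def test_proportional_calls_give_unit_oe(self):
        layout = GenomeLayout(("chr1",), (10 * 250_000,), 250_000)
        labels = LabelTrack(layout, [3] * 5 + [0] * 5, ("A1", "A2", "B1", "B2"))
        positions = [i * 250_000 + 5 for i in range(10)]
        calls = self._calls(["chr1"] * 10, positions)
        table = compartment_enrichment({"S": calls}, labels)
        for label in ("A1", "B2"):
            assert table[table["label"] == label]["oe"].iloc[0] == pytest.approx(1.0)

    def test_planted_b2_bias_recovered_across_samples(self):
        """Synthetic samples with a 4-fold B2 placement bias land near
        O/E 4 in B2 on average."""
        truth = simulate_truth(seed=11)
        oes = []
        for s in range(5):
            sim = simulate_reads(
                truth, sample_id=f"S{s}", seed=100 + s, error_rate=0.0, n_reads=120
            )
            tr = sim.truth
            dn = tr[tr["category"] == "de_novo"].copy()
            dn["call_class"] = "de_novo"
            dn["read_id"] = dn.index
            table = compartment_enrichment({f"S{s}": dn}, truth.labels)
            oes.append(table[table["label"] == "B2"]["oe"].iloc[0])
        assert 3.0 <= np.mean(oes) <= 5.0
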