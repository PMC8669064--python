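import itertools

import numpy as np
import pandas as pd
import pytest

from megadomain.comparison import (
    ReducedMatrix,
    contacts_per_window,
    hotspot_submatrix,
    paired_matrix_test,
    residual_summary,
    rollup_labels,
)
from megadomain.genome import BinVector, GenomeLayout
from megadomain.matrix import OEMatrix
from megadomain.subcompartments import NA, LabelTrack


def _layout(n_bins, bin_size=250_000, n_chrom=1):
    per = n_bins // n_chrom
    return GenomeLayout(
        tuple(f"chr{i+1}" for i in range(n_chrom)),
        (per * bin_size,) * n_chrom,
        bin_size,
    )


def _oe(values, layout):
    values = np.asarray(values, dtype=float)
    return OEMatrix(layout, values, np.ones(values.shape[0], dtype=bool), "both")


def signed_rank_oracle(diffs):
    """Two-sided exact signed-rank p by enumerating all sign assignments."""
    d = np.asarray([x for x in diffs if x != 0], dtype=float)
    n = d.size
    ranks = np.argsort(np.argsort(np.abs(d))) + 1.0
    w_obs = ranks[d > 0].sum()
    mean_w = n * (n + 1) / 4
    count = 0
    for signs in itertools.product([0, 1], repeat=n):
        w = sum(r for r, s in zip(ranks, signs) if s)
        if abs(w - mean_w) >= abs(w_obs - mean_w) - 1e-12:
            count += 1
    return count / 2 ** n


class TestHotspotSubmatrix:
    def _setup(self, rng):
        layout = _layout(10)
        values = rng.uniform(0.5, 2.0, (10, 10))
        values = (values + values.T) / 2
        hot = BinVector(layout, np.isin(np.arange(10), [1, 4, 7]))
        return _oe(values, layout), hot

    def test_shape_and_indexing(self, rng):
        oe, hot = self._setup(rng)
        red = hotspot_submatrix(oe, hot)
        assert red.values.shape == (3, 3)
        for a, ga in enumerate([1, 4, 7]):
            for b, gb in enumerate([1, 4, 7]):
                assert red.values[a, b] == oe.values[ga, gb]

    def test_two_identical_samples_double(self, rng):
        oe, hot = self._setup(rng)
        red = hotspot_submatrix([oe, oe], hot)
        single = hotspot_submatrix(oe, hot)
        np.testing.assert_allclose(red.values, 2 * single.values)
        assert red.summed_replicates

    def test_zero_hotspots_rejected(self, rng):
        oe, _ = self._setup(rng)
        empty = BinVector(oe.layout, np.zeros(10, dtype=bool))
        with pytest.raises(ValueError, match="zero hotspot"):
            hotspot_submatrix(oe, empty)


class TestPairedMatrixTest:
    def _reduced(self, values, layout=None):
        values = np.asarray(values, dtype=float)
        layout = layout or _layout(values.shape[0])
        return ReducedMatrix(values, np.arange(values.shape[0]), layout)

    def test_identical_matrices_degenerate(self, rng):
        v = rng.uniform(1, 2, (6, 6))
        a = self._reduced((v + v.T) / 2)
        with pytest.warns(UserWarning, match="zero"):
            res = paired_matrix_test(a, a)
        assert res["p_value"] == 1.0

    def test_five_all_positive_pairs(self):
        # 5 informative pairs all in one direction: exact p = 2/32
        base = np.zeros((4, 4))
        shift = np.zeros((4, 4))
        iu = np.triu_indices(4, k=1)
        base[iu] = [1, 2, 3, 4, 5, 0]
        shift[iu] = [1.5, 2.5, 3.7, 4.2, 5.9, 0]
        base, shift = base + base.T, shift + shift.T
        res = paired_matrix_test(self._reduced(shift), self._reduced(base))
        assert res["n_nonzero"] == 5
        assert res["p_value"] == pytest.approx(0.0625)

    @pytest.mark.parametrize("n_pairs", [4, 6, 8, 10])
    def test_matches_sign_enumeration_oracle(self, n_pairs, rng):
        # build symmetric matrices whose upper triangle realizes random diffs
        size = 5
        iu = np.triu_indices(size, k=1)
        for _ in range(20):
            diffs = rng.normal(0, 1, len(iu[0]))
            diffs[n_pairs:] = 0.0
            a = np.zeros((size, size))
            b = np.zeros((size, size))
            vals = rng.uniform(1, 2, len(iu[0]))
            a[iu], b[iu] = vals + diffs, vals
            a, b = a + a.T, b + b.T
            if (diffs[:n_pairs] == 0).any():
                continue
            res = paired_matrix_test(self._reduced(a), self._reduced(b))
            assert res["p_value"] == pytest.approx(
                signed_rank_oracle(diffs), rel=1e-9
            )

    def test_trans_only_restriction(self, rng):
        layout = _layout(6, n_chrom=2)  # bins 0-2 chr1, 3-5 chr2
        v = rng.uniform(1, 2, (6, 6))
        v = (v + v.T) / 2
        a = ReducedMatrix(v, np.arange(6), layout)
        b = ReducedMatrix(v + np.eye(6) * 0, np.arange(6), layout)
        shifted = v.copy()
        shifted[:3, 3:] += 0.5
        shifted[3:, :3] += 0.5
        res = paired_matrix_test(
            ReducedMatrix(shifted, np.arange(6), layout), a, trans_only=True
        )
        assert res["n_pairs"] == 9  # 3x3 inter-chromosomal pairs

    def test_mismatched_bins_rejected(self, rng):
        v = np.eye(3)
        a = ReducedMatrix(v, np.array([0, 1, 2]), _layout(5))
        b = ReducedMatrix(v, np.array([0, 1, 3]), _layout(5))
        with pytest.raises(ValueError, match="different bin sets"):
            paired_matrix_test(a, b)


class TestRollupLabels:
    def _track(self, codes, names=("A1", "A2", "B1", "B2")):
        return LabelTrack(_layout(len(codes)), np.asarray(codes), names)

    def test_majority_wins(self):
        track = self._track([0, 0, 0, 3])
        up = rollup_labels(track, 1_000_000)
        assert up.labels[0] == "A1"

    def test_tie_goes_to_smaller_genome_wide_label(self):
        # B2 (code 3) genome-wide smaller than A1 -> tie resolves to B2
        track = self._track([0, 0, 3, 3] + [0] * 4)
        up = rollup_labels(track, 1_000_000)
        assert up.labels[0] == "B2"

    def test_all_na_window_stays_na(self):
        track = self._track([NA, NA, NA, NA, 0, 0, 0, 0])
        up = rollup_labels(track, 1_000_000)
        assert up.labels[0] == "NA" and up.labels[1] == "A1"

    def test_matches_brute_force_fractions(self, rng):
        codes = rng.integers(0, 4, 40)
        track = self._track(codes)
        up = rollup_labels(track, 1_000_000)
        sizes = track.sizes_bp()
        for w in range(10):
            window = codes[4 * w : 4 * w + 4]
            counts = {c: np.sum(window == c) for c in set(window)}
            best = min(counts.items(), key=lambda kv: (-kv[1], sizes[track.names[kv[0]]]))
            assert up.codes[w] == best[0]

    def test_non_multiple_target_rejected(self):
        with pytest.raises(ValueError, match="multiple"):
            rollup_labels(self._track([0, 0]), 300_000)


def _diffs_from_pairs(labels_1mb, pair_counts, direction):
    """Build a differential-contact frame realizing the given label-pair
    counts using real bin coordinates."""
    layout = labels_1mb.layout
    lab = labels_1mb.labels
    chrom_ids = layout.bin_chrom_ids()
    starts = layout.bin_starts()
    by_label = {
        name: np.flatnonzero(lab == name) for name in labels_1mb.names
    }
    rows = []
    for (x, y), count in pair_counts.items():
        made = 0
        for i in by_label[x]:
            for j in by_label[y]:
                if i == j or chrom_ids[i] == chrom_ids[j]:
                    continue
                rows.append(
                    {
                        "chrom1": layout.chrom_names[chrom_ids[i]],
                        "start1": int(starts[i]),
                        "chrom2": layout.chrom_names[chrom_ids[j]],
                        "start2": int(starts[j]),
                        "log2fc": 1.0,
                        "padj": 0.01,
                        "direction": direction,
                    }
                )
                made += 1
                if made == count:
                    break
            if made == count:
                break
        assert made == count
    return pd.DataFrame(rows)


class TestResidualSummary:
    def _labels_half(self):
        # two chromosomes, labels A1 and B2 each covering half of each
        layout = GenomeLayout(("chr1", "chr2"), (4_000_000, 4_000_000), 1_000_000)
        codes = np.array([0, 0, 3, 3, 0, 0, 3, 3])
        return LabelTrack(layout, codes, ("A1", "A2", "B1", "B2"))

    def test_hand_computed_eight_contact_example(self):
        """p = (0.5, 0.5); 8 up contacts {AA:4, AB:2, BB:2} gives
        r(AA) = 2/sqrt(2), r(AB) = -1, r(BB) = 0."""
        labels = self._labels_half()
        diffs = _diffs_from_pairs(
            labels, {("A1", "A1"): 4, ("A1", "B2"): 2, ("B2", "B2"): 2}, "up"
        )
        table = residual_summary(diffs, labels).set_index("pair")
        assert table.loc["A1-A1", "r_up"] == pytest.approx(2 / np.sqrt(2))
        assert table.loc["A1-B2", "r_up"] == pytest.approx(-1.0)
        assert table.loc["B2-B2", "r_up"] == pytest.approx(0.0)

    def test_expected_counts_sum_to_direction_total(self):
        labels = self._labels_half()
        diffs = _diffs_from_pairs(
            labels, {("A1", "A1"): 3, ("A1", "B2"): 5}, "down"
        )
        table = residual_summary(diffs, labels)
        assert table["exp_down"].sum() == pytest.approx(8.0)
        assert table["obs_down"].sum() == 8

    def test_zero_residuals_when_observed_equals_expected(self):
        labels = self._labels_half()
        # expected split for 8 contacts: AA 2, AB 4, BB 2
        diffs = _diffs_from_pairs(
            labels, {("A1", "A1"): 2, ("A1", "B2"): 4, ("B2", "B2"): 2}, "up"
        )
        table = residual_summary(diffs, labels).set_index("pair")
        for pair in ("A1-A1", "A1-B2", "B2-B2"):
            assert table.loc[pair, "r_up"] == pytest.approx(0.0)

    def test_direction_swap_negates_r_diff(self):
        labels = self._labels_half()
        up = _diffs_from_pairs(labels, {("A1", "A1"): 4, ("A1", "B2"): 2}, "up")
        down = _diffs_from_pairs(labels, {("B2", "B2"): 3, ("A1", "B2"): 3}, "down")
        forward = residual_summary(pd.concat([up, down]), labels)
        swapped_up = up.assign(direction="down")
        swapped_down = down.assign(direction="up")
        backward = residual_summary(pd.concat([swapped_up, swapped_down]), labels)
        np.testing.assert_allclose(
            forward["r_diff"].to_numpy(), -backward["r_diff"].to_numpy()
        )


class TestContactsPerWindow:
    def _labels(self):
        # A2 spans 20 Mb across two chromosomes; B2 spans 20 Mb
        layout = GenomeLayout(("chr1", "chr2"), (20_000_000,) * 2, 1_000_000)
        codes = np.array(([1] * 10 + [3] * 10) * 2)
        return LabelTrack(layout, codes, ("A1", "A2", "B1", "B2"))

    def test_worked_density(self):
        labels = self._labels()
        diffs = _diffs_from_pairs(labels, {("A2", "B2"): 5}, "down")
        density = contacts_per_window(diffs, labels, ("A2", "B2"), 10_000_000)
        assert density == pytest.approx(5 / (20 / 10))

    def test_zero_matching_contacts(self):
        labels = self._labels()
        diffs = _diffs_from_pairs(labels, {("A2", "A2"): 2}, "down")
        assert contacts_per_window(diffs, labels, ("A2", "B2")) == 0.0

    def test_absent_label_rejected(self):
        labels = self._labels()
        diffs = _diffs_from_pairs(labels, {("A2", "B2"): 1}, "up")
        with pytest.raises(ValueError, match="zero genomic extent"):
            contacts_per_window(diffs, labels, ("A1", "B2"))
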