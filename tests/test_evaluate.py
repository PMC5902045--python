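from collections import Counter

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from motifstrat import (
    ChIPPeak,
    PBMProbe,
    auroc,
    chip_prepare,
    compare_groups,
    evaluate_pwm,
    pbm_bins,
    shuffle_controls,
)
from conftest import random_pwm
from _oracles import oracle_auroc


class TestAuroc:
    @pytest.mark.parametrize(
        "pos, neg, expected",
        [
            ([2, 3], [0, 1], 1.0),          # perfect separation
            ([1], [1], 0.5),                # pure tie
            ([1, 3], [2, 4], 0.25),         # hand-enumerated 4 pairs
            ([0, 1], [2, 3], 0.0),
        ],
    )
    def test_examples(self, pos, neg, expected):
        assert auroc(pos, neg) == pytest.approx(expected)

    def test_matches_pairwise_oracle_with_ties(self):
        rng = np.random.default_rng(20)
        for _ in range(100):
            pos = rng.integers(0, 6, size=rng.integers(1, 15)).astype(float)
            neg = rng.integers(0, 6, size=rng.integers(1, 15)).astype(float)
            assert auroc(pos, neg) == pytest.approx(
                oracle_auroc(list(pos), list(neg)), abs=1e-12
            )

    def test_role_swap_symmetry(self):
        rng = np.random.default_rng(21)
        pos, neg = rng.normal(size=9), rng.normal(size=7)
        assert auroc(pos, neg) == pytest.approx(1.0 - auroc(neg, pos))

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(22)
        pos, neg = rng.normal(size=8), rng.normal(size=8)
        assert auroc(pos, neg) == pytest.approx(
            auroc(np.exp(pos), np.exp(neg))
        )

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            auroc([], [1.0])

    @settings(derandomize=True, max_examples=80, deadline=None)
    @given(
        pos=st.lists(st.integers(-5, 5), min_size=1, max_size=12),
        neg=st.lists(st.integers(-5, 5), min_size=1, max_size=12),
    )
    def test_pairwise_oracle_property(self, pos, neg):
        assert auroc(pos, neg) == pytest.approx(
            oracle_auroc(pos, neg), abs=1e-12
        )


class TestShuffleControls:
    def test_composition_and_shape_preserved(self):
        seqs = ["ACGTACGTAA", "GGGCCC", "ATATATATATAT"]
        sets = shuffle_controls(seqs, n_sets=10, seed=3)
        assert len(sets) == 10
        for cset in sets:
            assert len(cset) == len(seqs)
            for orig, shuf in zip(seqs, cset):
                assert len(shuf) == len(orig)
                assert Counter(shuf) == Counter(orig)

    def test_length_one_is_fixed_point(self):
        assert shuffle_controls(["A"], n_sets=2, seed=0) == [["A"], ["A"]]

    def test_deterministic(self):
        seqs = ["ACGTACGT", "TTTTAAAA"]
        assert shuffle_controls(seqs, seed=9) == shuffle_controls(seqs, seed=9)


def _probes(n, seed=0):
    rng = np.random.default_rng(seed)
    return [
        PBMProbe(f"p{i}", "".join("ACGT"[j] for j in rng.integers(0, 4, 12)),
                 float(f))
        for i, f in enumerate(rng.permutation(np.arange(1, n + 1)))
    ]


class TestPbmBins:
    def test_top_bin_size_ceiling_rule(self):
        bins, _ = pbm_bins(_probes(1000))
        assert len(bins["top 0.25%"]) == 3

    def test_max_probe_in_top_bin(self):
        probes = _probes(1000)
        bins, _ = pbm_bins(probes)
        top_f = max(p.fluorescence for p in probes)
        assert top_f in [p.fluorescence for p in bins["top 0.25%"]]

    def test_bins_disjoint_and_ordered(self):
        bins, _ = pbm_bins(_probes(2000))
        labels = list(bins)
        seen = set()
        for label in labels:
            ids = {p.probe_id for p in bins[label]}
            assert not ids & seen
            seen |= ids
        for a, b in zip(labels, labels[1:]):
            assert min(p.fluorescence for p in bins[a]) >= max(
                p.fluorescence for p in bins[b]
            )

    def test_controls_matched_and_from_bottom_half(self):
        probes = _probes(1000)
        bins, controls = pbm_bins(probes, seed=4)
        median_f = float(np.median([p.fluorescence for p in probes]))
        bottom = {p.sequence for p in probes if p.fluorescence <= median_f}
        for label, members in bins.items():
            assert len(controls[label]) == 10
            for cset in controls[label]:
                assert len(cset) == len(members)
                assert all(s in bottom for s in cset)
                assert all(len(s) == len(members[0].sequence) for s in cset)

    def test_too_few_probes_rejected(self):
        with pytest.raises(ValueError):
            pbm_bins(_probes(100))


def _toy_genome(seed=30, length=30000):
    rng = np.random.default_rng(seed)
    return {"chr1": "".join("ACGT"[i] for i in rng.integers(0, 4, length))}


class TestChipPrepare:
    def test_central_trim(self):
        genome = _toy_genome()
        peaks = [ChIPPeak("chr1", 100, 300, 5.0, name="pk")]
        bins, _, _ = chip_prepare(peaks, genome, top_n=1, n_bins=1, seed=0)
        pk = bins[0]["peaks"][0]
        assert (pk.start, pk.end) == (150, 250)

    def test_exact_100bp_peak_unchanged(self):
        genome = _toy_genome()
        peaks = [ChIPPeak("chr1", 200, 300, 5.0)]
        bins, _, _ = chip_prepare(peaks, genome, top_n=1, n_bins=1, seed=0)
        pk = bins[0]["peaks"][0]
        assert (pk.start, pk.end) == (200, 300)

    def test_top_n_by_fold_enrichment(self):
        genome = _toy_genome()
        peaks = [ChIPPeak("chr1", 1000 * i, 1000 * i + 100, float(i))
                 for i in range(1, 9)]
        bins, _, _ = chip_prepare(peaks, genome, top_n=4, n_bins=2, seed=0)
        kept = [p.fold_enrichment for b in bins for p in b["peaks"]]
        assert sorted(kept) == [5.0, 6.0, 7.0, 8.0]
        # strongest bin first
        assert all(p.fold_enrichment >= 7 for p in bins[0]["peaks"])

    def test_controls_avoid_peaks_and_mask_exhaustively(self):
        genome = _toy_genome(length=50000)
        rng = np.random.default_rng(31)
        peaks = [
            ChIPPeak("chr1", int(s), int(s) + 100, float(f))
            for s, f in zip(rng.choice(490, 20, replace=False) * 100,
                            rng.uniform(2, 9, 20))
        ]
        mask = [("chr1", 10000, 12000), ("chr1", 30000, 31000)]
        bins, controls, coords = chip_prepare(peaks, genome, top_n=20,
                                              n_bins=2, mask=mask, seed=5)
        forbidden = [(p.start, p.end) for b in bins for p in b["peaks"]]
        forbidden += [(s, e) for _, s, e in mask]
        for label, coord_sets in coords.items():
            n_pos = len(next(b for b in bins if b["label"] == label)["peaks"])
            for cset, coord_set in zip(controls[label], coord_sets):
                assert len(cset) == n_pos
                assert all(len(s) == 100 for s in cset)
                for _, cs, ce in coord_set:
                    assert all(ce <= s or e <= cs for s, e in forbidden)

    def test_deterministic_given_seed(self):
        genome = _toy_genome(length=40000)
        peaks = [ChIPPeak("chr1", 1000 * i, 1000 * i + 150, float(i))
                 for i in range(1, 11)]
        a = chip_prepare(peaks, genome, top_n=10, n_bins=2, seed=5)
        b = chip_prepare(peaks, genome, top_n=10, n_bins=2, seed=5)
        assert a[1] == b[1] and a[2] == b[2]

    def test_unknown_chromosome_rejected(self):
        with pytest.raises(ValueError, match="absent"):
            chip_prepare([ChIPPeak("chrX", 0, 100, 1.0)], _toy_genome(),
                         top_n=1, n_bins=1)


class TestEvaluatePwm:
    def test_self_controls_give_half(self):
        rng = np.random.default_rng(32)
        pwm = random_pwm(rng, 5)
        seqs = ["".join("ACGT"[i] for i in rng.integers(0, 4, 20))
                for _ in range(15)]
        res = evaluate_pwm(pwm, seqs, [list(seqs)] * 3)
        assert res.aurocs == [0.5, 0.5, 0.5]
        assert res.median_auroc == 0.5

    def test_consensus_positives_beat_random_controls(self, truth_pwm):
        from motifstrat import consensus_sequence

        rng = np.random.default_rng(33)
        word = consensus_sequence(truth_pwm)
        pos, ctrl = [], []
        for _ in range(100):
            f = "".join("ACGT"[i] for i in rng.integers(0, 4, 30))
            off = int(rng.integers(0, 20))
            pos.append(f[:off] + word + f[off + 10:])
            ctrl.append("".join("ACGT"[i] for i in rng.integers(0, 4, 30)))
        res = evaluate_pwm(truth_pwm, pos, [ctrl])
        assert res.aurocs[0] >= 0.95

    def test_size_mismatch_rejected(self, soft_pwm):
        with pytest.raises(ValueError, match="control set size"):
            evaluate_pwm(soft_pwm, ["ACGT", "GGTT"], [["ACGT"]])


class TestCompareGroups:
    def test_identical_groups_not_significant(self):
        vals = list(np.arange(10.0))
        df = compare_groups({"a": vals, "b": vals})
        row = df[df.test == "mannwhitney"].iloc[0]
        assert row.p_adj == 1.0

    def test_exact_small_sample_p(self):
        df = compare_groups({"lo": [1, 2, 3], "hi": [101, 102, 103]})
        row = df[df.test == "mannwhitney"].iloc[0]
        assert row.statistic in (0.0, 9.0)
        assert row.p_raw == pytest.approx(0.1)

    def test_bonferroni_multiplies_by_pair_count(self):
        rng = np.random.default_rng(34)
        groups = {f"g{i}": rng.normal(i, 1, 25) for i in range(4)}  # 6 pairs
        df = compare_groups(groups)
        mw = df[df.test == "mannwhitney"]
        assert len(mw) == 6
        np.testing.assert_allclose(
            mw.p_adj, np.minimum(1.0, mw.p_raw * 6), atol=1e-12
        )

    def test_kruskal_row_present(self):
        df = compare_groups({"a": [1, 2, 3], "b": [4, 5, 6]})
        assert (df.test == "kruskal").sum() == 1

    def test_small_group_rejected(self):
        with pytest.raises(ValueError, match="fewer than 2"):
            compare_groups({"a": [1.0], "b": [1.0, 2.0]})
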