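"""Counting, normalization, filtering, BH-FDR and significance calling."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from conftest import make_read
from oracles import bh_oracle
from piratlas.core_model import GeneModel, GenomicInterval
from piratlas.quantify import (
    CountMatrix,
    DGEParams,
    benjamini_hochberg,
    call_significant,
    count_features,
    cpm,
    expression_filter,
    group_log2fc,
    mirna_denominators,
    rpkm,
    spikein_factors,
    te_expression,
    two_group_test,
    utr3_pirna_report,
)


class TestCountFeatures:
    def test_sense_and_antisense_modes(self):
        features = {"utr": GenomicInterval("chr1", 50, 200, "+")}
        read = make_read(start=100, length=26, strand="+")
        assert count_features([read], features, "sense")["utr"] == 1
        assert count_features([read], features, "antisense")["utr"] == 0

    def test_read_increments_every_overlapping_feature(self):
        features = {
            "a": GenomicInterval("chr1", 0, 200, "+"),
            "b": GenomicInterval("chr1", 100, 300, "+"),
        }
        read = make_read(start=110, length=26)
        counts = count_features([read], features)
        assert counts["a"] == 1 and counts["b"] == 1

    def test_unstranded_features_reject_stranded_mode(self):
        features = {"x": GenomicInterval("chr1", 0, 100, ".")}
        with pytest.raises(ValueError):
            count_features([], features, "sense")

    def test_tiling_features_conserve_reads(self):
        features = {
            f"bin{i}": GenomicInterval("chr1", i * 100, (i + 1) * 100)
            for i in range(10)
        }
        rng = np.random.default_rng(0)
        # reads fully inside single bins
        reads = [
            make_read(start=int(rng.integers(0, 10)) * 100 + 10, length=26)
            for _ in range(50)
        ]
        assert count_features(reads, features).sum() == 50


class TestTeExpression:
    def _read(self, te, length, strand):
        return make_read(chrom=te, start=10, length=length, strand=strand,
                         space="te_consensus")

    def test_sense_antisense_and_sirna_exclusion(self):
        reads = [
            self._read("ZAM", 26, "+"),
            self._read("ZAM", 26, "-"),
            self._read("ZAM", 21, "+"),   # siRNA length: excluded
        ]
        table = te_expression(reads, ["ZAM", "roo"])
        assert table.loc["ZAM", "sense"] == 1
        assert table.loc["ZAM", "antisense"] == 1
        assert table.loc["roo"].sum() == 0

    def test_unknown_te_listed_in_error(self):
        with pytest.raises(ValueError, match="gypsy"):
            te_expression([self._read("gypsy", 26, "+")], ["ZAM"])


class TestCpmRpkm:
    def _matrix(self):
        return CountMatrix(["f1", "f2"], ["s1"], np.array([[50], [0]]),
                           feature_lengths=np.array([2000, 1000]))

    def test_cpm_arithmetic(self):
        out = cpm(self._matrix(), [1e6])
        assert out.loc["f1", "s1"] == 50.0
        assert out.loc["f2", "s1"] == 0.0

    def test_cpm_joint_scaling_invariance(self):
        m1 = CountMatrix(["f"], ["s"], np.array([[123]]))
        a = cpm(m1, [4.2e5]).iloc[0, 0]
        m2 = CountMatrix(["f"], ["s"], np.array([[123 * 7]]))
        b = cpm(m2, [4.2e5 * 7]).iloc[0, 0]
        assert a == pytest.approx(b, rel=1e-9)

    def test_rpkm_arithmetic(self):
        m = CountMatrix(["f"], ["s"], np.array([[10]]),
                        feature_lengths=np.array([2000]))
        assert rpkm(m, [1e6]).iloc[0, 0] == pytest.approx(5.0)
        assert rpkm(m, [2e6]).iloc[0, 0] == pytest.approx(2.5)

    def test_rpkm_unit_case(self):
        m = CountMatrix(["f"], ["s"], np.array([[2]]),
                        feature_lengths=np.array([1000]))
        assert rpkm(m, [2e6]).iloc[0, 0] == pytest.approx(1.0)


class TestMirnaDenominators:
    def test_identical_counts_give_equal_denominators(self):
        m = CountMatrix(["m1", "m2", "m3"], ["a", "b"],
                        np.array([[10, 10], [20, 20], [30, 30]]))
        d = mirna_denominators(m, groups={"a": "x", "b": "y"})
        assert d["a"] == d["b"]

    def test_strongly_shifted_mirna_is_excluded(self):
        counts = np.array([
            [100, 100, 10000, 10000],   # 100-fold up in group B
            [50, 50, 50, 50],
            [60, 60, 60, 60],
            [70, 70, 70, 70],
        ])
        m = CountMatrix(["hot", "m2", "m3", "m4"],
                        ["a1", "a2", "b1", "b2"], counts)
        groups = {"a1": "A", "a2": "A", "b1": "B", "b2": "B"}
        d = mirna_denominators(m, n_exclude=2, groups=groups)
        # denominators cannot include the hot miRNA's counts
        assert d["b1"] < 10000

    def test_n_exclude_zero_is_plain_totals(self):
        m = CountMatrix(["m1", "m2"], ["a", "b"],
                        np.array([[10, 1], [20, 2]]))
        d = mirna_denominators(m, n_exclude=0,
                               groups={"a": "x", "b": "y"})
        assert d["a"] == 30 and d["b"] == 3

    def test_single_group_falls_back_with_warning(self):
        m = CountMatrix(["m1", "m2", "m3"], ["a", "b"],
                        np.array([[10, 10], [20, 20], [30, 30]]))
        with pytest.warns(UserWarning):
            mirna_denominators(m, groups={"a": "x", "b": "x"})


class TestSpikeinFactors:
    def test_equal_totals_unit_factors(self):
        factors, eff = spikein_factors({"a": 1000, "b": 1000},
                                       {"a": 5e5, "b": 7e5})
        assert factors["a"] == pytest.approx(1.0)
        assert factors["b"] == pytest.approx(1.0)
        assert eff["a"] == pytest.approx(5e5)

    def test_half_spikes_double_factor(self):
        factors, _ = spikein_factors({"a": 1000, "b": 500})
        assert factors["b"] / factors["a"] == pytest.approx(2.0)
        assert np.exp(np.mean(np.log(factors))) == pytest.approx(1.0)

    def test_zero_spike_total_is_error(self):
        with pytest.raises(ValueError):
            spikein_factors({"a": 0})


class TestExpressionFilter:
    def test_hand_counted_toy_matrix(self):
        # 5 features x 6 samples, denominators 1e6 so CPM == count;
        # cutoff 10, min_samples 3:
        counts = np.array([
            [20, 20, 20, 0, 0, 0],     # passes in exactly 3 -> kept
            [20, 20, 0, 0, 0, 0],      # passes in 2 -> removed
            [11, 11, 11, 11, 11, 11],  # passes in 6 -> kept
            [10, 10, 10, 10, 10, 10],  # CPM == 10 is not > 10 -> removed
            [0, 0, 0, 0, 0, 0],        # all zero -> removed
        ])
        m = CountMatrix([f"f{i}" for i in range(5)],
                        [f"s{j}" for j in range(6)], counts,
                        norm_denominators=np.full(6, 1e6))
        out = expression_filter(m, cpm_cutoff=10, min_samples=3)
        assert out.feature_ids == ["f0", "f2"]


class TestBenjaminiHochberg:
    def test_worked_example(self):
        np.testing.assert_allclose(
            benjamini_hochberg([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03]
        )

    def test_single_p_of_one(self):
        np.testing.assert_allclose(benjamini_hochberg([1.0]), [1.0])

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            benjamini_hochberg([0.5, 1.5])

    @pytest.mark.parametrize("seed", range(5))
    def test_agrees_with_stepup_oracle(self, seed):
        rng = np.random.default_rng(seed)
        p = rng.random(200)
        np.testing.assert_allclose(benjamini_hochberg(p), bh_oracle(p),
                                   rtol=1e-12)

    def test_agrees_with_statsmodels(self):
        from statsmodels.stats.multitest import multipletests
        rng = np.random.default_rng(99)
        p = rng.random(500)
        _, q_sm, _, _ = multipletests(p, method="fdr_bh")
        np.testing.assert_allclose(benjamini_hochberg(p), q_sm, rtol=1e-12)

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(st.lists(st.floats(0, 1), min_size=1, max_size=30))
    def test_qvalues_monotone_in_ranked_p(self, p):
        q = benjamini_hochberg(p)
        order = np.argsort(p, kind="stable")
        assert np.all(np.diff(q[order]) >= -1e-12)


class TestCallSignificant:
    @pytest.mark.parametrize("lfc,q,expected", [
        (1.0, 0.05, "up"),        # both boundaries inclusive
        (0.9, 0.001, "ns"),       # fails fold threshold
        (-3.0, 0.2, "ns"),        # fails FDR
        (-1.0, 0.05, "down"),
    ])
    def test_boundaries(self, lfc, q, expected):
        assert call_significant([lfc], [q]) == [expected]


class TestTwoGroupTest:
    def test_balanced_counts_not_significant(self):
        p = two_group_test([100, 100], ["A", "B"], [1e6, 1e6])
        assert p > 0.5

    def test_extreme_imbalance(self):
        p = two_group_test([1000, 0], ["A", "B"], [1e6, 1e6])
        assert p < 1e-6

    def test_group_label_symmetry(self):
        p1 = two_group_test([30, 70], ["A", "B"], [1e6, 2e6])
        p2 = two_group_test([70, 30], ["B", "A"], [2e6, 1e6])
        assert p1 == pytest.approx(p2)

    def test_zero_total_count(self):
        assert two_group_test([0, 0], ["A", "B"], [1e6, 1e6]) == 1.0


class TestUtr3Report:
    def _genes(self):
        g = GeneModel("g1", GenomicInterval("chr1", 0, 1000, "+"), "+")
        g.utr3 = [GenomicInterval("chr1", 100, 400, "+")]
        return {"g1": g}

    def test_antisense_producer(self):
        read = make_read(start=200, length=26, strand="-")
        rep = utr3_pirna_report([read], self._genes(), [])
        assert rep.loc["g1", "antisense_count"] == 1
        assert rep.loc["g1", "producer_class"] == "antisense"

    def test_both_class_with_min_count(self):
        reads = [make_read(start=200 + i * 5, length=26, strand=s)
                 for i in range(5) for s in "+-"]
        rep = utr3_pirna_report(reads, self._genes(), [], min_count=1)
        assert rep.loc["g1", "sense_count"] == 5
        assert rep.loc["g1", "antisense_count"] == 5
        assert rep.loc["g1", "producer_class"] == "both"

    def test_te_fragment_flag(self):
        rep = utr3_pirna_report(
            [], self._genes(), [GenomicInterval("chr1", 350, 600, "+")]
        )
        assert bool(rep.loc["g1", "has_te_fragment"]) is True

    def test_gene_without_utr3_is_none_class(self):
        g = GeneModel("bare", GenomicInterval("chr1", 0, 1000, "+"), "+")
        rep = utr3_pirna_report([make_read(start=200, length=26)],
                                {"bare": g}, [])
        assert rep.loc["bare", "producer_class"] == "none"
        assert rep.loc["bare", "sense_count"] == 0


def test_group_log2fc_recovers_known_shift():
    m = CountMatrix(["f"], ["a1", "a2", "b1", "b2"],
                    np.array([[1000, 1000, 4000, 4000]]),
                    norm_denominators=np.full(4, 1e6))
    lfc = group_log2fc(m, {"a1": "A", "a2": "A", "b1": "B", "b2": "B"},
                       np.full(4, 1e6), pseudo_count=0.0)
    assert lfc["f"] == pytest.approx(2.0)
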