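"""Partition agreement (NMI, RI) and intraclass correlation."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from sklearn.metrics import normalized_mutual_info_score, rand_score

from modtrt import (
    Partition,
    categorize_icc,
    icc,
    nmi,
    partition_overlap,
    rand_index,
    reliability_report,
)

from conftest import anova_icc_oracle, pair_counts_enum


def parts(a, b):
    return Partition(np.array(a)), Partition(np.array(b))


class TestPartitionOverlap:
    def test_identity_has_no_disagreeing_pairs(self):
        pa, pb = parts([1, 1, 2, 2, 3], [1, 1, 2, 2, 3])
        o = partition_overlap(pa, pb)
        assert o.n10 == o.n01 == 0
        assert o.confusion.sum() == o.n == 5

    def test_crossed_partition_counts(self):
        pa, pb = parts([1, 1, 2, 2], [1, 2, 1, 2])
        o = partition_overlap(pa, pb)
        assert (o.n11, o.n00) == (0, 2)

    def test_transposition_symmetry(self):
        rng = np.random.default_rng(0)
        pa = Partition(rng.integers(1, 4, 20))
        pb = Partition(rng.integers(1, 4, 20))
        o, ot = partition_overlap(pa, pb), partition_overlap(pb, pa)
        assert np.array_equal(ot.confusion, o.confusion.T)
        assert (o.n10, o.n01) == (ot.n01, ot.n10)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.integers(min_value=0, max_value=10_000))
    def test_pair_counts_match_direct_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(2, 200))
        a = rng.integers(1, 6, n)
        b = rng.integers(1, 6, n)
        o = partition_overlap(Partition(a), Partition(b))
        n11, n00, n10, n01 = pair_counts_enum(a, b)
        assert (o.n11, o.n00, o.n10, o.n01) == (n11, n00, n10, n01)
        assert o.n11 + o.n00 + o.n10 + o.n01 == n * (n - 1) // 2

    def test_node_set_mismatch_rejected(self):
        with pytest.raises(ValueError):
            partition_overlap(Partition(np.array([1, 2])), Partition(np.array([1, 2, 3])))


class TestNMI:
    def test_identical_partitions_give_one(self):
        pa, pb = parts([1, 1, 2, 2, 3], [1, 1, 2, 2, 3])
        assert nmi(partition_overlap(pa, pb)) == 1.0

    def test_independent_margins_give_zero(self):
        pa, pb = parts([1, 1, 2, 2], [1, 2, 1, 2])
        assert nmi(partition_overlap(pa, pb)) == 0.0

    def test_symmetry(self):
        rng = np.random.default_rng(1)
        pa = Partition(rng.integers(1, 4, 15))
        pb = Partition(rng.integers(1, 5, 15))
        assert nmi(partition_overlap(pa, pb)) == pytest.approx(
            nmi(partition_overlap(pb, pa)), abs=1e-14
        )

    def test_degenerate_single_module_conventions(self):
        one = Partition(np.ones(5, dtype=int))
        split = Partition(np.array([1, 1, 2, 2, 2]))
        assert nmi(partition_overlap(one, one)) == 1.0
        assert nmi(partition_overlap(one, split)) == 0.0

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.integers(min_value=0, max_value=10_000))
    def test_matches_sklearn_arithmetic_normalization(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(3, 40))
        a, b = rng.integers(1, 5, n), rng.integers(1, 5, n)
        ours = nmi(partition_overlap(Partition(a), Partition(b)))
        ref = normalized_mutual_info_score(a, b, average_method="arithmetic")
        assert ours == pytest.approx(ref, abs=1e-10)


class TestRandIndex:
    def test_identical_partitions_give_one(self):
        pa, pb = parts([1, 2, 2, 3], [1, 2, 2, 3])
        assert rand_index(partition_overlap(pa, pb)) == 1.0

    def test_crossed_partition_one_third(self):
        pa, pb = parts([1, 1, 2, 2], [1, 2, 1, 2])
        assert rand_index(partition_overlap(pa, pb)) == pytest.approx(1 / 3)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.integers(min_value=0, max_value=10_000))
    def test_matches_sklearn(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(2, 40))
        a, b = rng.integers(1, 5, n), rng.integers(1, 5, n)
        ours = rand_index(partition_overlap(Partition(a), Partition(b)))
        assert ours == pytest.approx(rand_score(a, b), abs=1e-12)

    def test_single_node_rejected(self):
        o = partition_overlap(Partition(np.array([1])), Partition(np.array([1])))
        with pytest.raises(ValueError):
            rand_index(o)


class TestICC:
    def test_perfect_repeatability(self):
        y = np.column_stack([np.arange(5.0), np.arange(5.0)])
        assert icc(y) == 1.0

    def test_session_shift_absorbed_by_two_way_model(self):
        base = np.array([0.3, 0.9, 0.1, 0.6])
        y = np.column_stack([base, base + 2.5])
        assert icc(y) == pytest.approx(1.0)

    def test_null_table_near_zero(self):
        rng = np.random.default_rng(5)
        y = rng.normal(size=(2000, 2))
        assert abs(icc(y, clamp=False)) <= 0.05

    def test_negative_estimate_clamps_to_zero(self):
        y = np.array([[0.0, 1.0], [1.0, 0.0], [0.0, 1.0], [1.0, 0.0]])
        assert icc(y, clamp=False) < 0
        assert icc(y) == 0.0

    def test_zero_variance_table(self):
        assert icc(np.ones((4, 2))) == 0.0

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_anova_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(3, 51))
        y = rng.normal(size=(n, 2)) + rng.normal(size=(n, 1))
        assert icc(y, clamp=False) == pytest.approx(anova_icc_oracle(y), abs=1e-10)

    def test_matches_pingouin_single_measures_consistency(self):
        import pandas as pd
        import pingouin as pg

        rng = np.random.default_rng(11)
        y = rng.normal(size=(15, 2)) + rng.normal(size=(15, 1))
        df = pd.DataFrame({
            "subj": np.repeat(np.arange(15), 2),
            "sess": np.tile([0, 1], 15),
            "y": y.ravel(),
        })
        res = pg.intraclass_corr(df, targets="subj", raters="sess", ratings="y")
        ref = float(res.loc[res.Type == "ICC(C,1)", "ICC"].iloc[0])
        assert icc(y, clamp=False) == pytest.approx(ref, abs=1e-8)

    def test_location_scale_invariance(self):
        rng = np.random.default_rng(6)
        y = rng.normal(size=(30, 2)) + rng.normal(size=(30, 1))
        v = icc(y)
        assert icc(y + 7.5) == pytest.approx(v, abs=1e-12)
        assert icc(y * 3.2) == pytest.approx(v, abs=1e-12)

    @pytest.mark.parametrize("sb,sw", [(1.0, 1.0), (2.0, 1.0), (1.0, 2.0)])
    def test_parameter_recovery(self, sb, sw):
        rng = np.random.default_rng(hash((sb, sw)) % 2**31)
        n = 500
        y = rng.normal(0, sb, size=(n, 1)) + rng.normal(0, sw, size=(n, 2))
        expected = sb**2 / (sb**2 + sw**2)
        assert icc(y) == pytest.approx(expected, abs=0.05)

    def test_missing_cells_rejected(self):
        y = np.array([[1.0, np.nan], [2.0, 2.0]])
        with pytest.raises(ValueError, match="missing"):
            icc(y)


class TestBands:
    @pytest.mark.parametrize(
        "value,band",
        [(0.0, "poor"), (0.19, "poor"), (0.2, "fair"), (0.4, "moderate"),
         (0.6, "good"), (0.79, "good"), (0.8, "excellent"), (0.85, "excellent"),
         (1.0, "excellent")],
    )
    def test_band_boundaries_left_closed(self, value, band):
        assert categorize_icc(value) == band

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            categorize_icc(-0.1)
        with pytest.raises(ValueError):
            categorize_icc(1.1)


class TestReport:
    def test_perfect_duplicate_cohort(self):
        rng = np.random.default_rng(7)
        base = rng.normal(size=5)
        tables = {m: np.column_stack([base, base]) for m in ("modularity", "intra_fc", "inter_fc")}
        nodal_base = rng.normal(size=(5, 3))
        nodal = {m: np.stack([np.stack([nodal_base[i], nodal_base[i]]) for i in range(5)])
                 for m in ("within_degree", "participation")}
        p = Partition(np.array([1, 1, 2]))
        rep = reliability_report(tables, nodal, [p] * 5, [p] * 5, level="individual")
        assert all(v["value"] == 1.0 for v in rep.icc.values())
        assert all(v["band"] == "excellent" for v in rep.icc.values())
        assert all(v["mean"] == 1.0 for v in rep.nodal_icc.values())
        assert rep.partition_agreement["mean_nmi"] == 1.0
        assert rep.partition_agreement["mean_rand_index"] == 1.0

    def test_report_enumeration_and_serialization(self, tmp_path):
        rng = np.random.default_rng(8)
        tables = {m: rng.normal(size=(6, 2)) for m in ("modularity", "intra_fc", "inter_fc")}
        nodal = {m: rng.normal(size=(6, 2, 4)) for m in ("within_degree", "participation")}
        rep = reliability_report(tables, nodal, level="individual")
        assert len(rep.icc) == 3
        assert len(rep.nodal_icc) == 2
        assert all(len(v["per_node"]) == 4 for v in rep.nodal_icc.values())
        text = rep.to_json(tmp_path / "r.json")
        assert (tmp_path / "r.json").read_text() == text

    def test_shuffled_subjects_destroy_pairing(self):
        rng = np.random.default_rng(9)
        base = rng.normal(size=300)
        noisy = base + rng.normal(0, 0.1, size=300)
        paired = icc(np.column_stack([base, noisy]))
        shuffled = icc(np.column_stack([base, rng.permutation(noisy)]))
        assert paired > 0.9
        assert shuffled < 0.2

    def test_subject_mismatch_rejected(self):
        p = Partition(np.array([1, 2]))
        with pytest.raises(ValueError, match="mismatch"):
            reliability_report({}, None, [p, p], [p], level="individual")
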