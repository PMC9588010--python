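"""Rank-sum tests, BH, exercise DE, composition, ORA, bulk overlap."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
import scipy.stats
from hypothesis import given, settings, strategies as st

import musclesc as ms
from musclesc.errors import ValidationError
from musclesc.io_formats import GeneSetCollection
from .test_preprocess import matrix_from_dense


def ranksum_enumeration_oracle(x, y, sidedness):
    """Exact rank-sum p by brute-force enumeration of group assignments."""
    pooled = np.concatenate([x, y])
    n1 = len(x)
    ranks = scipy.stats.rankdata(pooled)
    obs = ranks[:n1].sum()
    stats = [sum(ranks[list(c)]) for c in itertools.combinations(range(len(pooled)), n1)]
    stats = np.array(stats)
    if sidedness == "greater":
        return np.mean(stats >= obs - 1e-12)
    if sidedness == "less":
        return np.mean(stats <= obs + 1e-12)
    hi = np.mean(stats >= obs - 1e-12)
    lo = np.mean(stats <= obs + 1e-12)
    return min(1.0, 2 * min(hi, lo))


class TestRankSum:
    def test_three_vs_three_complete_separation_is_exactly_p05(self):
        res = ms.rank_sum_test([1, 2, 3], [4, 5, 6], "less")
        assert res.p == pytest.approx(0.05, abs=1e-12)
        assert res.method == "exact"

    def test_identical_samples_two_sided_p_is_one(self):
        res = ms.rank_sum_test([1.0, 2.0, 3.0], [1.0, 2.0, 3.0], "two")
        assert res.p == pytest.approx(1.0, abs=1e-6)

    def test_exact_path_matches_enumeration_on_random_8v8(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            vals = rng.permutation(1000)[:16].astype(float)
            x, y = vals[:8], vals[8:]
            for side in ("two", "greater", "less"):
                got = ms.rank_sum_test(x, y, side)
                want = ranksum_enumeration_oracle(x, y, side)
                assert got.p == pytest.approx(want, abs=1e-12)

    def test_exhaustive_small_sizes_match_oracle(self):
        """Every group-size pair with n1+n2 <= 12 agrees with enumeration."""
        rng = np.random.default_rng(1)
        for n1 in range(1, 11):
            for n2 in range(1, 12 - n1 + 1):
                vals = rng.permutation(1000)[: n1 + n2].astype(float)
                x, y = vals[:n1], vals[n1:]
                for side in ("two", "greater", "less"):
                    got = ms.rank_sum_test(x, y, side).p
                    want = ranksum_enumeration_oracle(x, y, side)
                    assert got == pytest.approx(want, abs=1e-12), (n1, n2, side)

    def test_ties_fall_back_to_normal_approximation(self):
        res = ms.rank_sum_test([1, 1, 2], [2, 3, 3], "two")
        assert res.method == "normal_approx"

    def test_empty_group_rejected(self):
        with pytest.raises(ValidationError):
            ms.rank_sum_test([], [1.0], "two")

    @given(st.lists(st.integers(0, 1000), min_size=1, max_size=8, unique=True),
           st.lists(st.integers(2000, 3000), min_size=1, max_size=8, unique=True))
    @settings(max_examples=50, deadline=None)
    def test_one_sided_p_bounded_and_consistent(self, x, y):
        x, y = [float(v) for v in x], [float(v) for v in y]
        lo = ms.rank_sum_test(x, y, "less").p
        hi = ms.rank_sum_test(x, y, "greater").p
        assert 0 < lo <= 1 and 0 < hi <= 1
        # y is always strictly larger, so "x less" is the supported side
        assert lo <= hi


class TestVectorizedRankSum:
    def test_matches_scipy_with_ties(self):
        from musclesc.differential import ranksum_p_vs_rest

        rng = np.random.default_rng(0)
        dense = rng.poisson(1.0, (40, 120)).astype(float)
        members = np.zeros(120, bool)
        members[rng.choice(120, 40, replace=False)] = True
        got = ranksum_p_vs_rest(dense, members)
        want = scipy.stats.mannwhitneyu(
            dense[:, members], dense[:, ~members], axis=1,
            alternative="two-sided", method="asymptotic",
        ).pvalue
        assert np.allclose(got, want, atol=1e-12)


class TestBH:
    def test_closed_form_example(self):
        got = ms.bh_adjust([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(got, [0.04, 0.04, 0.04, 0.04])

    def test_single_p_unchanged(self):
        assert ms.bh_adjust([0.3])[0] == pytest.approx(0.3)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValidationError):
            ms.bh_adjust([0.5, 1.5])

    @given(st.lists(st.floats(0, 1, allow_nan=False), min_size=1, max_size=40))
    @settings(max_examples=100, deadline=None)
    def test_adjusted_at_least_raw_and_order_preserved(self, p):
        adj = ms.bh_adjust(p)
        assert (adj >= np.asarray(p) - 1e-12).all()
        assert (adj <= 1.0 + 1e-12).all()
        # monotone: sorting raw p ascending sorts adjusted non-decreasing
        order = np.argsort(p, kind="stable")
        assert (np.diff(adj[order]) >= -1e-12).all()


class TestExerciseDE:
    def _norm_with_shift(self, shift, n_genes=30, n_per=40, seed=0):
        rng = np.random.default_rng(seed)
        dense = rng.poisson(5.0, (n_genes, 4 * n_per))
        tp = ["pre"] * n_per + ["post"] * n_per + ["pre"] * n_per + ["post"] * n_per
        # first 2*n_per cells are Myogenic, rest Endothelial
        dense[0, n_per:2 * n_per] += shift  # shifted post-exercise in Myogenic only
        m = matrix_from_dense(dense, timepoints=tp)
        norm = ms.normalize_log1p(m, ms.PipelineParams())
        types = np.array(["Myogenic"] * (2 * n_per) + ["Endothelial"] * (2 * n_per))
        return norm, types

    def test_shifted_gene_detected_only_in_its_type(self, params):
        norm, types = self._norm_with_shift(shift=30)
        de = ms.exercise_de(norm, types, params)
        myo = de[(de.cell_type == "Myogenic") & (de.gene == "G0")]
        assert len(myo) == 1 and myo.iloc[0].fdr < 0.05
        endo = de[(de.cell_type == "Endothelial") & (de.gene == "G0")]
        assert endo.empty or endo.iloc[0].fdr > 0.05

    def test_gate_requires_expression_at_both_timepoints(self, params):
        rng = np.random.default_rng(1)
        n = 40
        dense = rng.poisson(5.0, (3, 2 * n))
        dense[0, :n] = (np.arange(n) < int(0.6 * n)).astype(int) * 5  # 60% pre
        dense[0, n:] = (np.arange(n) < int(0.4 * n)).astype(int) * 5  # 40% post
        tp = ["pre"] * n + ["post"] * n
        norm = ms.normalize_log1p(matrix_from_dense(dense, timepoints=tp), params)
        de = ms.exercise_de(norm, np.array(["T"] * 2 * n), params)
        assert de[de.gene == "G0"].empty

    def test_null_data_yields_no_discoveries(self, params):
        rng = np.random.default_rng(2)
        n = 50
        dense = rng.poisson(5.0, (200, 2 * n))
        tp = ["pre"] * n + ["post"] * n
        norm = ms.normalize_log1p(matrix_from_dense(dense, timepoints=tp), params)
        de = ms.exercise_de(norm, np.array(["T"] * 2 * n), params)
        assert (de.fdr < 0.05).sum() == 0

    def test_type_missing_a_timepoint_skipped(self, params):
        dense = np.full((3, 20), 5)
        tp = ["pre"] * 20
        norm = ms.normalize_log1p(matrix_from_dense(dense, timepoints=tp), params)
        with pytest.warns(UserWarning, match="skipped"):
            de = ms.exercise_de(norm, np.array(["T"] * 20), params)
        assert de.empty


class TestComposition:
    @staticmethod
    def _comp(pre, post, ctype="Lymphocyte"):
        rows = []
        for i, v in enumerate(pre):
            rows.append((f"S{i}pre", "pre", ctype, 10, v))
            rows.append((f"S{i}pre", "pre", "Other", 10, 1 - v))
        for i, v in enumerate(post):
            rows.append((f"S{i}post", "post", ctype, 10, v))
            rows.append((f"S{i}post", "post", "Other", 10, 1 - v))
        return pd.DataFrame(rows, columns=["sample_id", "timepoint", "cell_type",
                                           "n_cells", "proportion"])

    def test_complete_separation_3v3_gives_p05(self):
        comp = self._comp([0.03, 0.04, 0.05], [0.07, 0.09, 0.10])
        res = ms.composition_shift_test(comp, "increase")
        assert res.loc["Lymphocyte", "p"] == pytest.approx(0.05, abs=1e-12)

    def test_equal_proportions_not_significant(self):
        comp = self._comp([0.03, 0.04, 0.05], [0.03, 0.04, 0.05])
        res = ms.composition_shift_test(comp, "increase")
        assert res.loc["Lymphocyte", "p"] > 0.5

    def test_direction_reversal_matches_enumeration(self):
        pre, post = [0.03, 0.06, 0.04], [0.07, 0.05, 0.10]
        comp = self._comp(pre, post)
        inc = ms.composition_shift_test(comp, "increase").loc["Lymphocyte", "p"]
        dec = ms.composition_shift_test(comp, "decrease").loc["Lymphocyte", "p"]
        assert inc == pytest.approx(
            ranksum_enumeration_oracle(np.array(post), np.array(pre), "greater"), abs=1e-12)
        assert dec == pytest.approx(
            ranksum_enumeration_oracle(np.array(post), np.array(pre), "less"), abs=1e-12)

    def test_single_sample_timepoint_rejected(self):
        comp = self._comp([0.05], [0.07, 0.09])
        with pytest.raises(ValidationError):
            ms.composition_shift_test(comp, "increase")

    def test_table_proportions_sum_to_one(self, full_run):
        comp = full_run["_objects"]["composition"]
        sums = comp.groupby("sample_id")["proportion"].sum()
        assert np.allclose(sums, 1.0, atol=1e-9)

    def test_designed_immune_increase_detected(self, full_run):
        tests = full_run["composition"]["tests"]
        assert tests["Lymphocyte"] < 0.05  # 4% -> 9%, the large influx
        # monocytes double from a tiny base (~20 cells/sample): the exact
        # 4v4 test is near-significant at worst under sampling noise
        assert tests["Monocyte"] <= 0.1
        assert tests["Endothelial"] > 0.5  # decreases, so one-sided increase is null


class TestORA:
    def test_five_of_five_overlap_closed_form(self):
        sets = GeneSetCollection(sets={"S": ("d", {f"G{i}" for i in range(5)})})
        background = {f"G{i}" for i in range(20)}
        query = {f"G{i}" for i in range(5)}
        res = ms.hypergeom_ora(query, sets, background)
        assert res.iloc[0].p == pytest.approx(1 / math.comb(20, 5), rel=1e-9)

    def test_zero_overlap_gives_p_one(self):
        sets = GeneSetCollection(sets={"S": ("d", {"G0", "G1"})})
        background = {f"G{i}" for i in range(20)}
        res = ms.hypergeom_ora({"G10", "G11"}, sets, background)
        assert res.iloc[0].p == pytest.approx(1.0)

    def test_tail_probability_matches_sampling(self):
        rng = np.random.default_rng(0)
        background = [f"G{i}" for i in range(40)]
        target = set(background[:8])
        sets = GeneSetCollection(sets={"S": ("d", target)})
        k_obs = 4
        n_draw = 10
        p = ms.hypergeom_ora(set(background[:k_obs]) | set(background[20:20 + n_draw - k_obs]),
                             sets, set(background)).iloc[0].p
        hits = 0
        reps = 10000
        for _ in range(reps):
            draw = rng.choice(40, n_draw, replace=False)
            if len(set(background[i] for i in draw) & target) >= k_obs:
                hits += 1
        assert abs(p - hits / reps) < 0.02

    def test_p_valid_under_random_queries(self):
        """Null ORA p-values are valid: P(p <= a) <= a (discrete tests
        are super-uniform, so exact uniformity is not expected)."""
        rng = np.random.default_rng(1)
        background = [f"G{i}" for i in range(200)]
        sets = GeneSetCollection(sets={"S": ("d", set(background[:40]))})
        pvals = np.array([
            ms.hypergeom_ora(set(rng.choice(background, 30, replace=False)),
                             sets, set(background)).iloc[0].p
            for _ in range(500)
        ])
        for alpha in (0.01, 0.05, 0.10, 0.25):
            assert (pvals <= alpha).mean() <= alpha + 0.03
        # and no evidence of anti-conservatism overall
        ks = scipy.stats.kstest(pvals, "uniform", alternative="greater").pvalue
        assert ks > 0.01

    def test_query_outside_background_rejected(self):
        sets = GeneSetCollection(sets={"S": ("d", {"G0"})})
        with pytest.raises(ValidationError):
            ms.hypergeom_ora({"NOT_THERE"}, sets, {"G0", "G1"})


class TestBulkOverlap:
    def test_boundary_logcpm_is_strictly_above(self, params):
        dense = np.full((3, 10), 5)
        norm = ms.normalize_log1p(matrix_from_dense(dense), params)
        bulk = pd.Series({"G0": 4.0, "G1": 4.01, "G2": 10.0})
        bulk_only, shared, sc_only = ms.bulk_sc_overlap(
            bulk, norm, np.array(["T"] * 10), params)
        assert "G0" not in bulk_only | shared  # exactly 4.0 is not detected

    def test_constructed_three_way_partition(self, params):
        # 6 genes: 2 bulk-only, 3 shared, 1 sc-only
        dense = np.zeros((6, 10), int)
        dense[1:5] = 5  # G1..G4 expressed in all cells
        m = matrix_from_dense(dense)
        norm = ms.normalize_log1p(m, params)
        bulk = pd.Series({"G0": 9.0, "G5": 8.0, "G1": 9.0, "G2": 9.0, "G3": 9.0,
                          "G4": 1.0})
        bulk_only, shared, sc_only = ms.bulk_sc_overlap(
            bulk, norm, np.array(["T"] * 10), params)
        assert bulk_only == {"G0", "G5"}
        assert shared == {"G1", "G2", "G3"}
        assert sc_only == {"G4"}

    def test_disjoint_universes_rejected(self, params):
        dense = np.full((2, 10), 5)
        norm = ms.normalize_log1p(matrix_from_dense(dense), params)
        with pytest.raises(ValidationError):
            ms.bulk_sc_overlap(pd.Series({"X": 5.0}), norm, np.array(["T"] * 10), params)
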