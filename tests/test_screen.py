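import numpy as np
import pandas as pd
import pytest
from scipy import stats

from conftest import bh_closed_form
from segain.prognostic_screen import (
    ExpressionMatrix,
    alteration_matrix,
    alteration_rank_metric,
    bh_adjust,
    filter_upregulated,
    kaplan_meier,
    logrank_test,
    median_split,
    mutual_exclusivity,
    preranked_gsea,
    run_screen,
    truncate_survival,
)


def make_expr(values, n_tumor, n_normal):
    genes = list(values.keys())
    cols = [f"T{i}" for i in range(n_tumor)] + [f"N{i}" for i in range(n_normal)]
    df = pd.DataFrame({g: v for g, v in values.items()}).T
    df.columns = cols
    labels = pd.Series(["tumor"] * n_tumor + ["normal"] * n_normal, index=cols)
    return ExpressionMatrix(values=df, sample_labels=labels)


class TestUpregulationFilter:
    def test_identical_distributions_yield_nothing(self):
        rng = np.random.default_rng(0)
        vals = rng.normal(5, 0.3, size=60)
        expr = make_expr({"G1": vals}, 30, 30)
        assert filter_upregulated(expr) == []

    def test_planted_twofold_gene_detected(self):
        rng = np.random.default_rng(1)
        base = rng.normal(5, 0.3, size=60)
        up = base.copy()
        up[:30] += 1.0  # 2-fold on log2 scale
        expr = make_expr({"UP": up, "FLAT": base}, 30, 30)
        assert filter_upregulated(expr) == ["UP"]

    def test_downregulated_gene_excluded_despite_tiny_p(self):
        vals = np.concatenate([np.full(30, 3.0), np.full(30, 6.0)])
        vals += np.random.default_rng(2).normal(0, 0.01, 60)
        expr = make_expr({"DOWN": vals}, 30, 30)
        assert filter_upregulated(expr) == []

    def test_single_sample_group_is_error(self):
        expr = make_expr({"G": np.arange(3.0)}, 2, 1)
        with pytest.raises(ValueError):
            filter_upregulated(expr)


class TestMedianSplit:
    def test_even_n(self):
        high, low = median_split(pd.Series([1, 2, 3, 4],
                                           index=list("abcd")))
        assert (set(high), set(low)) == ({"c", "d"}, {"a", "b"})

    def test_odd_n_ties_go_low(self):
        high, low = median_split(pd.Series([1, 2, 3], index=list("abc")))
        assert (set(high), set(low)) == ({"c"}, {"a", "b"})

    def test_constant_values_error(self):
        with pytest.raises(ValueError, match="degenerate"):
            median_split(pd.Series([2.0, 2.0, 2.0]))


class TestSurvival:
    def test_km_starts_at_one_and_matches_empirical_without_censoring(self):
        rng = np.random.default_rng(3)
        times = rng.exponential(100, size=40)
        df = pd.DataFrame({"time": times, "event": 1})
        km = kaplan_meier(df)
        assert km.loc[km.time == 0, "survival"].iloc[0] == 1.0
        for t, s in zip(km.time, km.survival):
            assert s == pytest.approx((times > t).mean())

    def test_identical_groups_statistic_zero(self):
        a = pd.DataFrame({"time": [1, 2], "event": [1, 1]})
        stat, p = logrank_test(a, a.copy())
        assert stat == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_hand_computed_instance(self):
        # A events at 1,3; B at 2,4; no censoring. O-E and hypergeometric
        # variances by hand: (O-E)=2/3, V=13/18, chi2=8/13.
        a = pd.DataFrame({"time": [1, 3], "event": [1, 1]})
        b = pd.DataFrame({"time": [2, 4], "event": [1, 1]})
        stat, p = logrank_test(a, b)
        assert stat == pytest.approx(8 / 13)
        assert p == pytest.approx(1 - stats.chi2.cdf(8 / 13, df=1))

    def test_no_events_is_error(self):
        a = pd.DataFrame({"time": [1, 2], "event": [0, 0]})
        with pytest.raises(ValueError, match="event"):
            logrank_test(a, a.copy())

    def test_truncation_censors_past_horizon(self):
        df = pd.DataFrame({"time": [100, 2_000, 1_825], "event": [1, 1, 1]})
        out = truncate_survival(df, horizon=1_825)
        assert list(out.time) == [100, 1_825, 1_825]
        assert list(out.event) == [1, 0, 1]


class TestAlterations:
    def test_sign_of_deviation(self):
        mat = alteration_matrix(pd.DataFrame([[1.0, 1.0, 1.0, 5.0]],
                                             index=["G"]))
        assert list(mat.loc["G"]) == [0, 0, 0, 1]

    def test_symmetric_values_split_half(self):
        mat = alteration_matrix(pd.DataFrame([[1.0, 2.0, 4.0, 5.0]],
                                             index=["G"]))
        assert mat.loc["G"].sum() == 2

    def test_zero_variance_gene_is_error(self):
        with pytest.raises(ValueError, match="zero-variance"):
            alteration_matrix(pd.DataFrame([[2.0, 2.0, 2.0]], index=["G"]))

    def test_altered_in_any_union_fraction(self):
        # 4 independent genes each altered in ~half the cohort:
        # P(altered in any) = 1 - 0.5^4 = 93.75%
        rng = np.random.default_rng(5)
        n = 4_000
        expr = pd.DataFrame(rng.normal(size=(4, n)),
                            index=list("ABCD"))
        mat = alteration_matrix(expr)
        frac = mat.any(axis=0).mean()
        assert frac == pytest.approx(1 - 0.5**4, abs=0.02)


class TestMutualExclusivity:
    def test_identical_rows_co_occur(self):
        mat = pd.DataFrame([[1, 1, 0, 0]] * 2, index=["A", "B"])
        (r,) = mutual_exclusivity(mat)
        assert r.tendency == "co-occurrence"
        assert r.table == (2, 0, 0, 2)
        _or, p = stats.fisher_exact([[2, 0], [0, 2]])
        assert r.p == pytest.approx(p)

    def test_haldane_corrected_odds_ratio(self):
        mat = pd.DataFrame(
            [[1] * 10 + [0] * 10, [1] * 10 + [0] * 10], index=["A", "B"])
        (r,) = mutual_exclusivity(mat)
        assert r.table == (10, 0, 0, 10)
        assert r.log2_odds_ratio == pytest.approx(
            np.log2((10.5 * 10.5) / (0.5 * 0.5)))

    def test_opposite_rows_are_mutually_exclusive(self):
        mat = pd.DataFrame([[1, 1, 0, 0], [0, 0, 1, 1]], index=["A", "B"])
        (r,) = mutual_exclusivity(mat)
        assert r.tendency == "mutual exclusivity"
        assert r.log2_odds_ratio < 0

    def test_independent_rows_give_uniformish_p_and_q_above_p(self):
        rng = np.random.default_rng(6)
        mat = pd.DataFrame((rng.random((12, 200)) < 0.5).astype(int),
                           index=[f"G{i}" for i in range(12)])
        res = mutual_exclusivity(mat)
        ps = np.array([r.p for r in res])
        assert all(r.q >= r.p - 1e-12 for r in res)
        assert (ps < 0.05).mean() < 0.25  # no wholesale false signal
        qs = bh_closed_form(ps)
        np.testing.assert_allclose([r.q for r in res], qs, rtol=1e-10)


class TestBH:
    def test_matches_step_up_closed_form(self):
        rng = np.random.default_rng(7)
        for n in (1, 2, 10, 101):
            p = rng.random(n)
            np.testing.assert_allclose(bh_adjust(p), bh_closed_form(p),
                                       rtol=1e-12)

    def test_monotone_in_p_rank(self):
        p = np.random.default_rng(8).random(50)
        q = bh_adjust(p)
        order = np.argsort(p)
        assert np.all(np.diff(q[order]) >= -1e-12)


class TestGSEA:
    def ranking(self, n=100, seed=9):
        rng = np.random.default_rng(seed)
        scores = np.sort(rng.normal(size=n))[::-1]
        return pd.Series(scores, index=[f"G{i}" for i in range(n)])

    def test_planted_top_set_is_significant(self):
        scores = self.ranking()
        top10 = list(scores.index[:10])
        (res,) = preranked_gsea(scores, {"top": top10}, n_perm=1_000, seed=1)
        assert res.es > 0
        assert res.p <= 0.01
        assert set(res.leading_edge) <= set(top10)

    def test_top_k_set_has_maximal_es_among_same_size_sets(self):
        scores = self.ranking()
        rng = np.random.default_rng(10)
        sets = {"top": list(scores.index[:10])}
        for i in range(20):
            sets[f"rand{i}"] = list(rng.choice(scores.index, 10, replace=False))
        res = {r.name: r.es for r in preranked_gsea(scores, sets, n_perm=10,
                                                    seed=2)}
        assert res["top"] == max(res.values())

    def test_disjoint_and_singleton_sets_skipped(self):
        scores = self.ranking(20)
        with pytest.warns(UserWarning):
            res = preranked_gsea(
                scores, {"absent": ["X1", "X2"], "single": ["G0"]},
                n_perm=10, seed=3)
        assert res == []

    def test_walk_returns_to_zero_at_final_position(self):
        from segain.prognostic_screen import _es_walk

        scores = self.ranking(50).to_numpy()
        mask = np.zeros(50, dtype=bool)
        mask[[3, 10, 30, 44]] = True
        weights = np.abs(scores) * mask
        p_hit = np.cumsum(weights) / weights.sum()
        p_miss = np.cumsum(~mask) / (~mask).sum()
        assert (p_hit - p_miss)[-1] == pytest.approx(0.0)
        es, _ = _es_walk(scores, mask)
        assert abs(es) <= 1.0

    def test_seeded_runs_reproduce(self):
        scores = self.ranking()
        sets = {"s": list(scores.index[5:25:2])}
        a = preranked_gsea(scores, sets, n_perm=200, seed=42)
        b = preranked_gsea(scores, sets, n_perm=200, seed=42)
        assert a == b


class TestRunScreen:
    @staticmethod
    def cohort(seed, effect=1.0, hr=2.0, n_genes=30, n_tumor=300, n_normal=30):
        from segain.synthetic_data import SyntheticConfig, simulate_cohort

        cfg = SyntheticConfig(
            n_tumor=n_tumor, n_normal=n_normal, log2_effect=effect,
            hazard_ratio=hr, seed=seed)
        genes = [f"G{i:03d}" for i in range(n_genes)]
        planted = genes[:4]
        expr, clinical = simulate_cohort(cfg, genes, planted)
        return expr, clinical, genes, planted

    def test_recovers_planted_genes(self):
        expr, clinical, genes, planted = self.cohort(seed=21)
        matrix = ExpressionMatrix(
            values=expr, sample_labels=clinical.set_index("sample")["group"])
        res = run_screen(matrix, clinical, genes, seed=0)
        assert set(planted) <= set(res.selected)
        assert res.alterations is not None
        assert len(res.exclusivity) == len(res.selected) * \
            (len(res.selected) - 1) // 2

    def test_null_cohort_selects_at_chance_rate(self):
        expr, clinical, genes, _ = self.cohort(seed=22, effect=0.0, hr=1.0)
        matrix = ExpressionMatrix(
            values=expr, sample_labels=clinical.set_index("sample")["group"])
        res = run_screen(matrix, clinical, genes, seed=0)
        # two independent p<0.05 hurdles: expect ~n*alpha^2 selections
        assert len(res.selected) <= 3

    def test_rank_metric_requires_both_groups(self):
        expr = pd.DataFrame(np.ones((2, 4)), index=["A", "B"])
        with pytest.raises(ValueError):
            alteration_rank_metric(expr, pd.Series([True] * 4))
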