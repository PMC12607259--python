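import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from hemilat.stats import (
    MixedModelResult,
    SummaryStats,
    ancova,
    chi_square,
    fdr_bh,
    fit_group_time_lmm,
    games_howell,
    one_sample_t,
    one_way_anova,
    partial_correlation,
    pooled_t,
)


class TestPooledT:
    def test_summary_route_equals_raw_route(self):
        rng = np.random.default_rng(0)
        a, b = rng.normal(0, 1, 15), rng.normal(0.5, 1.2, 20)
        raw = pooled_t(a, b)
        summ = pooled_t(SummaryStats.from_values(a), SummaryStats.from_values(b))
        assert raw.statistic == summ.statistic
        assert raw.p == summ.p
        assert raw.effect_size == summ.effect_size

    def test_matches_scipy_on_raw_data(self):
        rng = np.random.default_rng(1)
        a, b = rng.normal(0, 1, 12), rng.normal(0.3, 1, 17)
        res = pooled_t(a, b)
        ref = sps.ttest_ind(a, b, equal_var=True)
        assert res.statistic == pytest.approx(ref.statistic)
        assert res.p == pytest.approx(ref.pvalue)

    def test_equal_groups_give_zero(self):
        s = SummaryStats(10, 5.0, 2.0)
        res = pooled_t(s, s)
        assert res.statistic == 0.0 and res.p == 1.0 and res.effect_size == 0.0

    def test_identical_constant_groups_defined_as_zero(self):
        res = pooled_t(SummaryStats(5, 3.0, 0.0), SummaryStats(5, 3.0, 0.0))
        assert res.statistic == 0.0 and res.p == 1.0


class TestChiSquare:
    def test_identical_row_proportions_give_zero(self):
        res = chi_square([[10, 20], [20, 40]])
        assert res.statistic == pytest.approx(0.0)
        assert res.p == pytest.approx(1.0)

    def test_permutation_invariance(self):
        table = np.array([[8, 20], [12, 16], [19, 7]])
        a = chi_square(table)
        b = chi_square(table[::-1, ::-1])
        assert a.statistic == pytest.approx(b.statistic)

    def test_zero_marginal_rejected(self):
        with pytest.raises(ValueError, match="marginal"):
            chi_square([[0, 0], [5, 3]])

    def test_too_small_table_rejected(self):
        with pytest.raises(ValueError):
            chi_square([[3, 4]])


class TestOneWayAnova:
    def test_two_group_f_equals_t_squared(self):
        rng = np.random.default_rng(2)
        a, b = rng.normal(0, 1, 14), rng.normal(0.4, 1, 18)
        f = one_way_anova([a, b])
        t = pooled_t(a, b)
        assert f.statistic == pytest.approx(t.statistic**2)
        assert f.p == pytest.approx(t.p)

    def test_matches_scipy_f_oneway(self):
        rng = np.random.default_rng(3)
        groups = [rng.normal(m, 1, n) for m, n in ((0, 10), (0.5, 14), (1.0, 12))]
        res = one_way_anova(groups)
        ref = sps.f_oneway(*groups)
        assert res.statistic == pytest.approx(ref.statistic)
        assert res.p == pytest.approx(ref.pvalue)

    def test_equal_means_give_zero(self):
        res = one_way_anova(
            [SummaryStats(10, 5.0, 1.0), SummaryStats(12, 5.0, 2.0), SummaryStats(8, 5.0, 1.5)]
        )
        assert res.statistic == pytest.approx(0.0)

    def test_partial_eta_squared_definition(self):
        rng = np.random.default_rng(4)
        groups = [rng.normal(m, 1, 20) for m in (0, 1)]
        res = one_way_anova(groups)
        df1, df2 = res.df
        expected = res.statistic * df1 / (res.statistic * df1 + df2)
        assert res.effect_size == pytest.approx(expected)


class TestAncova:
    def _data(self, het=False, seed=5):
        rng = np.random.default_rng(seed)
        n = 90
        group = np.repeat(["a", "b", "c"], n // 3)
        covar = rng.normal(0, 1, n)
        sd = np.where(group == "a", 0.5, 2.0) if het else 1.0
        y = 0.5 * (group == "b") + 0.8 * covar + rng.normal(0, 1, n) * sd
        return y, group, covar

    def test_orthogonal_covariate_reduces_to_anova(self):
        rng = np.random.default_rng(6)
        n = 60
        group = np.repeat(["a", "b"], n // 2)
        y = 0.7 * (group == "b") + rng.normal(0, 1, n)
        covar = rng.normal(0, 1, n)
        # project out any accidental association with group and outcome
        design = np.column_stack([np.ones(n), group == "b", y])
        covar = covar - design @ np.linalg.lstsq(design, covar, rcond=None)[0]
        plain = one_way_anova([y[group == "a"], y[group == "b"]])
        adj = ancova(y, group, covar)
        assert adj.statistic == pytest.approx(plain.statistic, rel=0.05)

    def test_matches_pingouin_classical_f(self):
        import pingouin as pg

        y, group, covar = self._data()
        res = ancova(y, group, covar)
        ref = pg.ancova(
            data=pd.DataFrame({"y": y, "g": group, "c": covar}),
            dv="y", between="g", covar="c",
        )
        row = ref[ref.Source == "g"].iloc[0]
        assert res.statistic == pytest.approx(row.F)
        assert res.p == pytest.approx(row["p_unc"])
        assert res.effect_size == pytest.approx(row.np2, abs=1e-6)

    def test_hc3_changes_p_under_heteroskedasticity(self):
        diffs = []
        for seed in range(40):
            y, group, covar = self._data(het=True, seed=100 + seed)
            classical = ancova(y, group, covar)
            robust = ancova(y, group, covar, hc3=True)
            diffs.append(robust.p - classical.p)
        assert np.mean(np.array(diffs) != 0) == 1.0
        assert abs(np.mean(diffs)) > 0.001  # systematic, not noise

    def test_rank_deficiency_rejected(self):
        y, group, covar = self._data()
        dup = np.column_stack([covar, covar])
        with pytest.raises(ValueError, match="rank deficient"):
            ancova(y, group, dup)


class TestOneSampleT:
    def test_values_equal_mu(self):
        res = one_sample_t(np.full(10, 3.3), mu=3.3)
        assert res.statistic == 0.0 and res.p == 1.0

    def test_matches_scipy(self):
        rng = np.random.default_rng(7)
        x = rng.normal(0.5, 1, 26)
        res = one_sample_t(x)
        ref = sps.ttest_1samp(x, 0.0)
        assert res.statistic == pytest.approx(ref.statistic)
        assert res.effect_size == pytest.approx(x.mean() / x.std(ddof=1))

    def test_sign_flip_antisymmetry(self):
        rng = np.random.default_rng(8)
        x = rng.normal(0.2, 1, 20)
        a, b = one_sample_t(x), one_sample_t(-x)
        assert a.statistic == pytest.approx(-b.statistic)
        assert a.p == pytest.approx(b.p)

    def test_rightward_lateralization_detected(self):
        rng = np.random.default_rng(9)
        li = rng.normal(-0.1, 0.1, 26)
        res = one_sample_t(li)
        assert res.statistic < -2.615 and res.effect_size < -0.494


class TestPartialCorrelation:
    def test_no_covariates_equals_pearson(self):
        rng = np.random.default_rng(10)
        x, y = rng.normal(0, 1, 30), rng.normal(0, 1, 30)
        res = partial_correlation(x, y)
        ref_r, ref_p = sps.pearsonr(x, y)
        assert res.effect_size == pytest.approx(ref_r)
        assert res.p == pytest.approx(ref_p)

    def test_matches_pingouin(self):
        import pingouin as pg

        rng = np.random.default_rng(11)
        n = 40
        c = rng.normal(0, 1, (n, 2))
        x = c @ [0.5, -0.3] + rng.normal(0, 1, n)
        y = c @ [0.2, 0.4] + 0.5 * x + rng.normal(0, 1, n)
        res = partial_correlation(x, y, c)
        ref = pg.partial_corr(
            data=pd.DataFrame({"x": x, "y": y, "c1": c[:, 0], "c2": c[:, 1]}),
            x="x", y="y", covar=["c1", "c2"],
        )
        assert res.effect_size == pytest.approx(float(ref["r"].iloc[0]), abs=1e-10)
        assert res.p == pytest.approx(float(ref["p_val"].iloc[0]), abs=1e-10)

    def test_covariate_copy_residualized_to_zero(self):
        rng = np.random.default_rng(12)
        c = rng.normal(0, 1, 50)
        x = rng.normal(0, 1, 50)
        res = partial_correlation(x, c.copy(), c)
        assert abs(res.effect_size) < 1e-8

    def test_affine_transform_of_covariates_invariant(self):
        rng = np.random.default_rng(13)
        n = 35
        c = rng.normal(0, 1, (n, 2))
        x, y = rng.normal(0, 1, n), rng.normal(0, 1, n)
        a = partial_correlation(x, y, c)
        b = partial_correlation(x, y, c * [3.0, -0.5] + [10.0, -2.0])
        assert a.effect_size == pytest.approx(b.effect_size)

    def test_too_few_observations_rejected(self):
        with pytest.raises(ValueError, match="n > k"):
            partial_correlation(np.arange(4.0), np.arange(4.0), np.ones((4, 2)))


class TestFdrBH:
    def test_closed_form_example(self):
        np.testing.assert_allclose(fdr_bh([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03])

    def test_single_p_unchanged(self):
        assert fdr_bh([0.04])[0] == pytest.approx(0.04)

    def test_adjusted_at_least_raw_and_order_preserving(self):
        rng = np.random.default_rng(14)
        p = rng.uniform(0, 1, 20)
        adj = fdr_bh(p)
        assert (adj >= p - 1e-12).all()
        assert (np.argsort(p) == np.argsort(adj, kind="stable")).all() or (
            np.diff(adj[np.argsort(p)]) >= -1e-12
        ).all()

    def test_flat_adjusted_vector_is_fixed_point(self):
        p = fdr_bh([0.01, 0.02, 0.03])
        np.testing.assert_allclose(fdr_bh(p), p)

    def test_clipped_at_one(self):
        assert (fdr_bh([0.5, 0.9, 0.99, 1.0]) <= 1.0).all()


class TestGamesHowell:
    def test_equal_groups_all_near_one(self):
        rng = np.random.default_rng(15)
        groups = [rng.normal(0, 1, 30) for _ in range(3)]
        results = games_howell(groups)
        assert len(results) == 3
        assert all(r.p > 0.2 for r in results)

    def test_shifted_group_detected(self):
        rng = np.random.default_rng(16)
        groups = [rng.normal(0, 1, 60), rng.normal(0, 3, 60), rng.normal(2, 1, 60)]
        results = games_howell(groups, labels=["a", "b", "c"])
        pmap = {(r.extra["A"], r.extra["B"]): r.p for r in results}
        assert pmap[("a", "c")] < 0.01

    def test_two_group_case_close_to_welch_t(self):
        rng = np.random.default_rng(17)
        a, b = rng.normal(0, 1, 40), rng.normal(0.8, 2, 25)
        res = games_howell([a, b])[0]
        ref = sps.ttest_ind(a, b, equal_var=False)
        assert abs(res.statistic) == pytest.approx(abs(ref.statistic), rel=1e-6)
        # studentized range with k=2 maps exactly onto |t| via q = sqrt(2)|t|
        assert res.p == pytest.approx(ref.pvalue, abs=1e-6)


def _balanced_two_time_cohort(seed=18, n_per_group=20, effect=0.0):
    rng = np.random.default_rng(seed)
    rows = []
    for gi, group in enumerate(("CG", "TG")):
        for i in range(n_per_group):
            subject = f"{group}{i}"
            u = rng.normal(0, 0.6)
            for ti, time in enumerate(("W7", "M6")):
                y = u + 0.3 * gi + 0.2 * ti + effect * gi * ti + rng.normal(0, 1)
                rows.append(
                    {"subject": subject, "group": group, "time": time, "y": y}
                )
    return pd.DataFrame(rows)


class TestGroupTimeLMM:
    def test_balanced_interaction_equals_difference_score_anova(self):
        # with two complete timepoints the interaction F of the mixed model
        # is exactly the between-group ANOVA F on within-subject changes
        data = _balanced_two_time_cohort(effect=0.6)
        m = fit_group_time_lmm(data, "y")
        wide = data.pivot(index=["subject", "group"], columns="time", values="y")
        diff = (wide["M6"] - wide["W7"]).reset_index()
        groups = [diff.loc[diff.group == g, 0].to_numpy() for g in ("CG", "TG")]
        ref = one_way_anova(groups)
        assert m.tests["group:time"].statistic == pytest.approx(ref.statistic, rel=1e-6)
        assert m.tests["group:time"].df[1] == pytest.approx(ref.df[1], rel=1e-4)
        assert m.tests["group:time"].p == pytest.approx(ref.p, rel=1e-4)

    def test_balanced_group_effect_equals_subject_mean_anova(self):
        data = _balanced_two_time_cohort(effect=0.0)
        m = fit_group_time_lmm(data, "y")
        wide = data.pivot(index=["subject", "group"], columns="time", values="y")
        means = wide.mean(axis=1).reset_index()
        groups = [means.loc[means.group == g, 0].to_numpy() for g in ("CG", "TG")]
        ref = one_way_anova(groups)
        assert m.tests["group"].statistic == pytest.approx(ref.statistic, rel=1e-6)
        assert m.tests["group"].df[1] == pytest.approx(ref.df[1], rel=1e-4)

    def test_variance_components_match_statsmodels_mixedlm(self):
        import statsmodels.formula.api as smf

        data = _balanced_two_time_cohort(seed=19, effect=0.4)
        # drop some sessions to exercise the unbalanced path
        data = data.drop(index=data.index[[3, 11, 30]]).reset_index(drop=True)
        m = fit_group_time_lmm(data, "y")
        ref = smf.mixedlm(
            "y ~ C(group, Sum) * C(time, Sum)", data, groups=data["subject"]
        ).fit(reml=True)
        assert m.tau2 == pytest.approx(float(ref.cov_re.iloc[0, 0]), rel=1e-3, abs=1e-5)
        assert m.sigma2 == pytest.approx(float(ref.scale), rel=1e-3)
        names = ref.fe_params.index
        inter = [n for n in names if ":" in n][0]
        # sum-coding sign conventions may differ; the magnitude must agree
        assert abs(m.fe_params.iloc[3]) == pytest.approx(
            abs(float(ref.fe_params[inter])), rel=1e-3, abs=1e-6
        )

    def test_attrition_tolerated(self):
        data = _balanced_two_time_cohort(seed=20)
        data = data.drop(index=data.index[-5:])
        m = fit_group_time_lmm(data, "y")
        assert isinstance(m, MixedModelResult)
        assert m.df_method == "satterthwaite"
        assert m.n_obs == len(data)

    def test_constant_outcome_rejected(self):
        data = _balanced_two_time_cohort()
        data["y"] = 1.0
        with pytest.raises(ValueError, match="constant"):
            fit_group_time_lmm(data, "y")

    def test_empty_cell_rejected(self):
        data = _balanced_two_time_cohort()
        data = data[~((data.group == "TG") & (data.time == "M6"))]
        with pytest.raises(ValueError, match="empty group-by-time cell"):
            fit_group_time_lmm(data, "y")

    def test_covariates_enter_fixed_effects(self):
        rng = np.random.default_rng(21)
        data = _balanced_two_time_cohort(seed=22)
        data["age"] = rng.normal(65, 7, len(data))
        m = fit_group_time_lmm(data, "y", ["age"])
        assert "age" in m.fe_params.index
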