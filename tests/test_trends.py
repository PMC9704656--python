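import numpy as np
import pandas as pd
import pytest
from statsmodels.formula.api import ols
from statsmodels.stats.anova import anova_lm

from marshflood import (
    EstimationError,
    LinearTrend,
    PorewaterSample,
    RateOnRateRegression,
    ZoneMixedModel,
    fit_linear_trend,
    fit_zone_mixed_model,
    monthly_anomaly,
    monthly_plot_means,
    nakagawa_r2,
    plot_trends,
    rate_grid,
    rates_vs_inundation,
)
from marshflood.trends import TrendResult


def normal_equations(x, y):
    """Closed-form (XᵀX)⁻¹Xᵀy oracle for simple regression."""
    X = np.column_stack([np.ones_like(x), x])
    beta = np.linalg.solve(X.T @ X, X.T @ y)
    return beta[1], beta[0]


class TestLinearTrend:
    def test_exact_line_recovered(self):
        x = np.arange(2009, 2020, dtype=float)
        y = 2.0 * x + 1.0
        tr = fit_linear_trend(x, y)
        assert tr.slope == pytest.approx(2.0, abs=1e-10)
        assert tr.intercept == pytest.approx(1.0, abs=1e-6)
        assert tr.r_squared == pytest.approx(1.0)
        assert tr.p_value < 1e-12
        assert tr.significant

    def test_matches_normal_equations_oracle(self):
        rng = np.random.default_rng(0)
        for _ in range(30):
            n = int(rng.integers(5, 40))
            x = rng.uniform(-8.0, 8.0, n)
            y = rng.normal(0, 5, n)
            slope, intercept = normal_equations(x, y)
            tr = fit_linear_trend(x, y)
            assert tr.slope == pytest.approx(slope, abs=1e-10)
            assert tr.intercept == pytest.approx(intercept, abs=1e-10)

    def test_constant_response_convention(self):
        tr = fit_linear_trend([1.0, 2.0, 3.0, 4.0], [5.0, 5.0, 5.0, 5.0])
        assert tr.slope == 0.0
        assert tr.r_squared == 0.0
        assert tr.p_value == 1.0
        assert not tr.significant

    def test_too_few_points_and_degenerate_x_error(self):
        with pytest.raises(EstimationError, match=">= 3"):
            fit_linear_trend([1.0, 2.0], [1.0, 2.0])
        with pytest.raises(EstimationError, match="degenerate"):
            fit_linear_trend([2.0, 2.0, 2.0], [1.0, 2.0, 3.0])

    def test_missing_values_dropped_pairwise(self):
        tr = fit_linear_trend([1, 2, 3, 4, 5], [1, 2, np.nan, 4, 5])
        assert tr.n == 4
        assert tr.slope == pytest.approx(1.0)

    def test_estimator_api_and_unbiasedness(self):
        """Slope estimator is unbiased on linear + Gaussian data (3 SE)."""
        rng = np.random.default_rng(7)
        x = np.repeat(np.arange(2009, 2020, dtype=float), 4)
        slopes = [
            LinearTrend().fit(x, 1.3 * x + rng.normal(0, 5, x.size)).slope_
            for _ in range(200)
        ]
        arr = np.asarray(slopes)
        se = arr.std(ddof=1) / np.sqrt(arr.size)
        assert abs(arr.mean() - 1.3) < 3 * se
        est = LinearTrend(alpha=0.01)
        assert est.get_params() == {"alpha": 0.01}
        est.fit(x, 2 * x)
        np.testing.assert_allclose(est.predict([2010.0]), [4020.0])


class TestMonthlyMeans:
    def test_triplicate_mean(self):
        samples = [
            PorewaterSample("p", 2009, 5, r, nh4=v, po4=1.0, salinity=30.0)
            for r, v in [(1, 1.0), (2, 2.0), (3, 3.0)]
        ]
        m = monthly_plot_means(samples)
        assert len(m) == 1
        assert m.loc[0, "nh4"] == 2.0

    def test_missing_replicate_tolerated(self):
        samples = [
            PorewaterSample("p", 2009, 5, 1, nh4=1.0),
            PorewaterSample("p", 2009, 5, 2, nh4=3.0),
            PorewaterSample("p", 2009, 5, 3, nh4=np.nan),
        ]
        m = monthly_plot_means(samples)
        assert m.loc[0, "nh4"] == 2.0

    def test_full_plot_yields_44_monthly_means(self):
        samples = [
            PorewaterSample("p", y, mo, r, nh4=1.0, po4=1.0, salinity=1.0)
            for y in range(2009, 2020)
            for mo in (5, 6, 7, 8)
            for r in (1, 2, 3)
        ]
        assert len(monthly_plot_means(samples)) == 44


class TestRateGrid:
    def _trends(self, plots, pvals):
        return [
            TrendResult(p.plot_id, "nh4", slope=float(i), intercept=0.0, slope_se=1.0,
                        t_stat=1.0, p_value=pvals[i], r_squared=0.5, n=44, alpha=0.05)
            for i, p in enumerate(plots)
        ]

    def test_values_equal_slopes_and_masking_only_hides(self, default_plots):
        trends = self._trends(default_plots, [0.01] * len(default_plots))
        grids = rate_grid(trends, default_plots, alpha=0.05)
        assert {g.segment for g in grids} == {"A", "B"}
        slope_of = {t.plot_id: t.slope for t in trends}
        for g in grids:
            assert not g.masked.to_numpy().any()
            for p in default_plots:
                if p.segment == g.segment:
                    assert g.values.loc[p.transect, p.position_index] == slope_of[p.plot_id]

    def test_non_significant_cells_masked_but_value_kept(self, default_plots):
        pvals = [0.2 if i % 2 else 0.001 for i in range(len(default_plots))]
        trends = self._trends(default_plots, pvals)
        grids = rate_grid(trends, default_plots, alpha=0.05)
        n_masked = sum(int(g.masked.to_numpy()[~np.isnan(g.values.to_numpy())].sum())
                       for g in grids)
        assert n_masked == sum(p >= 0.05 for p in pvals)
        # masking never alters values
        for g in grids:
            assert np.nanmax(np.abs(g.values.to_numpy())) > 0

    def test_plot_without_trend_is_structural_error(self, default_plots):
        trends = self._trends(default_plots[:-1], [0.01] * 50)
        with pytest.raises(EstimationError, match="no trend result"):
            rate_grid(trends, default_plots)


class TestZoneMixedModel:
    @staticmethod
    def _two_zone_frame(n_reps=10, sd=0.3, seed=0, months=(5, 6, 7, 8)):
        rng = np.random.default_rng(seed)
        rows = []
        for zone, base in (("low", 4.0), ("high", 2.0)):
            for year in (2009, 2019):
                for month in months:
                    for rep in range(n_reps):
                        mu = base + (0.5 if year == 2019 else 0.0) \
                            + (0.3 if zone == "low" and year == 2019 else 0.0)
                        rows.append(dict(
                            plot_id=f"{zone}{rep}", zone=zone, year=year, month=month,
                            nh4=float(np.exp(mu + rng.normal(0, sd))),
                        ))
        return pd.DataFrame(rows)

    def test_fixed_effects_limit_matches_anova_oracle(self):
        """With one month per year the random variances sit at 0 and the
        sequential F statistics equal the two-way fixed-effects ANOVA."""
        df = self._two_zone_frame(n_reps=12, months=(6,))
        est = ZoneMixedModel("nh4").fit(df)
        df["logy"] = np.log(df["nh4"])
        oracle = anova_lm(ols("logy ~ C(zone) * C(year)", data=df).fit(), typ=1)
        for term, row_name in [("zone", "C(zone)"), ("year", "C(year)"),
                               ("zone:year", "C(zone):C(year)")]:
            mine = est.anova_.set_index("term").loc[term, "F"]
            ref = oracle.loc[row_name, "F"]
            assert mine == pytest.approx(ref, rel=1e-3)

    def test_nakagawa_formula_cases(self):
        marg, cond = nakagawa_r2(2.0, [1.0], 1.0)
        assert marg == 0.5
        assert cond == 0.75
        marg, cond = nakagawa_r2(0.0, [0.0], 1.0)
        assert marg == 0.0 and cond == 0.0

    def test_marginal_never_exceeds_conditional(self):
        df = self._two_zone_frame(seed=3)
        est = ZoneMixedModel("nh4").fit(df)
        assert 0.0 <= est.marginal_r2_ <= est.conditional_r2_ <= 1.0
        assert all(v >= 0 for v in est.variance_components_.values())

    def test_term_structure_and_dfs(self, default_plots):
        rng = np.random.default_rng(1)
        rows = []
        for p in default_plots:
            for year in (2009, 2019):
                for month in (5, 6, 7, 8):
                    rows.append(dict(
                        plot_id=p.plot_id, year=year, month=month,
                        nh4=float(rng.lognormal(3, 0.5)), po4=float(rng.lognormal(1, 0.5)),
                        salinity=30.0,
                    ))
        monthly = pd.DataFrame(rows)
        res_a = fit_zone_mixed_model(monthly, default_plots, "A", "nh4")
        res_b = fit_zone_mixed_model(monthly, default_plots, "B", "nh4")
        a = res_a.anova.set_index("term")
        b = res_b.anova.set_index("term")
        assert list(a.index) == ["zone", "year", "zone:year"]
        assert a.loc["zone", "num_df"] == 2  # three zones at segment A
        assert b.loc["zone", "num_df"] == 1  # two zones at segment B
        assert a.loc["year", "den_df"] == 6  # 8 year:month groups - 2 years
        assert res_a.n_obs == 27 * 8

    def test_nonpositive_concentration_is_hard_error(self):
        df = self._two_zone_frame()
        df.loc[3, "nh4"] = 0.0
        with pytest.raises(EstimationError, match="log transform"):
            ZoneMixedModel("nh4").fit(df)

    def test_single_zone_segment_rejected(self):
        df = self._two_zone_frame()
        with pytest.raises(EstimationError, match="two zones"):
            ZoneMixedModel("nh4").fit(df[df.zone == "low"])


class TestRateRelation:
    def test_exact_proportionality(self):
        inund = [TrendResult(f"p{i}", "hours_inundated", slope=float(10 + i),
                             intercept=0, slope_se=1, t_stat=1, p_value=0.01,
                             r_squared=0.9, n=11, alpha=0.05) for i in range(6)]
        nut = [TrendResult(t.plot_id, "nh4", slope=0.02 * t.slope, intercept=0,
                           slope_se=1, t_stat=1, p_value=0.5, r_squared=0.1,
                           n=44, alpha=0.05) for t in inund]
        rel = rates_vs_inundation(nut, inund)
        assert rel.slope == pytest.approx(0.02, abs=1e-12)
        assert rel.r_squared == pytest.approx(1.0)
        assert rel.n_plots == 6

    def test_matches_normal_equations_oracle(self):
        rng = np.random.default_rng(5)
        x = rng.normal(50, 20, 6)
        y = rng.normal(5, 2, 6)
        mk = lambda pid, var, s: TrendResult(pid, var, slope=float(s), intercept=0,
                                             slope_se=1, t_stat=1, p_value=0.5,
                                             r_squared=0.1, n=11, alpha=0.05)
        inund = [mk(f"p{i}", "hours_inundated", x[i]) for i in range(6)]
        nut = [mk(f"p{i}", "po4", y[i]) for i in range(6)]
        rel = rates_vs_inundation(nut, inund)
        slope, intercept = normal_equations(x, y)
        assert rel.slope == pytest.approx(slope, abs=1e-10)
        assert rel.intercept == pytest.approx(intercept, abs=1e-10)

    def test_non_significant_slopes_are_included(self):
        # all nutrient p-values above alpha; the relation still uses them all
        mk = lambda pid, var, s, p: TrendResult(pid, var, slope=s, intercept=0,
                                                slope_se=1, t_stat=1, p_value=p,
                                                r_squared=0.1, n=11, alpha=0.05)
        inund = [mk(f"p{i}", "h", float(i), 0.01) for i in range(5)]
        nut = [mk(f"p{i}", "nh4", float(i), 0.99) for i in range(5)]
        assert rates_vs_inundation(nut, inund).n_plots == 5

    def test_mismatched_plot_sets_error(self):
        mk = lambda pid: TrendResult(pid, "nh4", 1, 0, 1, 1, 0.5, 0.1, 11, 0.05)
        with pytest.raises(EstimationError, match="mismatched"):
            rates_vs_inundation([mk("a"), mk("b"), mk("c")],
                                [mk("a"), mk("b"), mk("d")])

    def test_sklearn_estimator_surface(self):
        est = RateOnRateRegression().fit([0.0, 1.0, 2.0, 3.0], [1.0, 3.0, 5.0, 7.0])
        assert est.slope_ == pytest.approx(2.0)
        np.testing.assert_allclose(est.predict([4.0]), [9.0])


class TestMonthlyAnomaly:
    @staticmethod
    def _series(values, start="2010-01-01"):
        idx = pd.date_range(start, periods=len(values), freq="MS")
        return pd.Series(np.asarray(values, dtype=float), index=idx)

    def test_series_equal_to_climatology_gives_zero_anomalies(self):
        cycle = np.tile(np.arange(12, dtype=float), 4)
        anom, trend = monthly_anomaly(self._series(cycle))
        np.testing.assert_allclose(anom.to_numpy(), 0.0, atol=1e-12)
        assert trend.slope == 0.0

    def test_climatology_matches_per_month_mean_oracle(self):
        rng = np.random.default_rng(2)
        vals = rng.normal(10, 2, 60)
        series = self._series(vals)
        anom, _ = monthly_anomaly(series)
        for month in range(1, 13):
            sel = series.index.month == month
            oracle = series[sel] - series[sel].mean()
            np.testing.assert_allclose(anom[sel].to_numpy(), oracle.to_numpy(),
                                       atol=1e-12)

    def test_white_noise_type_i_error_near_alpha(self):
        rng = np.random.default_rng(11)
        rejections = sum(
            monthly_anomaly(self._series(rng.normal(0, 1, 48)))[1].significant
            for _ in range(400)
        )
        rate = rejections / 400
        assert abs(rate - 0.05) < 3 * np.sqrt(0.05 * 0.95 / 400) + 0.005

    def test_too_short_series_rejected(self):
        with pytest.raises(ValueError, match="24"):
            monthly_anomaly(self._series(np.ones(12)))
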