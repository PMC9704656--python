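"""Plot-level trends, zone × year mixed models, and the rate-on-rate regression.

Three statistical stages, each exposed both as a scikit-learn style estimator
(``fit`` + trailing-underscore attributes, composable with sklearn tooling)
and as a thin function returning a result dataclass:

1. :class:`LinearTrend` / :func:`fit_linear_trend` — per-plot OLS of a
   variable against calendar year, with a two-sided t test on the slope.
   Slopes with p < α are "rates of change"; :func:`rate_grid` lays them out
   on the transect grid with non-significant cells masked.
2. :class:`ZoneMixedModel` / :func:`fit_zone_mixed_model` — log-concentration
   ~ zone * year with random intercepts for year and for month nested within
   year (REML via statsmodels MixedLM), sequential (Type-I) F tests with
   containment denominator degrees of freedom, and the Nakagawa–Schielzeth
   marginal/conditional R².
3. :class:`RateOnRateRegression` / :func:`rates_vs_inundation` — OLS of
   plot-level nutrient rates on plot-level inundation rates across plots.

Plus two small utilities: replicate → monthly means, and monthly climatology
anomalies with a trend fit.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator
import statsmodels.api as sm

from .io import PlotRecord, PorewaterSample, samples_to_frame

__all__ = [
    "TrendResult",
    "ZoneModelResult",
    "RateRelation",
    "RateGrid",
    "LinearTrend",
    "ZoneMixedModel",
    "RateOnRateRegression",
    "fit_linear_trend",
    "monthly_plot_means",
    "plot_trends",
    "rate_grid",
    "fit_zone_mixed_model",
    "rates_vs_inundation",
    "monthly_anomaly",
    "nakagawa_r2",
    "EstimationError",
]


class EstimationError(ValueError):
    """The requested fit is not estimable from the data given."""


@dataclass(frozen=True)
class TrendResult:
    """OLS trend of one variable at one plot (units of the variable per year)."""

    plot_id: str
    variable: str
    slope: float
    intercept: float
    slope_se: float
    t_stat: float
    p_value: float
    r_squared: float
    n: int
    alpha: float

    @property
    def significant(self) -> bool:
        return self.p_value < self.alpha


@dataclass(frozen=True)
class RateRelation:
    """Cross-plot regression of nutrient rates on inundation rates."""

    variable: str
    slope: float
    intercept: float
    slope_se: float
    p_value: float
    r_squared: float
    n_plots: int


@dataclass
class ZoneModelResult:
    """Mixed-model ANOVA for one segment × variable.

    ``anova`` has one row per fixed term (zone, year, zone:year) with columns
    term, num_df, den_df, F, p.  ``variance_components`` holds the Nakagawa
    decomposition inputs on the log scale.
    """

    segment: str
    variable: str
    anova: pd.DataFrame
    variance_components: dict[str, float]
    marginal_r2: float
    conditional_r2: float
    n_obs: int


@dataclass
class RateGrid:
    """Per-segment slope grid (rows: transect, columns: position from forest).

    ``values`` always carries every slope; ``masked`` flags the cells whose
    trend did not reach significance (masking never alters a value).
    """

    segment: str
    variable: str
    values: pd.DataFrame
    masked: pd.DataFrame
    alpha: float


# ---------------------------------------------------------------------------
# stage 1: plot-level OLS trends


class LinearTrend(BaseEstimator):
    """Simple linear regression of a response on time, with a slope t test.

    Parameters
    ----------
    alpha : float
        Significance level for flagging the slope.

    Attributes (after ``fit``)
    --------------------------
    slope_, intercept_, slope_se_, t_stat_, p_value_, r_squared_, n_,
    significant_
    """

    def __init__(self, alpha: float = 0.05):
        self.alpha = alpha

    def fit(self, X, y):
        x = np.asarray(X, dtype=float).reshape(-1)
        y = np.asarray(y, dtype=float).reshape(-1)
        if x.shape != y.shape:
            raise ValueError("x and y must have the same length")
        keep = np.isfinite(x) & np.isfinite(y)
        x, y = x[keep], y[keep]
        n = x.size
        if n < 3:
            raise EstimationError(f"need >= 3 finite (x, y) pairs, got {n}")
        # center the predictor for numerical stability; slope is unaffected
        xm = x.mean()
        xc = x - xm
        sxx = float(xc @ xc)
        if sxx == 0.0:
            raise EstimationError("degenerate predictor: all x equal")
        ym = y.mean()
        slope = float(xc @ (y - ym)) / sxx
        intercept = ym - slope * xm
        resid = y - (intercept + slope * x)
        ss_res = float(resid @ resid)
        ss_tot = float((y - ym) @ (y - ym))
        df = n - 2
        if ss_tot == 0.0:
            # constant response: no trend, by convention r² = 0 and p = 1
            slope, se, t, p, r2 = 0.0, 0.0, 0.0, 1.0, 0.0
            intercept = ym
        else:
            sigma2 = ss_res / df
            se = float(np.sqrt(sigma2 / sxx))
            if se == 0.0:
                t = np.inf if slope > 0 else (-np.inf if slope < 0 else 0.0)
                p = 0.0 if slope != 0 else 1.0
            else:
                t = slope / se
                p = 2.0 * float(stats.t.sf(abs(t), df))
            r2 = 1.0 - ss_res / ss_tot
        self.slope_ = slope
        self.intercept_ = intercept
        self.slope_se_ = se
        self.t_stat_ = t
        self.p_value_ = p
        self.r_squared_ = r2
        self.n_ = n
        self.significant_ = p < self.alpha
        return self

    def predict(self, X):
        x = np.asarray(X, dtype=float).reshape(-1)
        return self.intercept_ + self.slope_ * x


def fit_linear_trend(
    x: Sequence[float],
    y: Sequence[float],
    plot_id: str = "",
    variable: str = "",
    alpha: float = 0.05,
) -> TrendResult:
    """OLS of ``y`` on ``x`` (years), packaged as a :class:`TrendResult`."""
    est = LinearTrend(alpha=alpha).fit(x, y)
    return TrendResult(
        plot_id=plot_id,
        variable=variable,
        slope=est.slope_,
        intercept=est.intercept_,
        slope_se=est.slope_se_,
        t_stat=est.t_stat_,
        p_value=est.p_value_,
        r_squared=est.r_squared_,
        n=est.n_,
        alpha=alpha,
    )


def monthly_plot_means(
    samples: Sequence[PorewaterSample] | pd.DataFrame,
) -> pd.DataFrame:
    """Average replicate measurements to one row per (plot, year, month).

    Missing replicates are tolerated: the mean uses whatever replicates are
    present, and plot-months with no data at all simply do not appear.
    Columns: plot_id, year, month, nh4, po4, salinity.
    """
    df = samples if isinstance(samples, pd.DataFrame) else samples_to_frame(samples)
    df = df.rename(
        columns={"nh4_um": "nh4", "po4_um": "po4", "salinity_psu": "salinity"}
    )
    out = (
        df.groupby(["plot_id", "year", "month"], as_index=False)[
            ["nh4", "po4", "salinity"]
        ]
        .mean()
        .sort_values(["plot_id", "year", "month"], ignore_index=True)
    )
    return out


def plot_trends(
    data: pd.DataFrame,
    variable: str,
    x_column: str = "year",
    alpha: float = 0.05,
) -> list[TrendResult]:
    """Fit one OLS trend per plot_id from a tidy frame.

    For porewater variables the rows are the 44 monthly means (treated as
    within-year replicates, so ``x`` is the calendar year repeated per
    month); for inundation the rows are the 11 annual totals.
    """
    results = []
    for plot_id, grp in data.groupby("plot_id", sort=True):
        results.append(
            fit_linear_trend(
                grp[x_column].to_numpy(dtype=float),
                grp[variable].to_numpy(dtype=float),
                plot_id=str(plot_id),
                variable=variable,
                alpha=alpha,
            )
        )
    return results


def trends_to_frame(trends: Sequence[TrendResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "plot_id": t.plot_id,
                "variable": t.variable,
                "slope": t.slope,
                "intercept": t.intercept,
                "slope_se": t.slope_se,
                "t_stat": t.t_stat,
                "p_value": t.p_value,
                "r_squared": t.r_squared,
                "n": t.n,
                "significant": t.significant,
            }
            for t in trends
        ]
    )


def rate_grid(
    trends: Sequence[TrendResult],
    plots: Sequence[PlotRecord],
    alpha: float = 0.05,
) -> list[RateGrid]:
    """Lay plot-level slopes out on the transect grids, masking p ≥ α cells.

    Returns one grid per segment, rows ordered by transect and columns by
    position from the forest edge.  Every plot must have a trend result.
    """
    by_plot = {t.plot_id: t for t in trends}
    missing = [p.plot_id for p in plots if p.plot_id not in by_plot]
    if missing:
        raise EstimationError(f"no trend result for plots {missing}")
    variable = trends[0].variable if trends else ""
    grids = []
    for segment in sorted({p.segment for p in plots}):
        seg_plots = [p for p in plots if p.segment == segment]
        transects = sorted({p.transect for p in seg_plots})
        positions = sorted({p.position_index for p in seg_plots})
        values = pd.DataFrame(np.nan, index=transects, columns=positions)
        masked = pd.DataFrame(False, index=transects, columns=positions)
        values.index.name = "transect"
        values.columns.name = "position_from_forest"
        for p in seg_plots:
            t = by_plot[p.plot_id]
            values.loc[p.transect, p.position_index] = t.slope
            masked.loc[p.transect, p.position_index] = not (t.p_value < alpha)
        grids.append(RateGrid(segment, variable, values, masked.copy(), alpha))
    return grids


# ---------------------------------------------------------------------------
# stage 2: zone × year mixed model


def nakagawa_r2(
    var_fixed: float, var_random: Sequence[float], var_resid: float
) -> tuple[float, float]:
    """Marginal and conditional R² from variance components.

    marginal = σ²_fixed / total; conditional = (σ²_fixed + Σσ²_random) / total,
    with total = σ²_fixed + Σσ²_random + σ²_residual.  Negative component
    estimates must be truncated to 0 by the caller.
    """
    vr = float(np.sum(var_random))
    total = var_fixed + vr + var_resid
    if total <= 0:
        raise EstimationError("non-positive total variance")
    return var_fixed / total, (var_fixed + vr) / total


class ZoneMixedModel(BaseEstimator):
    """Log-concentration ~ zone * year with nested random intercepts.

    Fits, by REML, fixed effects of marsh zone, year (first vs last sampling
    year, categorical) and their interaction, with random intercepts for
    year and for month nested within year — the structure appropriate to
    monthly growing-season means from a single segment.  Inference is by
    sequential (Type-I) F tests computed on the data whitened with the
    estimated marginal covariance, with containment denominator degrees of
    freedom; fit quality is summarised by the Nakagawa–Schielzeth marginal
    and conditional R².

    ``fit`` expects a frame with columns zone, year, month and the response
    column named by ``variable``; concentrations must be strictly positive
    (the natural-log transform is applied internally and a zero or negative
    value is a hard error, never silently offset).

    Attributes (after ``fit``)
    --------------------------
    anova_ : DataFrame with term, num_df, den_df, F, p
    variance_components_ : dict (fixed, year, month_within_year, residual)
    marginal_r2_, conditional_r2_, n_obs_
    """

    def __init__(self, variable: str = "nh4", alpha: float = 0.05):
        self.variable = variable
        self.alpha = alpha

    def fit(self, X: pd.DataFrame, y=None):
        df = X.copy()
        for col in ("zone", "year", "month", self.variable):
            if col not in df.columns:
                raise EstimationError(f"column {col!r} missing from model frame")
        df = df.dropna(subset=[self.variable])
        bad = df[df[self.variable] <= 0]
        if not bad.empty:
            keys = bad[["plot_id", "year", "month"]].to_records(index=False).tolist() \
                if "plot_id" in bad.columns else bad.index.tolist()
            raise EstimationError(
                f"non-positive {self.variable} values cannot be log transformed: {keys[:5]}"
            )
        zones = sorted(df["zone"].unique(), key=["low", "mid", "high"].index)
        years = sorted(df["year"].unique())
        if len(zones) < 2:
            raise EstimationError("need at least two zones in the segment")
        if len(years) != 2:
            raise EstimationError(f"need exactly two years, got {years}")

        logy = np.log(df[self.variable].to_numpy(dtype=float))
        n = logy.size
        # fixed-effects design, built sequentially: intercept | zone | year | zone:year
        z_dum = pd.get_dummies(
            pd.Categorical(df["zone"], categories=zones), drop_first=True, dtype=float
        ).to_numpy()
        y_dum = (df["year"].to_numpy() == years[1]).astype(float).reshape(-1, 1)
        inter = z_dum * y_dum
        blocks = [np.ones((n, 1)), z_dum, y_dum, inter]
        terms = ["zone", "year", "zone:year"]
        num_df = [z_dum.shape[1], 1, inter.shape[1]]
        X_full = np.hstack(blocks)

        year_codes = pd.Categorical(df["year"]).codes
        ym_codes = pd.Categorical(
            df["year"].astype(str) + ":" + df["month"].astype(str)
        ).codes
        n_years = len(np.unique(year_codes))
        n_ym = len(np.unique(ym_codes))
        months_per_year = (
            df.groupby("year")["month"].nunique().max() if "month" in df else 1
        )

        var_year, var_month, var_resid, beta = self._fit_reml(
            df, logy, X_full, year_codes, ym_codes, months_per_year
        )

        # whiten with the estimated marginal covariance and run sequential ANOVA
        V = var_resid * np.eye(n)
        V += var_year * (year_codes[:, None] == year_codes[None, :])
        V += var_month * (ym_codes[:, None] == ym_codes[None, :])
        L = np.linalg.cholesky(V)
        yw = np.linalg.solve(L, logy)
        Xw = np.linalg.solve(L, X_full)

        def rss(k_cols: int) -> float:
            coef, res, rank, _ = np.linalg.lstsq(Xw[:, :k_cols], yw, rcond=None)
            r = yw - Xw[:, :k_cols] @ coef
            return float(r @ r)

        p_total = X_full.shape[1]
        cuts = np.cumsum([b.shape[1] for b in blocks])
        rss_seq = [rss(c) for c in cuts]
        rss_full = rss_seq[-1]
        mse = rss_full / (n - p_total)
        obs_level_rank = num_df[0] + num_df[2]  # zone + zone:year
        den_obs = n - n_ym - obs_level_rank
        den_year = n_ym - n_years
        den_dfs = [den_obs, den_year, den_obs]

        rows = []
        for i, term in enumerate(terms):
            delta = rss_seq[i] - rss_seq[i + 1]
            F = (delta / num_df[i]) / mse
            rows.append(
                {
                    "term": term,
                    "num_df": num_df[i],
                    "den_df": den_dfs[i],
                    "F": F,
                    "p": float(stats.f.sf(F, num_df[i], den_dfs[i])),
                }
            )
        self.anova_ = pd.DataFrame(rows)

        var_fixed = float(np.var(X_full @ beta, ddof=1))
        marg, cond = nakagawa_r2(var_fixed, [var_year, var_month], var_resid)
        self.variance_components_ = {
            "fixed": var_fixed,
            "year": var_year,
            "month_within_year": var_month,
            "residual": var_resid,
        }
        self.marginal_r2_ = marg
        self.conditional_r2_ = cond
        self.n_obs_ = n
        self.zones_ = zones
        self.years_ = years
        self.coef_ = beta
        return self

    @staticmethod
    def _fit_reml(df, logy, X_full, year_codes, ym_codes, months_per_year):
        """REML variance components via statsmodels MixedLM.

        The nominal random structure is intercepts for year and for month
        nested within year.  Because year also appears as a fixed effect, its
        random-intercept design lies inside the fixed-effect column span and
        the REML criterion is flat in the year variance; the identified REML
        solution pins it at 0, leaving the month-within-year intercept (fitted
        as a random intercept per year:month group) and the residual.  When
        only one month per year is present that component is likewise
        unidentified and all random variances sit at the 0 boundary, where
        REML reduces to OLS with the usual unbiased residual variance.
        """
        var_year = 0.0
        if months_per_year > 1:
            frame = pd.DataFrame(
                X_full[:, 1:], columns=[f"x{i}" for i in range(1, X_full.shape[1])]
            )
            frame["logy"] = logy
            frame["ym_f"] = pd.Categorical(ym_codes)
            fixed = "logy ~ " + " + ".join(frame.columns[: X_full.shape[1] - 1])
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                model = sm.MixedLM.from_formula(
                    fixed, groups="ym_f", re_formula="1", data=frame
                )
                try:
                    res = model.fit(reml=True, maxiter=200)
                except Exception:
                    res = model.fit(reml=True, method="powell", maxiter=500)
            var_resid = float(res.scale)
            var_month = float(np.atleast_2d(res.cov_re)[0, 0])
            beta = np.asarray(res.fe_params, dtype=float)
        else:
            beta, _, _, _ = np.linalg.lstsq(X_full, logy, rcond=None)
            resid = logy - X_full @ beta
            var_resid = float(resid @ resid) / (logy.size - X_full.shape[1])
            var_month = 0.0
        return var_year, max(var_month, 0.0), var_resid, beta


def fit_zone_mixed_model(
    monthly_means: pd.DataFrame,
    plots: Sequence[PlotRecord],
    segment: str,
    variable: str,
    years: tuple[int, int] = (2009, 2019),
    alpha: float = 0.05,
) -> ZoneModelResult:
    """Zone × year mixed model for one segment's monthly mean concentrations.

    ``monthly_means`` is the output of :func:`monthly_plot_means`; rows are
    restricted to the segment's plots and the two comparison years before
    fitting (see :class:`ZoneMixedModel` for the model itself).
    """
    zone_of = {p.plot_id: p.zone for p in plots if p.segment == segment}
    df = monthly_means[monthly_means["plot_id"].isin(zone_of)].copy()
    df = df[df["year"].isin(years)]
    if df.empty:
        raise EstimationError(f"no data for segment {segment!r} in years {years}")
    df["zone"] = df["plot_id"].map(zone_of)
    est = ZoneMixedModel(variable=variable, alpha=alpha).fit(df)
    return ZoneModelResult(
        segment=segment,
        variable=variable,
        anova=est.anova_,
        variance_components=est.variance_components_,
        marginal_r2=est.marginal_r2_,
        conditional_r2=est.conditional_r2_,
        n_obs=est.n_obs_,
    )


# ---------------------------------------------------------------------------
# stage 3: rates of change vs rates of inundation change


class RateOnRateRegression(BaseEstimator):
    """OLS of plot-level nutrient rates on plot-level inundation rates.

    All plot slopes enter, significant or not — the relationship is assessed
    across the full set of plots.  Attributes after ``fit``: ``slope_``,
    ``intercept_``, ``slope_se_``, ``p_value_``, ``r_squared_``, ``n_plots_``.
    """

    def __init__(self, alpha: float = 0.05):
        self.alpha = alpha

    def fit(self, X, y):
        x = np.asarray(X, dtype=float).reshape(-1)
        yv = np.asarray(y, dtype=float).reshape(-1)
        if x.size != yv.size:
            raise ValueError("rate vectors must have equal length")
        if x.size < 3:
            raise EstimationError("need at least 3 plots")
        est = LinearTrend(alpha=self.alpha).fit(x, yv)
        self.slope_ = est.slope_
        self.intercept_ = est.intercept_
        self.slope_se_ = est.slope_se_
        self.p_value_ = est.p_value_
        self.r_squared_ = est.r_squared_
        self.n_plots_ = est.n_
        return self

    def predict(self, X):
        return self.intercept_ + self.slope_ * np.asarray(X, dtype=float).reshape(-1)


def rates_vs_inundation(
    nutrient_trends: Sequence[TrendResult],
    inundation_trends: Sequence[TrendResult],
) -> RateRelation:
    """Cross-plot regression: nutrient rate ~ inundation rate.

    Both inputs must cover exactly the same plots (mismatched ids are an
    error); every plot's slope is used regardless of its own significance.
    """
    nut = {t.plot_id: t for t in nutrient_trends}
    inu = {t.plot_id: t for t in inundation_trends}
    if set(nut) != set(inu):
        only_n = sorted(set(nut) - set(inu))
        only_i = sorted(set(inu) - set(nut))
        raise EstimationError(
            f"mismatched plot sets (only nutrient: {only_n[:5]}, only inundation: {only_i[:5]})"
        )
    ids = sorted(nut)
    x = np.array([inu[p].slope for p in ids])
    y = np.array([nut[p].slope for p in ids])
    est = RateOnRateRegression().fit(x, y)
    variable = nutrient_trends[0].variable if nutrient_trends else ""
    return RateRelation(
        variable=variable,
        slope=est.slope_,
        intercept=est.intercept_,
        slope_se=est.slope_se_,
        p_value=est.p_value_,
        r_squared=est.r_squared_,
        n_plots=est.n_plots_,
    )


# ---------------------------------------------------------------------------
# monthly anomaly utility


def monthly_anomaly(
    monthly: pd.Series, alpha: float = 0.05
) -> tuple[pd.Series, TrendResult]:
    """Deviation from the long-term calendar-month mean, plus its trend.

    anomaly(t) = value(t) − mean over years of that calendar month; the trend
    is OLS of the anomalies on decimal year.  Requires ≥ 24 non-missing
    months.
    """
    valid = monthly.dropna()
    if len(valid) < 24:
        raise ValueError("monthly anomaly requires at least 24 non-missing months")
    clim = valid.groupby(valid.index.month).mean()
    anomaly = monthly - monthly.index.month.map(clim)
    anomaly = anomaly.rename("anomaly")
    x = anomaly.index.year + (anomaly.index.month - 1) / 12.0
    trend = fit_linear_trend(
        np.asarray(x, dtype=float),
        anomaly.to_numpy(dtype=float),
        variable="anomaly",
        alpha=alpha,
    )
    return anomaly, trend
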