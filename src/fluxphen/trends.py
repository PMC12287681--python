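"""Mann-Kendall trend tests, Theil-Sen slopes and their applications.

The rank-based Mann-Kendall test and the Theil-Sen median-of-pairwise-
slopes estimator are implemented from first principles (S statistic,
tie-corrected variance, continuity-corrected normal score).  On top of
them sit the multi-resolution analyses used for long flux records:
annual/seasonal trend tables, per-day-of-year trends of smoothed NEE with
a six-way sink/source classification, per-percentile trends, and Pettitt
change-point detection.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from fluxphen.flux_io import assign_season
from fluxphen.phenology import SmoothingSpec, moving_average

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class TrendResult:
    """Mann-Kendall test plus Theil-Sen slope for one series."""

    n: int
    s_statistic: int
    var_s: float
    z: float
    p_value: float
    tau: float
    sen_slope: float
    sen_intercept: float
    significant: bool
    alpha: float = 0.05


def mann_kendall(series, alpha: float = 0.05) -> TrendResult:
    """Mann-Kendall test for a monotonic trend, with Theil-Sen slope.

    S = sum over i<j of sign(x_j - x_i); Var(S) uses the tie correction
    [n(n-1)(2n+5) - sum_t t(t-1)(2t+5)] / 18 over tie groups of size t;
    the normal score z applies a +/-1 continuity correction; the p-value
    is two-sided.  tau = S / (n(n-1)/2).

    Missing values are removed (time points of the survivors keep their
    original spacing for the slope).
    """
    x = np.asarray(series, dtype=float)
    t_idx = np.arange(len(x), dtype=float)
    keep = np.isfinite(x)
    x, t_idx = x[keep], t_idx[keep]
    n = len(x)
    if n < 3:
        raise ValueError("mann_kendall requires n >= 3 non-missing values")

    diff = np.sign(x[np.newaxis, :] - x[:, np.newaxis])
    s = int(np.triu(diff, k=1).sum())

    _, counts = np.unique(x, return_counts=True)
    tie_term = float(np.sum(counts * (counts - 1) * (2 * counts + 5)))
    var_s = (n * (n - 1) * (2 * n + 5) - tie_term) / 18.0

    if var_s > 0 and s != 0:
        z = (s - np.sign(s)) / np.sqrt(var_s)
    else:
        z = 0.0
    p = 2.0 * stats.norm.sf(abs(z))
    tau = s / (n * (n - 1) / 2.0)

    slope, intercept = theil_sen(x, t_idx)
    return TrendResult(
        n=n, s_statistic=s, var_s=var_s, z=float(z), p_value=float(p),
        tau=float(tau), sen_slope=slope, sen_intercept=intercept,
        significant=bool(p < alpha), alpha=alpha,
    )


def theil_sen(series, time=None) -> tuple[float, float]:
    """Theil-Sen estimator: median pairwise slope and matching intercept.

    slope = median over i<j of (x_j - x_i)/(t_j - t_i);
    intercept = median(x_i - slope * t_i).
    """
    x = np.asarray(series, dtype=float)
    t = np.arange(len(x), dtype=float) if time is None else np.asarray(time, float)
    keep = np.isfinite(x)
    x, t = x[keep], t[keep]
    n = len(x)
    if n < 2 or len(np.unique(t)) < 2:
        raise ValueError("theil_sen requires >= 2 distinct time points")
    i, j = np.triu_indices(n, k=1)
    dt = t[j] - t[i]
    ok = dt != 0
    slopes = (x[j] - x[i])[ok] / dt[ok]
    slope = float(np.median(slopes))
    intercept = float(np.median(x - slope * t))
    return slope, intercept


# ---------------------------------------------------------------------------
# annual / seasonal table


#: variable -> within-period aggregation used for the trend table
_AGGREGATIONS = {
    "t_air_mean": "mean",
    "t_air_min": "min",
    "t_air_max": "max",
    "hours_below_0": "sum",
    "vpd": "mean",
    "rg": "mean",
    "prec": "sum",
    "rh": "mean",
    "swc": "mean",
    "ppfd": "mean",
    "daylength": "mean",
    "nee": "sum",
}


def _stars(p: float) -> str:
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


def annual_seasonal_trend_table(
    met: pd.DataFrame, daily_nee: pd.Series, alpha: float = 0.05
) -> pd.DataFrame:
    """Means +/- SD and Mann-Kendall/Theil-Sen trends per variable and period.

    Periods are the full year and the climatological seasons (DJF with
    December assigned to the following season-year).  Aggregation within a
    period: mean for state variables, sum for precipitation, NEE and
    freezing hours, min of daily minima for minimum temperature, max of
    daily maxima for maximum temperature.  Variables with fewer than three
    aggregated years are skipped with a warning.
    """
    data = met.copy()
    data["nee"] = daily_nee
    rows = []
    for period in ("annual", "DJF", "MAM", "JJA", "SON"):
        if period == "annual":
            grouper = data.index.year
            sub = data
        else:
            lab = assign_season(data.index)
            sub = data[lab["season"].to_numpy() == period]
            grouper = lab.loc[lab["season"] == period, "season_year"].to_numpy()
        for var, how in _AGGREGATIONS.items():
            if var not in sub.columns:
                continue
            series = sub[var].groupby(grouper).agg(how).dropna()
            if len(series) < 3:
                logger.warning("%s/%s: <3 years, skipped", var, period)
                continue
            res = mann_kendall(series.to_numpy(), alpha=alpha)
            rows.append(
                {
                    "variable": var,
                    "period": period,
                    "n_years": res.n,
                    "mean": float(series.mean()),
                    "sd": float(series.std(ddof=1)),
                    "sen_slope": res.sen_slope,
                    "p_value": res.p_value,
                    "stars": _stars(res.p_value),
                }
            )
    return pd.DataFrame(rows).set_index(["variable", "period"])


# ---------------------------------------------------------------------------
# per-DOY trends


TREND_CATEGORIES = (
    "source-larger",     # mean NEE > 0, positive trend
    "sink-smaller",      # mean NEE < 0, positive trend, no sign switch
    "switch-to-source",  # fitted line crosses 0 upward over the record
    "sink-larger",       # mean NEE < 0, negative trend
    "source-smaller",    # mean NEE > 0, negative trend, no sign switch
    "switch-to-sink",    # fitted line crosses 0 downward over the record
)


def classify_doy_trend(mean_nee: float, trend: TrendResult, span: int) -> str:
    """Assign one of the six sink/source trend categories for a DOY.

    The Theil-Sen fit is evaluated at the first and last year; a sign
    change of the fitted value takes precedence (switch categories),
    otherwise the combination of sign(mean NEE) and sign(slope) decides.
    """
    f1 = trend.sen_intercept
    f2 = trend.sen_intercept + trend.sen_slope * (span - 1)
    if f1 != 0 and f2 != 0 and np.sign(f1) != np.sign(f2):
        return "switch-to-sink" if f2 < 0 else "switch-to-source"
    if trend.sen_slope == 0 and mean_nee == 0:
        return "none"
    if trend.sen_slope >= 0:
        return "source-larger" if mean_nee > 0 else "sink-smaller"
    return "sink-larger" if mean_nee < 0 else "source-smaller"


def doy_trend_analysis(
    daily_nee: pd.Series,
    smoothing: SmoothingSpec = SmoothingSpec(5, "trailing"),
    alpha: float = 0.05,
    min_years: int = 10,
    bh_correction: bool = False,
) -> pd.DataFrame:
    """Cross-year trend of smoothed daily NEE for each calendar day.

    Each year's series is smoothed (5-day moving average by default), Feb 29
    is dropped so DOY 1-365 align across years, then for every DOY the
    across-year Mann-Kendall test and Theil-Sen slope are computed.  DOYs
    with fewer than ``min_years`` valid years are skipped.  Raw p-values
    are used by default; ``bh_correction`` applies Benjamini-Hochberg
    across the 365 tests.
    """
    idx = pd.DatetimeIndex(daily_nee.index)
    keep = ~((idx.month == 2) & (idx.day == 29))
    series = daily_nee[keep]

    by_year = {}
    for year, sub in series.groupby(series.index.year):
        sm = moving_average(sub.to_numpy(), smoothing)
        doy_rank = np.arange(1, len(sm) + 1)  # post leap-removal alignment
        by_year[year] = pd.Series(sm.to_numpy(), index=doy_rank)
    mat = pd.DataFrame(by_year)  # rows: DOY 1..365, cols: years
    mat = mat.reindex(range(1, 366))

    rows = []
    for doy in mat.index:
        vals = mat.loc[doy].to_numpy(dtype=float)
        if np.isfinite(vals).sum() < min_years:
            continue
        res = mann_kendall(vals, alpha=alpha)
        mean_nee = float(np.nanmean(vals))
        rows.append(
            {
                "doy": int(doy),
                "mean_nee": mean_nee,
                "sen_slope": res.sen_slope,
                "p_value": res.p_value,
                "significant": res.significant,
                "category": classify_doy_trend(mean_nee, res, span=res.n),
            }
        )
    out = pd.DataFrame(rows).set_index("doy")
    if bh_correction and len(out):
        p = out["p_value"].to_numpy()
        order = np.argsort(p)
        ranked = p[order] * len(p) / (np.arange(len(p)) + 1)
        adj = np.minimum.accumulate(ranked[::-1])[::-1].clip(max=1.0)
        p_adj = np.empty_like(adj)
        p_adj[order] = adj
        out["p_value_bh"] = p_adj
        out["significant"] = out["p_value_bh"] < alpha
    return out


# ---------------------------------------------------------------------------
# percentile trends


def percentile_trends(
    daily_nee: pd.Series,
    percentiles=(1, 5, 50, 95, 99),
    alpha: float = 0.05,
    min_valid_days: int = 300,
) -> dict[float, TrendResult]:
    """Cross-year trends of annual NEE percentiles (unsmoothed daily values).

    Percentiles use the linear-interpolation quantile definition.  Years
    with fewer than ``min_valid_days`` valid days are excluded.
    """
    per_year = {}
    for year, sub in daily_nee.groupby(daily_nee.index.year):
        vals = sub.dropna().to_numpy()
        if len(vals) < min_valid_days:
            continue
        per_year[year] = np.percentile(vals, percentiles)
    if not per_year:
        raise ValueError("no year with sufficient coverage")
    mat = pd.DataFrame(per_year, index=list(percentiles)).T.sort_index()
    return {
        float(p): mann_kendall(mat[p].to_numpy(), alpha=alpha)
        for p in percentiles
    }


# ---------------------------------------------------------------------------
# change-point detection


def pettitt_changepoint(series) -> tuple[int, float]:
    """Pettitt's nonparametric change-point test.

    U_t = sum_{i<=t} sum_{j>t} sign(x_j - x_i); the change point is the
    index t (0-based, last index of the first segment) maximising |U_t|,
    with approximate significance p = 2*exp(-6 K^2 / (n^3 + n^2)).
    """
    x = np.asarray(series, dtype=float)
    x = x[np.isfinite(x)]
    n = len(x)
    if n < 8:
        raise ValueError("pettitt_changepoint requires n >= 8")
    sgn = np.sign(x[np.newaxis, :] - x[:, np.newaxis])  # sgn[i, j] = sign(x_j - x_i)
    # U_t = sum_{i <= t} sum_{j > t} sgn[i, j]
    u = np.array([sgn[: t + 1, t + 1:].sum() for t in range(n - 1)])
    k_idx = int(np.argmax(np.abs(u)))
    k = float(np.abs(u[k_idx]))
    p = min(1.0, 2.0 * np.exp(-6.0 * k**2 / (n**3 + n**2)))
    return k_idx, float(p)
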