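"""Net carbon uptake period (CUP_net) extraction from daily NEE.

The season boundaries are the first and last zero-crossings of a smoothed
daily NEE series (10-day moving average by default), with a persistence
criterion: the smoothed series must remain negative for at least 14
consecutive days following the start of season (SOS) and for 14 days
preceding the end of season (EOS).  Candidates failing the criterion are
discarded — together with their whole contiguous negative run — and the
search continues inward, which keeps short uptake spells at the year's
margins from producing spuriously early or late season dates.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats


@dataclass(frozen=True)
class SmoothingSpec:
    """Moving-window mean specification.

    ``trailing`` averages the previous ``window`` days including the current
    day; ``centered`` uses a symmetric window (for even windows, the extra
    day is taken from the past side).  Windows are truncated at the series
    edges: the available days are averaged rather than dropped.
    """

    window: int = 10
    alignment: Literal["trailing", "centered"] = "trailing"

    def __post_init__(self) -> None:
        if self.window < 1:
            raise ValueError("window must be >= 1")
        if self.alignment not in ("trailing", "centered"):
            raise ValueError("alignment must be 'trailing' or 'centered'")


def moving_average(series, spec: SmoothingSpec) -> pd.Series:
    """Moving mean of a regular daily series under ``spec``.

    Edge windows use only the available days (no NaN padding), so the
    output has the same length as the input.
    """
    s = pd.Series(series, dtype=float)
    w = spec.window
    if spec.alignment == "trailing":
        return s.rolling(window=w, min_periods=1).mean()
    # centered with even-window past-side bias: window covering
    # [d - ceil((w-1)/2), d + floor((w-1)/2)]
    ahead = (w - 1) // 2
    out = s.rolling(window=w, min_periods=1).mean().shift(-ahead)
    # the shift re-opens the tail: recompute truncated tail windows directly
    n = len(s)
    back = w - 1 - ahead
    for i in range(max(n - ahead, 0), n):
        out.iloc[i] = s.iloc[max(i - back, 0): i + ahead + 1].mean()
    return out


@dataclass(frozen=True)
class PhenologyResult:
    """Per-year season boundaries and day-count diagnostics.

    SOS/EOS are days of year; ``cup_length`` is inclusive
    (EOS - SOS + 1).  ``n_release_days_within`` counts days inside
    [SOS, EOS] whose unsmoothed NEE is positive (net release during the
    uptake period); ``n_uptake_days_outside`` counts days outside with
    negative NEE.  All boundary fields are None for a year without a
    qualifying uptake period (``no_cup`` flag set).
    """

    year: int
    sos_doy: int | None
    eos_doy: int | None
    cup_length: int | None
    n_release_days_within: int | None = None
    n_uptake_days_outside: int | None = None
    pct_release_within: float | None = None
    pct_uptake_outside: float | None = None
    no_cup: bool = False

    @property
    def defined(self) -> bool:
        return not self.no_cup


def _negative_runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Contiguous True runs as (start, stop) index pairs, stop inclusive."""
    runs = []
    in_run = False
    start = 0
    for i, flag in enumerate(mask):
        if flag and not in_run:
            in_run, start = True, i
        elif not flag and in_run:
            runs.append((start, i - 1))
            in_run = False
    if in_run:
        runs.append((start, len(mask) - 1))
    return runs


def extract_cup(
    daily,
    spec: SmoothingSpec = SmoothingSpec(10, "trailing"),
    persistence: int = 14,
    min_valid_days: int = 300,
) -> PhenologyResult:
    """Extract SOS, EOS and CUP length for one year of daily NEE.

    Parameters
    ----------
    daily
        Date-indexed Series (one calendar year) or plain array of daily
        NEE, g C m-2 d-1; negative = net uptake.
    spec
        Smoothing applied before the zero-crossing search.
    persistence
        Minimum consecutive negative days required after SOS / before EOS
        (the SOS/EOS day itself counts toward the window).
    min_valid_days
        Minimum non-missing days required in the year.

    Notes
    -----
    A smoothed value of exactly zero counts as non-negative.  Because the
    persistence window starts at the candidate day, a candidate is accepted
    iff the contiguous negative run it starts (for SOS) or ends (for EOS)
    has at least ``persistence`` days — so the search reduces to: SOS is
    the start of the earliest negative run of length >= persistence, EOS
    the end of the latest such run.
    """
    if isinstance(daily, pd.Series):
        values = daily.to_numpy(dtype=float)
        years = pd.DatetimeIndex(daily.index).year
        if len(set(years)) > 1:
            raise ValueError("extract_cup expects a single calendar year")
        year = int(years[0])
        doys = pd.DatetimeIndex(daily.index).dayofyear.to_numpy()
    else:
        values = np.asarray(daily, dtype=float)
        year = 0
        doys = np.arange(1, len(values) + 1)

    n_valid = int(np.isfinite(values).sum())
    if n_valid < min_valid_days:
        raise ValueError(
            f"year {year}: only {n_valid} valid days (< {min_valid_days})"
        )

    smoothed = moving_average(values, spec).to_numpy()
    negative = np.isfinite(smoothed) & (smoothed < 0.0)
    qualifying = [
        (a, b) for a, b in _negative_runs(negative) if (b - a + 1) >= persistence
    ]
    if not qualifying:
        return PhenologyResult(year, None, None, None, no_cup=True)

    sos_idx = qualifying[0][0]
    eos_idx = qualifying[-1][1]
    sos_doy = int(doys[sos_idx])
    eos_doy = int(doys[eos_idx])
    length = eos_doy - sos_doy + 1

    inside = (doys >= sos_doy) & (doys <= eos_doy)
    finite = np.isfinite(values)
    n_release = int(np.sum(inside & finite & (values > 0)))
    n_uptake_out = int(np.sum(~inside & finite & (values < 0)))
    n_inside = int(np.sum(inside & finite))
    n_outside = int(np.sum(~inside & finite))
    return PhenologyResult(
        year=year,
        sos_doy=sos_doy,
        eos_doy=eos_doy,
        cup_length=length,
        n_release_days_within=n_release,
        n_uptake_days_outside=n_uptake_out,
        pct_release_within=100.0 * n_release / n_inside if n_inside else None,
        pct_uptake_outside=100.0 * n_uptake_out / n_outside if n_outside else None,
    )


def extract_cup_all_years(
    daily: pd.Series,
    spec: SmoothingSpec = SmoothingSpec(10, "trailing"),
    persistence: int = 14,
    min_valid_days: int = 300,
) -> list[PhenologyResult]:
    """Run :func:`extract_cup` on every calendar year of a daily series."""
    results = []
    for _, sub in daily.groupby(daily.index.year):
        results.append(extract_cup(sub, spec, persistence, min_valid_days))
    return results


def results_frame(results: Sequence[PhenologyResult]) -> pd.DataFrame:
    """Tabulate per-year phenology results (one row per year)."""
    return pd.DataFrame(
        [
            {
                "year": r.year,
                "sos_doy": r.sos_doy,
                "eos_doy": r.eos_doy,
                "cup_length": r.cup_length,
                "n_release_days_within": r.n_release_days_within,
                "n_uptake_days_outside": r.n_uptake_days_outside,
                "pct_release_within": r.pct_release_within,
                "pct_uptake_outside": r.pct_uptake_outside,
                "no_cup": r.no_cup,
            }
            for r in results
        ]
    ).set_index("year")


def cup_summary(results: Sequence[PhenologyResult]) -> dict:
    """Means, spreads, extremes and cross-year trends of SOS/EOS/length.

    Trends are Mann-Kendall tests with Theil-Sen slopes across the defined
    years (requires >= 3 defined years; otherwise trend entries are None).
    """
    from fluxphen.trends import mann_kendall, theil_sen

    defined = [r for r in results if r.defined]
    if not defined:
        raise ValueError("no year with a defined uptake period")
    summary: dict = {"n_years": len(results), "n_defined": len(defined)}
    for name in ("sos_doy", "eos_doy", "cup_length"):
        vals = np.array([getattr(r, name) for r in defined], dtype=float)
        yrs = np.array([r.year for r in defined])
        entry = {
            "mean": float(vals.mean()),
            "sd": float(vals.std(ddof=1)) if len(vals) > 1 else 0.0,
            "min": float(vals.min()),
            "min_year": int(yrs[int(np.argmin(vals))]),
            "max": float(vals.max()),
            "max_year": int(yrs[int(np.argmax(vals))]),
        }
        if len(vals) >= 3:
            mk = mann_kendall(vals)
            slope, intercept = theil_sen(vals)
            entry["trend"] = {
                "sen_slope": slope,
                "sen_intercept": intercept,
                "p_value": mk.p_value,
                "significant": mk.significant,
            }
        else:
            entry["trend"] = None
        summary[name] = entry
    return summary


def phenology_nee_relationships(
    annual_nee: pd.Series, results: Sequence[PhenologyResult]
) -> pd.DataFrame:
    """Regress annual NEE on CUP length, SOS and EOS across years.

    ``annual_nee`` is indexed by year (g C m-2 yr-1).  For each predictor
    the OLS slope/intercept/R^2/two-sided p and the Spearman rank
    correlation are reported.  Predictors with no variance are flagged and
    their statistics left undefined.
    """
    frame = results_frame(results)
    frame = frame[~frame["no_cup"]]
    years = frame.index.intersection(annual_nee.index)
    if len(years) < 4:
        raise ValueError("need >= 4 paired years")
    y = annual_nee.loc[years].to_numpy(dtype=float)

    rows = []
    for name in ("cup_length", "sos_doy", "eos_doy"):
        x = frame.loc[years, name].to_numpy(dtype=float)
        if np.ptp(x) == 0 or np.ptp(y) == 0:
            rows.append(
                {"predictor": name, "degenerate": True, "slope": np.nan,
                 "intercept": np.nan, "r2": np.nan, "p_value": np.nan,
                 "spearman_rho": np.nan, "n": len(years)}
            )
            continue
        ols = stats.linregress(x, y)
        rho, _ = stats.spearmanr(x, y)
        rows.append(
            {
                "predictor": name,
                "degenerate": False,
                "slope": float(ols.slope),
                "intercept": float(ols.intercept),
                "r2": float(ols.rvalue**2),
                "p_value": float(ols.pvalue),
                "spearman_rho": float(rho),
                "n": len(years),
            }
        )
    return pd.DataFrame(rows).set_index("predictor")
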