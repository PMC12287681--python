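"""Flux/met table I/O, derived variables and uncertainty aggregation.

Conventions follow the FLUXNET/ICOS dialect: half-hourly files carry
``TIMESTAMP_START``/``TIMESTAMP_END`` as ``YYYYMMDDHHMM`` strings in local
standard time (no DST), missing values are encoded as ``-9999``; daily
files use ISO dates.  Fluxes are CO2 (umol CO2 m-2 s-1), daily sums are
carbon mass (g C m-2 d-1), micrometeorological sign convention: negative
NEE is net ecosystem uptake.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: FLUXNET missing-value sentinel.
SENTINEL = -9999.0

#: Molar mass of carbon, g mol-1. Daily NEE sums are carbon, not CO2.
MOLAR_MASS_C = 12.0107

#: Seconds per half-hour averaging interval.
HALFHOUR_SECONDS = 1800.0

#: g C per (umol CO2 m-2 s-1 held for one half-hour).
UMOL_HALFHOUR_TO_GC = HALFHOUR_SECONDS * MOLAR_MASS_C * 1e-6


# ---------------------------------------------------------------------------
# reading / writing


def read_halfhourly_csv(
    path: str | Path,
    column_map: Mapping[str, str] | None = None,
    strict: bool = False,
) -> pd.DataFrame:
    """Read a half-hourly flux CSV into a tidy frame.

    Parameters
    ----------
    path
        CSV with ``TIMESTAMP_START`` / ``TIMESTAMP_END`` columns in
        ``YYYYMMDDHHMM`` format and a ``NEE`` column; optional columns
        ``NEE_RANDUNC`` (random uncertainty), ``NEE_USTAR16`` and
        ``NEE_USTAR84`` (fluxes gap-filled under the 16th/84th-percentile
        u* thresholds).
    column_map
        Optional mapping from the file's column names to the canonical
        names above, e.g. ``{"NEE_VUT_REF": "NEE"}``.
    strict
        If True, non-monotone timestamps or unknown columns raise.

    Returns
    -------
    DataFrame indexed by ``timestamp_start`` with lower-case columns;
    sentinel values are mapped to NaN.
    """
    df = pd.read_csv(path, dtype={"TIMESTAMP_START": str, "TIMESTAMP_END": str})
    if column_map:
        df = df.rename(columns=dict(column_map))
    required = {"TIMESTAMP_START", "TIMESTAMP_END", "NEE"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"missing required columns: {sorted(missing)}")
    known = required | {"NEE_RANDUNC", "NEE_USTAR16", "NEE_USTAR84"}
    unknown = set(df.columns) - known
    if unknown and strict:
        raise ValueError(f"unknown columns under strict mode: {sorted(unknown)}")

    try:
        start = pd.to_datetime(df["TIMESTAMP_START"], format="%Y%m%d%H%M")
        end = pd.to_datetime(df["TIMESTAMP_END"], format="%Y%m%d%H%M")
    except ValueError as exc:
        raise ValueError(f"malformed timestamp in {path}: {exc}") from exc

    if not start.is_monotonic_increasing or start.duplicated().any():
        raise ValueError("timestamps must be strictly increasing")
    spacing = start.diff().dropna()
    if len(spacing) and not (spacing == pd.Timedelta(minutes=30)).all():
        if strict:
            raise ValueError("non 30-min spacing between records")
        logger.warning("gaps in half-hourly timestamps in %s", path)

    out = pd.DataFrame({"timestamp_start": start, "timestamp_end": end})
    for col in ["NEE", "NEE_RANDUNC", "NEE_USTAR16", "NEE_USTAR84"]:
        if col in df.columns:
            vals = pd.to_numeric(df[col], errors="coerce")
            out[col.lower()] = vals.mask(vals == SENTINEL)
    return out.set_index("timestamp_start")


def read_daily_csv(path: str | Path) -> pd.DataFrame:
    """Read a daily CSV (ISO ``date`` column) into a date-indexed frame."""
    df = pd.read_csv(path, parse_dates=["date"])
    df = df.set_index("date").sort_index()
    return df.mask(df == SENTINEL)


def write_daily_csv(
    df: pd.DataFrame,
    path: str | Path,
    provenance: Mapping | None = None,
) -> None:
    """Write a date-indexed daily frame as CSV with a JSON provenance sidecar.

    Missing values are written as the -9999 sentinel so the file round-trips
    through :func:`read_daily_csv`.
    """
    path = Path(path)
    out = df.copy()
    out.index.name = "date"
    out = out.fillna(SENTINEL)
    out.to_csv(path, date_format="%Y-%m-%d")
    sidecar = dict(provenance or {})
    sidecar.setdefault("columns", list(df.columns))
    sidecar.setdefault("n_rows", int(len(df)))
    path.with_suffix(path.suffix + ".json").write_text(
        json.dumps(sidecar, indent=2, default=str)
    )


# ---------------------------------------------------------------------------
# aggregation


def aggregate_daily(records: pd.DataFrame) -> pd.Series:
    """Aggregate half-hourly NEE to daily 24-h cumulative sums (NEE_c,DOY).

    Each half-hourly flux (umol CO2 m-2 s-1) is integrated over its 1800 s
    interval and converted to grams of carbon.  A day with any missing
    half-hour, or fewer than 48 records, yields a missing daily value:
    inputs are expected gap-filled, so incompleteness flags an upstream
    problem rather than being silently partially summed.

    Returns a Series of g C m-2 d-1 indexed by date.
    """
    if "nee" not in records.columns:
        raise ValueError("records must carry an 'nee' column")
    day = records.index.normalize()
    grouped = records["nee"].groupby(day)
    n = grouped.size()
    n_missing = grouped.apply(lambda s: int(s.isna().sum()))
    daily = grouped.sum(min_count=48) * UMOL_HALFHOUR_TO_GC
    incomplete = (n < 48) | (n_missing > 0)
    daily[incomplete] = np.nan
    n_bad = int(incomplete.sum())
    if n_bad:
        logger.info("aggregate_daily: %d incomplete day(s) set to missing", n_bad)
    daily.index.name = "date"
    daily.name = "nee"
    return daily


# ---------------------------------------------------------------------------
# derived met variables


def compute_daylength(latitude: float, doy) -> np.ndarray | float:
    """Hours between sunrise and sunset from solar declination and latitude.

    Uses declination delta = -23.44 deg * cos(2*pi*(doy+10)/365) and the
    sunset hour angle cos(w0) = -tan(lat)*tan(delta).  The cosine is clamped
    to [-1, 1], so polar day/night saturate at 24 h / 0 h; latitudes beyond
    the polar circles trigger a warning but are still computed.
    """
    if abs(latitude) > 66.5:
        logger.warning("latitude %.2f outside validated band (|lat| <= 66.5)", latitude)
    doy_arr = np.asarray(doy, dtype=float)
    if np.any((doy_arr < 1) | (doy_arr > 366)):
        raise ValueError("doy must be in [1, 366]")
    decl = np.deg2rad(-23.44) * np.cos(2.0 * np.pi * (doy_arr + 10.0) / 365.0)
    cos_w0 = -np.tan(np.deg2rad(latitude)) * np.tan(decl)
    cos_w0 = np.clip(cos_w0, -1.0, 1.0)
    hours = np.degrees(np.arccos(cos_w0)) * 2.0 / 15.0
    hours = np.clip(hours, 0.0, 24.0)
    return float(hours) if np.isscalar(doy) else hours


def compute_vpd(t_air, rh) -> np.ndarray | float:
    """Vapor pressure deficit (hPa) from air temperature (degC) and RH (%).

    Magnus saturation vapor pressure e_s(T) = 6.1078 * exp(17.27*T/(T+237.3)).
    """
    t = np.asarray(t_air, dtype=float)
    r = np.asarray(rh, dtype=float)
    valid = np.isnan(r) | ((r >= 0.0) & (r <= 100.0))
    if not np.all(valid):
        raise ValueError("rh must lie in [0, 100]")
    es = saturation_vapor_pressure(t)
    vpd = es * (1.0 - r / 100.0)
    return float(vpd) if np.isscalar(t_air) and np.isscalar(rh) else vpd


def saturation_vapor_pressure(t_air) -> np.ndarray | float:
    """Magnus saturation vapor pressure over water, hPa."""
    t = np.asarray(t_air, dtype=float)
    es = 6.1078 * np.exp(17.27 * t / (t + 237.3))
    return float(es) if np.isscalar(t_air) else es


_SEASON_OF_MONTH = {
    12: "DJF", 1: "DJF", 2: "DJF",
    3: "MAM", 4: "MAM", 5: "MAM",
    6: "JJA", 7: "JJA", 8: "JJA",
    9: "SON", 10: "SON", 11: "SON",
}


def assign_season(date) -> tuple[str, int] | pd.DataFrame:
    """Climatological season (DJF/MAM/JJA/SON) plus season-year.

    December belongs to the DJF of the *following* calendar year, so the
    winter 1997/1998 is labelled (DJF, 1998).  Scalar input returns a
    ``(season, year)`` tuple; a DatetimeIndex/Series returns a DataFrame
    with ``season`` and ``season_year`` columns.
    """
    if isinstance(date, (pd.DatetimeIndex, pd.Series)):
        idx = pd.DatetimeIndex(date)
        season = idx.month.map(_SEASON_OF_MONTH)
        year = idx.year + (idx.month == 12).astype(int)
        return pd.DataFrame({"season": season, "season_year": year}, index=idx)
    ts = pd.Timestamp(date)
    return _SEASON_OF_MONTH[ts.month], ts.year + (1 if ts.month == 12 else 0)


# ---------------------------------------------------------------------------
# uncertainty


@dataclass(frozen=True)
class AnnualUncertainty:
    """Annual NEE uncertainty components, g C m-2 yr-1 (all >= 0)."""

    year: int
    random_component: float
    ustar_component: float | None
    joint: float


def joint_annual_uncertainty(
    daily_random_uncertainty: pd.Series,
    annual_nee_by_threshold: Sequence[float] | None,
    year: int | None = None,
) -> AnnualUncertainty:
    """Combine random and u*-filtering uncertainty into an annual value.

    The random component assumes independent daily errors:
    sqrt(sum of squared daily uncertainties).  The u* component is half the
    absolute range of annual NEE across the gap-filled series computed under
    the {16th, 50th, 84th}-percentile u* thresholds.  The joint uncertainty
    adds the two in quadrature.  If no threshold series is available the u*
    component is absent and the joint equals the random component.
    """
    vals = pd.Series(daily_random_uncertainty).dropna().to_numpy(dtype=float)
    random = float(np.sqrt(np.sum(vals**2)))
    if year is None:
        idx = pd.Series(daily_random_uncertainty).index
        year = int(pd.DatetimeIndex(idx).year[0]) if len(idx) and isinstance(
            idx, pd.DatetimeIndex
        ) else 0
    if annual_nee_by_threshold is None or len(annual_nee_by_threshold) == 0:
        logger.warning("no u*-threshold series for %s: joint = random", year)
        return AnnualUncertainty(year, random, None, random)
    arr = np.asarray(annual_nee_by_threshold, dtype=float)
    ustar = float((arr.max() - arr.min()) / 2.0)
    joint = float(np.hypot(random, ustar))
    return AnnualUncertainty(year, random, ustar, joint)
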