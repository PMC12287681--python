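"""Synthetic daily met + NEE generator with known ground truth.

The generator emulates the statistical structure of a long-term subalpine
eddy-covariance site: sinusoidal seasonality in temperature and radiation,
AR(1) day-to-day noise, optional linear trends per variable, and daily NEE
composed of temperature-driven respiration minus a light/temperature/
moisture-driven uptake term.  The defaults approximate a cool subalpine
spruce site (mean annual air temperature ~4.3 degC, ~870 mm precipitation,
one contiguous warm season) so that each calendar year contains exactly one
dominant negative-NEE (net uptake) season.

Because the uptake and respiration terms are known, the noise-free
zero-crossing days of the smoothed NEE series provide exact per-year ground
truth for the season start/end (SOS*/EOS*) against which the phenology
extractor can be validated.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from fluxphen import flux_io
from fluxphen.phenology import SmoothingSpec, extract_cup


@dataclass
class SeasonalVariable:
    """Seasonal-sinusoid parameters for one daily met variable.

    value(day) = mean + amplitude * cos(2*pi*(DOY - phase_doy)/365)
               + trend * (year - start_year) + AR(1) noise
    """

    mean: float
    amplitude: float = 0.0
    phase_doy: float = 200.0
    trend: float = 0.0  # units yr-1
    noise_sd: float = 0.0
    ar1: float = 0.0


def _default_variables() -> dict[str, SeasonalVariable]:
    # Subalpine spruce-site climatology: winter means near -3 degC, summer
    # near 12 degC, radiation peaking at the solstice, moist soils.
    return {
        "t_air_mean": SeasonalVariable(4.3, 8.0, 205.0, noise_sd=1.5, ar1=0.6),
        "t_air_min": SeasonalVariable(0.3, 8.0, 205.0, noise_sd=1.8, ar1=0.6),
        "t_air_max": SeasonalVariable(9.0, 9.0, 205.0, noise_sd=1.8, ar1=0.6),
        "rg": SeasonalVariable(148.0, 75.0, 172.0, noise_sd=25.0, ar1=0.3),
        "rh": SeasonalVariable(75.0, 5.0, 20.0, noise_sd=6.0, ar1=0.4),
        "swc": SeasonalVariable(26.0, 3.0, 120.0, noise_sd=1.5, ar1=0.9),
        "prec": SeasonalVariable(2.4, 0.8, 190.0, noise_sd=3.0, ar1=0.1),
    }


@dataclass
class SyntheticScenario:
    """Full specification of a synthetic multi-year site run.

    NEE model (g C m-2 d-1, micrometeorological sign convention):

        NEE_d = R_d - U_d + trend term + AR(1) noise
        R_d   = r0 * q10 ** ((T_mean - 10) / 10)
        U_d   = lue * Rg * ramp(T_mean; t_low, t_opt, t_high)
                    * SWC / (SWC + swc_half)

    where ramp rises linearly 0 -> 1 on [t_low, t_opt] and falls 1 -> 0 on
    [t_opt, t_high].  ``nee_trend`` is expressed on the annual-sum scale
    (g C m-2 yr-1 per year) and applied as a uniform daily offset.
    """

    n_years: int = 26
    start_year: int = 1997
    latitude: float = 46.815
    variables: dict[str, SeasonalVariable] = field(default_factory=_default_variables)
    # NEE model coefficients
    r0: float = 2.0          # base respiration at 10 degC, g C m-2 d-1
    q10: float = 2.2         # respiration temperature sensitivity
    lue: float = 0.027       # uptake per unit radiation, g C m-2 d-1 per W m-2
    t_low: float = -5.0      # degC, uptake shuts off below
    t_opt: float = 12.0      # degC, uptake optimum
    t_high: float = 30.0     # degC, uptake shuts off above
    swc_half: float = 10.0   # %, half-saturation of the soil-moisture factor
    nee_noise_sd: float = 0.5   # g C m-2 d-1, daily AR(1) noise
    nee_ar1: float = 0.3
    nee_trend: float = 0.0   # g C m-2 yr-1 per year, annual-sum scale
    seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.n_years < 1:
            raise ValueError("n_years must be >= 1")
        if not (self.t_low < self.t_opt < self.t_high):
            raise ValueError("require t_low < t_opt < t_high")
        if self.swc_half <= 0:
            raise ValueError("swc_half must be > 0")
        if not (0.0 <= self.nee_ar1 < 1.0):
            raise ValueError("nee_ar1 must lie in [0, 1)")
        if self.nee_noise_sd < 0:
            raise ValueError("nee_noise_sd must be >= 0")
        for name, var in self.variables.items():
            if not isinstance(var, SeasonalVariable):
                raise TypeError(f"variables[{name!r}] must be a SeasonalVariable")
            if var.amplitude < 0:
                raise ValueError(f"variables[{name!r}].amplitude must be >= 0")
            if not (0.0 <= var.ar1 < 1.0):
                raise ValueError(f"variables[{name!r}].ar1 must lie in [0, 1)")
            if var.noise_sd < 0:
                raise ValueError(f"variables[{name!r}].noise_sd must be >= 0")

    # -- serialisation ------------------------------------------------------

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SyntheticScenario":
        raw = yaml.safe_load(Path(path).read_text())
        raw["variables"] = {
            k: SeasonalVariable(**v) for k, v in raw.get("variables", {}).items()
        }
        return cls(**raw)


# ---------------------------------------------------------------------------


def _ar1_noise(rng: np.random.Generator, n: int, sd: float, ar1: float) -> np.ndarray:
    """Stationary AR(1) noise with marginal standard deviation ``sd``."""
    if sd == 0.0:
        return np.zeros(n)
    eps = np.empty(n)
    eps[0] = rng.normal(0.0, sd)
    innov = rng.normal(0.0, sd * np.sqrt(1.0 - ar1**2), size=n - 1)
    for t in range(1, n):
        eps[t] = ar1 * eps[t - 1] + innov[t - 1]
    return eps


def _hours_below_zero(t_min: np.ndarray, t_max: np.ndarray) -> np.ndarray:
    """Hours per day with T_air < 0 degC by linear within-day interpolation.

    The diurnal course is treated as a triangle wave between the daily
    minimum and maximum, so the fraction of the day below freezing is the
    linear fraction of the min-max span below zero.
    """
    span = t_max - t_min
    with np.errstate(divide="ignore", invalid="ignore"):
        frac = np.where(span > 0, (0.0 - t_min) / span, np.where(t_min < 0, 1.0, 0.0))
    return 24.0 * np.clip(frac, 0.0, 1.0)


def generate_met(scenario: SyntheticScenario) -> pd.DataFrame:
    """Generate the daily meteorological driver table for a scenario.

    One row per calendar day (Feb 29 included but flagged in ``is_leap_day``
    so downstream DOY analyses can drop it).  Relative humidity and soil
    water content are clipped to [0, 100] %, precipitation to >= 0.
    Daylength and VPD are derived with :mod:`fluxphen.flux_io`.
    """
    scenario.validate()
    rng = np.random.default_rng(scenario.seed)
    end_year = scenario.start_year + scenario.n_years - 1
    dates = pd.date_range(
        f"{scenario.start_year}-01-01", f"{end_year}-12-31", freq="D"
    )
    doy = dates.dayofyear.to_numpy(dtype=float)
    year_offset = (dates.year - scenario.start_year).to_numpy(dtype=float)
    n = len(dates)

    cols: dict[str, np.ndarray] = {}
    for name in sorted(scenario.variables):
        var = scenario.variables[name]
        seasonal = var.mean + var.amplitude * np.cos(
            2.0 * np.pi * (doy - var.phase_doy) / 365.0
        )
        cols[name] = seasonal + var.trend * year_offset + _ar1_noise(
            rng, n, var.noise_sd, var.ar1
        )

    for name in ("rh", "swc"):
        if name in cols:
            cols[name] = np.clip(cols[name], 0.0, 100.0)
    if "prec" in cols:
        cols["prec"] = np.clip(cols["prec"], 0.0, None)
    if "rg" in cols:
        cols["rg"] = np.clip(cols["rg"], 0.0, None)

    met = pd.DataFrame(cols, index=dates)
    met.index.name = "date"

    # enforce t_air_min <= t_air_mean <= t_air_max
    if {"t_air_mean", "t_air_min", "t_air_max"} <= set(met.columns):
        met["t_air_min"] = np.minimum(met["t_air_min"], met["t_air_mean"])
        met["t_air_max"] = np.maximum(met["t_air_max"], met["t_air_mean"])
        met["hours_below_0"] = _hours_below_zero(
            met["t_air_min"].to_numpy(), met["t_air_max"].to_numpy()
        )

    met["daylength"] = flux_io.compute_daylength(scenario.latitude, doy.clip(1, 366))
    if {"t_air_mean", "rh"} <= set(met.columns):
        met["vpd"] = flux_io.compute_vpd(
            met["t_air_mean"].to_numpy(), met["rh"].to_numpy()
        )
    # PPFD proportional to shortwave radiation (~2.1 umol per J of Rg)
    if "rg" in met.columns and "ppfd" not in met.columns:
        met["ppfd"] = 2.1 * met["rg"]
    met["is_leap_day"] = (dates.month == 2) & (dates.day == 29)
    met.attrs["scenario_seed"] = scenario.seed
    met.attrs["latitude"] = scenario.latitude
    return met


def temperature_ramp(t, t_low: float, t_opt: float, t_high: float) -> np.ndarray:
    """Piecewise-linear uptake-efficiency ramp: 0 at t_low, 1 at t_opt, 0 at t_high."""
    t = np.asarray(t, dtype=float)
    up = (t - t_low) / (t_opt - t_low)
    down = (t_high - t) / (t_high - t_opt)
    return np.clip(np.minimum(up, down), 0.0, 1.0)


def generate_daily_nee(
    scenario: SyntheticScenario, met: pd.DataFrame
) -> pd.DataFrame:
    """Generate daily NEE from the met table under the scenario's NEE model.

    Returns a date-indexed frame with columns ``nee`` (g C m-2 d-1),
    ``nee_noisefree``, ``respiration`` and ``uptake``.  The per-year ground
    truth SOS*/EOS* — obtained by running the season extractor on the
    noise-free series with its default settings (10-day trailing mean,
    14-day persistence) — is stored in ``result.attrs["ground_truth"]``.
    """
    scenario.validate()
    required = {"t_air_mean", "rg", "swc"}
    if not required <= set(met.columns):
        raise ValueError(f"met table lacks columns {sorted(required - set(met.columns))}")
    exp_start = pd.Timestamp(f"{scenario.start_year}-01-01")
    exp_end = pd.Timestamp(f"{scenario.start_year + scenario.n_years - 1}-12-31")
    if met.index[0] > exp_start or met.index[-1] < exp_end:
        raise ValueError("met table does not cover the scenario span")

    t = met["t_air_mean"].to_numpy(dtype=float)
    rg = met["rg"].to_numpy(dtype=float)
    swc = met["swc"].to_numpy(dtype=float)
    resp = scenario.r0 * scenario.q10 ** ((t - 10.0) / 10.0)
    uptake = (
        scenario.lue
        * rg
        * temperature_ramp(t, scenario.t_low, scenario.t_opt, scenario.t_high)
        * swc
        / (swc + scenario.swc_half)
    )
    year_offset = (met.index.year - scenario.start_year).to_numpy(dtype=float)
    trend_daily = scenario.nee_trend * year_offset / 365.0
    noisefree = resp - uptake + trend_daily

    rng = np.random.default_rng(np.random.SeedSequence([scenario.seed, 1]))
    noise = _ar1_noise(rng, len(noisefree), scenario.nee_noise_sd, scenario.nee_ar1)

    daily = pd.DataFrame(
        {
            "nee": noisefree + noise,
            "nee_noisefree": noisefree,
            "respiration": resp,
            "uptake": uptake,
        },
        index=met.index,
    )
    daily.index.name = "date"
    daily.attrs["latitude"] = scenario.latitude
    daily.attrs["ground_truth"] = _phenology_ground_truth(daily)
    return daily


def _phenology_ground_truth(daily: pd.DataFrame) -> pd.DataFrame:
    """Per-year SOS*/EOS* of the noise-free series, via the season extractor."""
    rows = []
    series = daily["nee_noisefree"]
    for year, sub in series.groupby(series.index.year):
        res = extract_cup(sub, min_valid_days=300)
        rows.append(
            {"year": int(year), "sos_doy": res.sos_doy, "eos_doy": res.eos_doy}
        )
    return pd.DataFrame(rows).set_index("year")


def generate_halfhourly_nee(daily: pd.DataFrame, seed: int = 0) -> pd.DataFrame:
    """Disaggregate daily NEE into 48 half-hourly fluxes per day.

    The respiration part (plus daily noise) is spread flat over 24 h; the
    uptake part follows a half-sine over the daylight window (daylength from
    the site latitude stored in ``daily.attrs``, else 12 h).  A small seeded
    zero-sum jitter is added within each day, so the flux-unit daily
    integral equals the daily value to machine precision.

    Returns a frame indexed by half-hour start time with column ``nee``
    in umol CO2 m-2 s-1.
    """
    if daily["nee"].isna().any():
        raise ValueError("daily series must be complete (gap-filled)")
    rng = np.random.default_rng(seed)
    lat = daily.attrs.get("latitude", None)
    has_parts = {"respiration", "uptake"} <= set(daily.columns)

    hours = np.arange(48) * 0.5 + 0.25  # interval midpoints
    frames = []
    for date, row in daily.iterrows():
        nee_d = float(row["nee"])
        if has_parts:
            uptake_d = float(row["uptake"])
            flat_d = nee_d + uptake_d  # respiration + noise share
        else:
            uptake_d, flat_d = 0.0, nee_d
        if lat is not None:
            daylen = float(flux_io.compute_daylength(lat, min(date.dayofyear, 366)))
        else:
            daylen = 12.0
        daylen = max(daylen, 1.0)
        sunrise = 12.0 - daylen / 2.0
        phase = (hours - sunrise) / daylen
        w = np.where((phase > 0) & (phase < 1), np.sin(np.pi * phase), 0.0)
        w_sum = w.sum()
        w = w / w_sum if w_sum > 0 else np.full(48, 1.0 / 48.0)

        gc_per_halfhour = flat_d / 48.0 - uptake_d * w
        jitter = rng.normal(0.0, 0.02 * (abs(nee_d) / 48.0 + 1e-3), size=48)
        jitter -= jitter.mean()  # zero-sum: preserves the daily integral
        gc_per_halfhour = gc_per_halfhour + jitter

        flux = gc_per_halfhour / flux_io.UMOL_HALFHOUR_TO_GC
        start = pd.date_range(date, periods=48, freq="30min")
        frames.append(pd.DataFrame({"nee": flux}, index=start))

    out = pd.concat(frames)
    out.index.name = "timestamp_start"
    out["timestamp_end"] = out.index + pd.Timedelta(minutes=30)
    return out


def write_scenario_csvs(
    scenario: SyntheticScenario, outdir: str | Path
) -> dict[str, Path]:
    """Generate a scenario and write met + daily NEE CSVs (with sidecars)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    met = generate_met(scenario)
    daily = generate_daily_nee(scenario, met)
    met_path = outdir / "met_daily.csv"
    nee_path = outdir / "nee_daily.csv"
    prov = {"generator": "fluxphen.synthetic", "seed": scenario.seed}
    flux_io.write_daily_csv(met.drop(columns=["is_leap_day"]), met_path, prov)
    flux_io.write_daily_csv(daily[["nee"]], nee_path, prov)
    return {"met": met_path, "nee": nee_path}
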