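# Methods

## Scope and data model

The package analyses daily cumulative net ecosystem CO₂ exchange
(`NEE_c,DOY`, g C m⁻² d⁻¹) together with daily meteorology. Fluxes follow
the micrometeorological sign convention: negative NEE is net ecosystem
uptake (sink), positive is net loss (source). Inputs are assumed
gap-filled; raw eddy-covariance processing (despiking, rotation, spectral
corrections, u* filtering, gap-filling) is upstream and out of scope.

Half-hourly fluxes (µmol CO₂ m⁻² s⁻¹) are aggregated to daily sums as
Σ(flux · 1800 s) · 12.0107×10⁻⁶ g C µmol⁻¹ — daily values are carbon
mass, not CO₂. Any missing half-hour voids the whole day: since inputs
are expected gap-filled, an incomplete day flags an upstream problem, and
a silent partial sum would bias the daily cumulative value.

Derived variables: vapor pressure deficit uses the Magnus saturation
pressure e_s(T) = 6.1078·exp(17.27·T/(T+237.3)) hPa (a common WMO
variant; coefficients matter little over the site's temperature range).
Daylength uses solar declination δ = −23.44°·cos(2π(DOY+10)/365) and the
sunset hour angle cos ω₀ = −tan(lat)·tan(δ), clamped so polar day/night
saturate at 24/0 h; validated for |lat| ≤ 66.5°. Climatological seasons
assign December to the DJF of the following year, so seasonal aggregates
use a "season-year"; this choice shifts DJF means slightly relative to a
calendar-year convention and is noted as a reproducibility sensitivity.

Annual NEE uncertainty combines a random component (quadrature sum of
daily random uncertainties, assuming independent errors) and a
u*-filtering component (half the range of annual NEE across the
16th/50th/84th-percentile u*-threshold versions), added in quadrature.

## Season extraction

SOS and EOS are the first and last days of the year where the 10-day
moving average of daily NEE is negative, with a persistence requirement:
the smoothed series must stay negative for at least 14 consecutive days
from SOS onward and up to EOS backward (the boundary day counts toward
its window). Failed candidates are discarded together with the whole
contiguous negative run that contains them, and the search continues
inward — this is equivalent to taking the start of the earliest and the
end of the latest negative run of length ≥ 14, which both guarantees
termination and makes the procedure amenable to exhaustive-search
validation (the test suite checks equivalence with a brute-force oracle
at window 3 / persistence 4 on short series).

Numerical conventions: a smoothed value of exactly 0 counts as
non-negative; CUP length is inclusive (EOS − SOS + 1); the moving average
is trailing (mean over the previous w days including the current one),
with windows truncated at the series edges rather than dropped, so the
year's first days remain valid candidates; windows do not cross Jan 1.
A centered alignment is available by configuration. Years with fewer than
300 valid days (configurable) are rejected; years with no qualifying run
are flagged "no CUP" with undefined dates. Release/uptake-day diagnostics
(days with positive unsmoothed NEE inside the CUP, negative outside) are
computed from the unsmoothed series.

## Trend analyses

Mann–Kendall and Theil–Sen are implemented from first principles:
S = Σ_{i<j} sign(x_j − x_i); Var(S) with tie correction
[n(n−1)(2n+5) − Σ_t t(t−1)(2t+5)]/18; z-score with ±1 continuity
correction; two-sided normal p-value; slope = median of all pairwise
slopes, intercept = median(x_i − slope·t_i). Missing values are removed
while preserving the time spacing of survivors. Tests are two-sided at
α = 0.05 with significance stars at 0.05/0.01. No autocorrelation
correction (pre-whitening) is applied; per-day-of-year counts use raw
p-values, with a Benjamini–Hochberg option off by default, since the
headline quantity is the raw count of significant days.

Annual/seasonal aggregation per variable: mean for state variables; sum
for precipitation, NEE, and freezing hours; annual min of daily minima
(T_min) and max of daily maxima (T_max). Per-DOY trends smooth each
year's series with a trailing 5-day mean first; Feb 29 is dropped before
DOY indexing so DOY 1–365 align across years. Percentile trends use the
linear-interpolation quantile definition (the most common default, but a
known sensitivity between software stacks). Change points use Pettitt's
nonparametric test with p ≈ 2·exp(−6K²/(n³+n²)).

## Driver model and attribution

Predictors are engineered from the met table as original, trailing
moving-average (MA), trailing moving-sum (MS) and lagged versions; the
window statistic is applied first, then the lag, and leading rows without
full history are left missing. The default 21-feature set combines
instantaneous variables with short temperature smooths (sustained warmth
precedes season start in conifers), a cumulative freezing-hours term
(MS15, lag 15), and long-lagged radiation/temperature means (MA30 with
lags of 180 and 365 days) carrying previous-season carryover effects. The
set is configurable via YAML.

The regression model is XGBoost with max_depth 6, learning_rate 0.05,
subsample 0.8, colsample_bytree 0.8 and 300 boosting rounds by default
(an optional 10-fold CV early-stopping mode selects rounds instead; the
fixed default keeps runs fast and deterministic). The train/test split is
random at the day level (75/25, seeded); block-wise splits can be probed
by configuration. Missing predictors (e.g. soil moisture before its
sensor deployment) are passed to the tree learner's default-direction
routing rather than imputed, which allows the full NEE record to be used.

Attributions are path-dependent tree-SHAP values computed by this
package's own double-precision implementation (`fluxphen._treeshap`,
numba-accelerated). XGBoost's built-in `pred_contribs` implements the
same algorithm in float32, whose cross-tree accumulation error (~10⁻⁵
over hundreds of trees) is too large to certify the additivity identity
at 10⁻⁶; the float64 route makes base value + Σ SHAP equal the model
margin to ~10⁻¹⁴, and the native float32 output serves as an independent
cross-check in the tests. Attribution statistics use all days (train and
test); the fit is reported on held-out days only (R², RMSE).

Derived attribution statistics: per-DOY mean SHAP across years (with
per-feature availability windows); favorable ranges as merged runs of
equal-count bins whose mean SHAP is negative; per-feature seasonal mean
SHAP trended across years; and the transition-shift statistic
Δ = median(SHAP, days +1…+10) − median(SHAP, days −10…−1) around SOS/EOS,
median across years (the transition day belongs to neither window; years
without both full windows are skipped). The "strongest interacting
feature" is a descriptive proxy only: the feature whose binned values
most reduce the variance of the focal feature's SHAP values.

## Synthetic generator

Each met variable follows mean + amplitude·cos(2π(DOY−phase)/365) +
trend·(year−start) + AR(1) noise, with the AR(1) process initialised at
its stationary distribution and a single seeded RNG stream per scenario
(same seed ⇒ bit-identical output). Humidity and soil moisture are
clipped to [0, 100] %, precipitation and radiation to ≥ 0, and the
temperature triple is ordered (min ≤ mean ≤ max). Freezing hours per day
come from a triangle-wave diurnal interpolation between the daily min and
max. Feb 29 is generated but flagged so DOY analyses can drop it.

Daily NEE is R − U + ε: respiration R = r0·q10^((T−10)/10) and uptake
U = lue·Rg·ramp(T; t_low, t_opt, t_high)·SWC/(SWC+swc_half), with a
piecewise-linear temperature ramp and AR(1) daily noise ε. Defaults
emulate a cool subalpine spruce site: mean annual temperature 4.3 °C
(amplitude 8 °C), radiation 148 ± 75 W m⁻², r0 = 2 g C m⁻² d⁻¹,
q10 = 2.2, lue = 0.027 g C per W m⁻², ramp −5/12/30 °C, producing one
contiguous uptake season per year from late March to mid-October
(noise-free transitions near DOY 88/290) and an annual sink of roughly
−90 to −250 g C m⁻² yr⁻¹ depending on noise — realistic orders of
magnitude for such a site. Daily NEE noise defaults to 0.5 g C m⁻² d⁻¹
with lag-1 autocorrelation 0.3. An `nee_trend` parameter imposes a linear
annual-sum trend (g C m⁻² yr⁻¹ per year) as a uniform daily offset.

The generator records the zero-crossing days of the noise-free series —
extracted with the same settings as the phenology module — as per-year
ground truth SOS*/EOS*, which makes noise-free recovery tests exact and
noisy recovery quantifiable. Half-hourly disaggregation spreads the
respiration share flat over 24 h and the uptake share as a half-sine over
the daylight window, plus a zero-sum seeded jitter, so the daily integral
round-trips exactly.

What the generator does **not** emulate: weather fronts and synoptic
regimes, gaps and instrument changes, drought/heat extremes, snow-cover
effects, interactions between drivers beyond those in the NEE formula,
and trends in variance. Passing recovery tests therefore demonstrates
correctness of the algorithms under the stated statistical structure, not
performance on every feature of real tower data.

## Problem sizes and numerical choices

The standard study configuration is 26 years of daily data (~9,500 days).
Statistical acceptance checks use: 2000 replicates for the Mann–Kendall
type-I rate (n = 26, expected in [0.03, 0.07]); 100 seeded replicates for
trend-slope recovery (pairs bootstrap, 600 resamples, 95% percentile
interval) and for SOS recovery under noise (median |error| ≤ 5 days);
200 random series for the season-extractor oracle equivalence; and three
pooled seeds of 365 independent null series for the per-DOY false-positive
count (Binomial 99% band). The driver model runs at 300 trees; a full
26-year attribution takes well under a minute.

## Known limitations

- The Mann–Kendall normal approximation is coarse below n ≈ 10 (the test
  suite quantifies the gap against the exact permutation distribution at
  n = 8: within 0.03).
- Percentile trends and seasonal-mean conventions are sensitive to
  quantile definition and season-year assignment; both are documented
  defaults rather than universal standards.
- The driver model is correlational: SHAP attributions describe the
  fitted surrogate, not causal effects, and collinear predictors (e.g.
  radiation vs daylength vs PPFD) share credit in ways that depend on the
  tree structure.
- Pettitt's test assumes a single abrupt change and is approximate for
  short autocorrelated series.
- No GPP/respiration partitioning: all statements concern net exchange.
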