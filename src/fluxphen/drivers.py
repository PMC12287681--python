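"""Gradient-boosted driver model of daily NEE with SHAP attribution.

Daily NEE is modelled from the met table through a configurable set of
engineered predictors — original, trailing-moving-average (MA), trailing-
moving-sum (MS) and lagged versions of each variable — with an XGBoost
regression ensemble.  Per-day, per-feature attributions are exact tree
SHAP values (computed natively by XGBoost via ``pred_contribs``), which
sum to prediction minus base value for every day.  On top of the
attributions sit the summary statistics used for flux interpretation:
mean seasonal-course contributions, favorable feature ranges (where the
binned mean SHAP is negative, i.e. pushes toward net uptake), the
SOS/EOS driver-shift statistic, and cross-year trends of seasonal mean
SHAP values.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd
import xgboost as xgb
import yaml

from fluxphen.flux_io import assign_season
from fluxphen.phenology import PhenologyResult
from fluxphen.trends import TrendResult, mann_kendall

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class FeatureSpec:
    """One engineered predictor: window statistic first, then lag shift.

    ``moving_average`` / ``moving_sum`` use a trailing window over the
    previous ``window`` days including the current day; ``lag`` then shifts
    the column forward in time so day d sees the value of day d - lag.
    Leading rows without full history are left missing.
    """

    name: str
    base_variable: str
    transform: Literal["none", "moving_average", "moving_sum"] = "none"
    window: int = 1
    lag: int = 0

    def __post_init__(self) -> None:
        if self.transform != "none" and self.window < 1:
            raise ValueError(f"{self.name}: window must be >= 1")
        if self.lag < 0:
            raise ValueError(f"{self.name}: lag must be >= 0")


def default_feature_specs() -> list[FeatureSpec]:
    """The default 21-predictor set.

    Combines the instantaneous met variables with short smoothed versions
    of temperature (sustained warmth matters for season start), a
    cumulative freezing-hours predictor, and long-lagged radiation/
    temperature averages that carry previous-season carryover effects.
    """
    f = FeatureSpec
    return [
        f("t_air_mean", "t_air_mean"),
        f("t_air_min", "t_air_min"),
        f("t_air_max", "t_air_max"),
        f("t_air_mean_ma3", "t_air_mean", "moving_average", 3),
        f("t_air_min_ma5", "t_air_min", "moving_average", 5),
        f("hours_below_0", "hours_below_0"),
        f("t_below0_ms15_lag15", "hours_below_0", "moving_sum", 15, 15),
        f("rg", "rg"),
        f("rg_ma30", "rg", "moving_average", 30),
        f("rg_ma30_lag180", "rg", "moving_average", 30, 180),
        f("t_air_mean_ma30_lag180", "t_air_mean", "moving_average", 30, 180),
        f("t_air_mean_ma30_lag365", "t_air_mean", "moving_average", 30, 365),
        f("swc", "swc"),
        f("swc_ma15", "swc", "moving_average", 15),
        f("ppfd", "ppfd"),
        f("daylength", "daylength"),
        f("prec", "prec"),
        f("prec_ms15", "prec", "moving_sum", 15),
        f("rh", "rh"),
        f("vpd", "vpd"),
        f("vpd_ma3", "vpd", "moving_average", 3),
    ]


def load_feature_specs(path: str | Path) -> list[FeatureSpec]:
    """Load feature specs from a YAML list of mappings."""
    raw = yaml.safe_load(Path(path).read_text())
    return [FeatureSpec(**entry) for entry in raw]


def build_features(
    met: pd.DataFrame, specs: Sequence[FeatureSpec] | None = None
) -> pd.DataFrame:
    """Assemble the predictor matrix from a continuous daily met table.

    Transforms cross year boundaries (the met table must be continuous in
    time).  Missing base values propagate into windows containing them.
    """
    if specs is None:
        specs = default_feature_specs()
    cols = {}
    for spec in specs:
        if spec.base_variable not in met.columns:
            raise ValueError(
                f"feature {spec.name!r}: unknown base variable {spec.base_variable!r}"
            )
        s = met[spec.base_variable].astype(float)
        if spec.transform == "moving_average":
            s = s.rolling(spec.window, min_periods=spec.window).mean()
        elif spec.transform == "moving_sum":
            s = s.rolling(spec.window, min_periods=spec.window).sum()
        if spec.lag:
            s = s.shift(spec.lag)
        cols[spec.name] = s
    out = pd.DataFrame(cols, index=met.index)
    out.index.name = "date"
    return out


# ---------------------------------------------------------------------------
# model fitting


DEFAULT_HYPERPARAMS: dict = {
    "max_depth": 6,
    "learning_rate": 0.05,
    "subsample": 0.8,
    "colsample_bytree": 0.8,
    "n_estimators": 300,
}


@dataclass
class FittedModel:
    """Fitted booster plus the feature schema and held-out fit metrics."""

    booster: xgb.Booster
    feature_names: list[str]
    r2: float
    rmse: float
    split_fraction: float
    seed: int
    n_train: int
    n_test: int
    test_index: pd.Index = field(repr=False, default=None)


def train_gbm(
    features: pd.DataFrame,
    target: pd.Series,
    split_fraction: float = 0.75,
    hyperparams: Mapping | None = None,
    seed: int = 0,
    cv_rounds: bool = False,
) -> FittedModel:
    """Fit a gradient-boosted tree model of daily NEE.

    Rows with a missing target are dropped; missing predictors are passed
    through to XGBoost's native default-direction routing (no imputation).
    The train/test split is random at the day level.  With
    ``cv_rounds=True`` the boosting-round count is chosen by 10-fold CV
    early stopping instead of the fixed default.

    Returns the fitted model with held-out R^2 and RMSE.
    """
    y = target.reindex(features.index)
    keep = np.isfinite(y.to_numpy(dtype=float))
    x = features.loc[keep]
    y = y.loc[keep]
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.info("train_gbm: dropped %d rows with missing target", n_dropped)
    if len(x) < 1000:
        logger.warning("train_gbm: only %d rows; fit may be unstable", len(x))

    params = dict(DEFAULT_HYPERPARAMS)
    if hyperparams:
        params.update(hyperparams)
    n_rounds = int(params.pop("n_estimators"))

    rng = np.random.default_rng(seed)
    n = len(x)
    perm = rng.permutation(n)
    n_train = int(round(split_fraction * n))
    train_idx, test_idx = perm[:n_train], perm[n_train:]

    xgb_params = {**params, "objective": "reg:squarederror", "seed": seed}
    dtrain = xgb.DMatrix(
        x.iloc[train_idx], label=y.iloc[train_idx], feature_names=list(x.columns),
        missing=np.nan,
    )
    if cv_rounds:
        cv = xgb.cv(
            xgb_params, dtrain, num_boost_round=2000, nfold=10,
            early_stopping_rounds=25, seed=seed,
        )
        n_rounds = len(cv)
    booster = xgb.train(xgb_params, dtrain, num_boost_round=n_rounds)

    dtest = xgb.DMatrix(
        x.iloc[test_idx], feature_names=list(x.columns), missing=np.nan
    )
    pred = booster.predict(dtest)
    resid = y.iloc[test_idx].to_numpy() - pred
    rmse = float(np.sqrt(np.mean(resid**2)))
    ss_tot = float(np.sum((y.iloc[test_idx] - y.iloc[test_idx].mean()) ** 2))
    r2 = float(1.0 - np.sum(resid**2) / ss_tot) if ss_tot > 0 else np.nan
    return FittedModel(
        booster=booster,
        feature_names=list(x.columns),
        r2=r2,
        rmse=rmse,
        split_fraction=split_fraction,
        seed=seed,
        n_train=len(train_idx),
        n_test=len(test_idx),
        test_index=x.index[test_idx],
    )


# ---------------------------------------------------------------------------
# attribution


@dataclass
class AttributionResult:
    """Per-day, per-feature SHAP attributions in target units (g C m-2 d-1).

    ``shap`` is a date-indexed frame (one column per feature);
    ``base_value`` is the mean model prediction; ``prediction`` the per-day
    model output.  Additivity holds for every day:
    base_value + sum of SHAP = prediction.
    """

    shap: pd.DataFrame
    base_value: float
    prediction: pd.Series
    r2: float
    rmse: float
    seed: int

    def check_additivity(self, rtol: float = 1e-6) -> None:
        """Assert base_value + sum(SHAP) = prediction for every day,
        relative to the per-day prediction magnitude (floored at 1)."""
        shap64 = self.shap.to_numpy(dtype=np.float64)
        total = shap64.sum(axis=1) + self.base_value
        pred = self.prediction.to_numpy(dtype=np.float64)
        err = np.abs(total - pred) / np.maximum(np.abs(pred), 1.0)
        if np.nanmax(err) > rtol:
            raise AssertionError(
                f"SHAP additivity violated: max rel err {np.nanmax(err):.2e}"
            )


def compute_attributions(
    model: FittedModel, features: pd.DataFrame
) -> AttributionResult:
    """Exact tree-path SHAP values for every day (train and test alike).

    Attributions are computed by the double-precision path-dependent
    tree-SHAP in :mod:`fluxphen._treeshap`, so the additivity identity
    holds to float64 round-off.  The booster's native float32
    ``pred_contribs`` implements the same algorithm and serves as an
    independent cross-check in the test suite.
    """
    from fluxphen._treeshap import TreeEnsemble, shap_values

    if list(features.columns) != model.feature_names:
        raise ValueError("feature schema does not match the fitted model")
    ensemble = TreeEnsemble(model.booster)
    x = features.to_numpy(dtype=np.float64)
    phi, base = shap_values(ensemble, x)
    shap_vals = pd.DataFrame(
        phi, index=features.index, columns=model.feature_names
    )
    pred = pd.Series(
        ensemble.predict_margin(x), index=features.index, name="prediction"
    )
    result = AttributionResult(
        shap=shap_vals, base_value=float(base), prediction=pred,
        r2=model.r2, rmse=model.rmse, seed=model.seed,
    )
    result.check_additivity()
    return result


def mean_daily_attribution(
    attr: AttributionResult,
    availability: Mapping[str, tuple[int, int]] | None = None,
) -> pd.DataFrame:
    """Mean SHAP value per DOY (1-365) and feature across years.

    ``availability`` optionally restricts a feature's mean to a year window
    ``(first_year, last_year)`` — e.g. soil moisture measured only from part
    of the record onward.  Feb 29 is dropped before DOY alignment.
    """
    idx = pd.DatetimeIndex(attr.shap.index)
    keep = ~((idx.month == 2) & (idx.day == 29))
    shap = attr.shap[keep]
    idx = idx[keep]
    # DOY rank after leap-day removal so days align across years
    doy = np.concatenate(
        [np.arange(1, g.sum() + 1) for _, g in pd.Series(1, index=idx).groupby(idx.year)]
    )
    years = idx.year

    out = {}
    for feat in shap.columns:
        col = shap[feat]
        if availability and feat in availability:
            lo, hi = availability[feat]
            mask = (years >= lo) & (years <= hi)
        else:
            mask = np.ones(len(col), dtype=bool)
        out[feat] = (
            pd.Series(col.to_numpy()[mask], index=doy[mask]).groupby(level=0).mean()
        )
    table = pd.DataFrame(out).reindex(range(1, 366))
    table.index.name = "doy"
    return table


def favorable_ranges(
    attr: AttributionResult,
    feature_values: pd.Series,
    feature: str,
    n_bins: int = 50,
    min_obs: int = 500,
) -> list[tuple[float, float]]:
    """Feature-value intervals whose binned mean SHAP is negative.

    Negative SHAP pushes the prediction toward net uptake, so these are the
    ranges of the driver that favor carbon uptake.  Bins are equal-count
    over the observed values; contiguous negative-mean bins are merged and
    reported as (lower, upper) bin-boundary pairs.
    """
    shap_col = attr.shap[feature]
    vals = feature_values.reindex(shap_col.index)
    ok = np.isfinite(vals.to_numpy(dtype=float))
    vals, shap_col = vals[ok], shap_col[ok]
    if len(vals) < min_obs:
        raise ValueError(f"{feature}: only {len(vals)} observations (< {min_obs})")

    edges = np.unique(np.quantile(vals, np.linspace(0, 1, n_bins + 1)))
    which = np.clip(np.searchsorted(edges, vals, side="right") - 1, 0, len(edges) - 2)
    means = pd.Series(shap_col.to_numpy()).groupby(which).mean()

    intervals: list[tuple[float, float]] = []
    current = None
    for b in range(len(edges) - 1):
        neg = b in means.index and means[b] < 0
        if neg:
            if current is None:
                current = [edges[b], edges[b + 1]]
            else:
                current[1] = edges[b + 1]
        elif current is not None:
            intervals.append(tuple(current))
            current = None
    if current is not None:
        intervals.append(tuple(current))
    return intervals


def sos_eos_driver_shift(
    attr: AttributionResult,
    phenology: Sequence[PhenologyResult],
    window: int = 10,
) -> pd.DataFrame:
    """Change in each feature's SHAP contribution across SOS and EOS.

    For every year and feature, Delta = median(SHAP on days +1..+window
    after the transition) - median(SHAP on days -window..-1 before it); the
    transition day itself belongs to neither window.  The reported
    statistic is the median Delta across years.  Negative values mean the
    feature's contribution decreased after the transition.  Years without
    a full window on both sides are skipped with a warning.
    """
    idx = pd.DatetimeIndex(attr.shap.index)
    rows: dict[str, dict[str, float]] = {"sos": {}, "eos": {}}
    deltas: dict[str, list[pd.Series]] = {"sos": [], "eos": []}

    for result in phenology:
        if not result.defined:
            continue
        for kind, doy in (("sos", result.sos_doy), ("eos", result.eos_doy)):
            day0 = pd.Timestamp(f"{result.year}-01-01") + pd.Timedelta(days=doy - 1)
            before = attr.shap[(idx >= day0 - pd.Timedelta(days=window)) & (idx < day0)]
            after = attr.shap[(idx > day0) & (idx <= day0 + pd.Timedelta(days=window))]
            if len(before) < window or len(after) < window:
                logger.warning(
                    "%s %d: incomplete +/-%d-day window, year skipped",
                    kind, result.year, window,
                )
                continue
            deltas[kind].append(after.median() - before.median())

    out = {}
    for kind in ("sos", "eos"):
        if not deltas[kind]:
            raise ValueError(f"no year with full windows around {kind.upper()}")
        out[kind] = pd.concat(deltas[kind], axis=1).median(axis=1)
    table = pd.DataFrame(out)
    table.index.name = "feature"
    return table


def seasonal_attribution_trends(
    attr: AttributionResult, season: str, alpha: float = 0.05
) -> dict[str, TrendResult]:
    """Cross-year Mann-Kendall trends of per-feature seasonal mean SHAP."""
    lab = assign_season(pd.DatetimeIndex(attr.shap.index))
    mask = lab["season"].to_numpy() == season
    sub = attr.shap[mask]
    years = lab.loc[mask, "season_year"].to_numpy()
    results = {}
    for feat in sub.columns:
        per_year = pd.Series(sub[feat].to_numpy(), index=years).groupby(level=0).mean()
        if len(per_year) < 10:
            raise ValueError(f"{feat}: fewer than 10 seasonal years")
        results[feat] = mann_kendall(per_year.to_numpy(), alpha=alpha)
    return results


def strongest_interacting_feature(
    attr: AttributionResult,
    feature_matrix: pd.DataFrame,
    focal: str,
    n_bins: int = 10,
) -> str:
    """Descriptive proxy for the focal feature's strongest interaction.

    The feature whose binned values most reduce the variance of the focal
    feature's SHAP values (largest between-bin variance share).
    """
    shap_col = attr.shap[focal].to_numpy()
    best, best_score = None, -np.inf
    for other in feature_matrix.columns:
        if other == focal:
            continue
        vals = feature_matrix[other].reindex(attr.shap.index).to_numpy(dtype=float)
        ok = np.isfinite(vals) & np.isfinite(shap_col)
        if ok.sum() < 10 * n_bins:
            continue
        v, s = vals[ok], shap_col[ok]
        edges = np.unique(np.quantile(v, np.linspace(0, 1, n_bins + 1)))
        if len(edges) < 3:
            continue
        which = np.clip(np.searchsorted(edges, v, side="right") - 1, 0, len(edges) - 2)
        groups = pd.Series(s).groupby(which)
        between = float((groups.mean() ** 2 * groups.size()).sum() / len(s) -
                        (s.mean()) ** 2)
        total = float(s.var())
        score = between / total if total > 0 else 0.0
        if score > best_score:
            best, best_score = other, score
    if best is None:
        raise ValueError("no candidate feature with sufficient data")
    return best
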