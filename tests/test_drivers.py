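import numpy as np
import pandas as pd
import pytest

from fluxphen import synthetic as sy
from fluxphen.drivers import (
    AttributionResult,
    FeatureSpec,
    build_features,
    compute_attributions,
    default_feature_specs,
    favorable_ranges,
    load_feature_specs,
    mean_daily_attribution,
    seasonal_attribution_trends,
    sos_eos_driver_shift,
    strongest_interacting_feature,
    train_gbm,
)
from fluxphen.phenology import PhenologyResult


def naive_feature(values, transform, window, lag):
    """Loop-based oracle for one engineered feature."""
    n = len(values)
    out = np.full(n, np.nan)
    for d in range(n):
        src = d - lag
        if src < 0:
            continue
        if transform == "none":
            out[d] = values[src]
            continue
        if src - window + 1 < 0:
            continue
        block = values[src - window + 1: src + 1]
        out[d] = block.mean() if transform == "moving_average" else block.sum()
    return out


class TestBuildFeatures:
    def test_identity_column(self, met):
        out = build_features(met, [FeatureSpec("x", "rg")])
        assert np.allclose(out["x"], met["rg"])

    def test_moving_sum_of_constant(self):
        idx = pd.date_range("2000-01-01", periods=40, freq="D")
        frame = pd.DataFrame({"v": np.ones(40)}, index=idx)
        out = build_features(frame, [FeatureSpec("ms", "v", "moving_sum", 15)])
        assert out["ms"].iloc[:14].isna().all()
        assert np.allclose(out["ms"].iloc[14:], 15.0)

    def test_ma3_with_lag2_hand_case(self):
        idx = pd.date_range("2000-01-01", periods=6, freq="D")
        frame = pd.DataFrame({"v": [1.0, 2, 3, 4, 5, 6]}, index=idx)
        out = build_features(
            frame, [FeatureSpec("f", "v", "moving_average", 3, lag=2)]
        )
        # MA3 = [nan, nan, 2, 3, 4, 5]; lagged by 2 -> [nan]*4 + [2, 3]
        expected = [np.nan, np.nan, np.nan, np.nan, 2.0, 3.0]
        assert np.allclose(out["f"], expected, equal_nan=True)

    def test_agrees_with_naive_loop_on_random_input(self):
        rng = np.random.default_rng(0)
        idx = pd.date_range("2000-01-01", periods=500, freq="D")
        frame = pd.DataFrame({"v": rng.normal(size=500)}, index=idx)
        cases = [
            ("none", 1, 0), ("none", 1, 15), ("moving_average", 7, 0),
            ("moving_average", 30, 180), ("moving_sum", 15, 15),
        ]
        for transform, window, lag in cases:
            spec = FeatureSpec("f", "v", transform, window, lag)
            got = build_features(frame, [spec])["f"].to_numpy()
            want = naive_feature(frame["v"].to_numpy(), transform, window, lag)
            assert np.allclose(got, want, equal_nan=True), (transform, window, lag)

    def test_unknown_base_variable_raises(self, met):
        with pytest.raises(ValueError, match="nope"):
            build_features(met, [FeatureSpec("f", "nope")])

    def test_default_set_has_21_features(self, met):
        specs = default_feature_specs()
        assert len(specs) == 21
        out = build_features(met, specs)
        assert out.shape[1] == 21

    def test_yaml_spec_round_trip(self, tmp_path):
        import yaml

        specs = [
            {"name": "a", "base_variable": "rg"},
            {"name": "b", "base_variable": "rg", "transform": "moving_sum",
             "window": 15, "lag": 15},
        ]
        path = tmp_path / "features.yaml"
        path.write_text(yaml.safe_dump(specs))
        loaded = load_feature_specs(path)
        assert loaded[1] == FeatureSpec("b", "rg", "moving_sum", 15, 15)


class TestTrainGbm:
    def test_exact_linear_target_fits_nearly_perfectly(self, met):
        feats = build_features(met, [FeatureSpec("rg", "rg"),
                                     FeatureSpec("t", "t_air_mean")])
        target = 0.02 * feats["rg"] - 1.0
        model = train_gbm(feats, target, seed=0)
        assert model.r2 >= 0.99

    def test_shuffled_target_has_no_skill(self, met, daily):
        feats = build_features(met, default_feature_specs())
        rng = np.random.default_rng(0)
        shuffled = pd.Series(
            rng.permutation(daily["nee"].to_numpy()), index=daily.index
        )
        model = train_gbm(feats, shuffled, seed=0)
        assert model.r2 <= 0.1

    def test_split_sizes(self, fitted_model):
        total = fitted_model.n_train + fitted_model.n_test
        assert fitted_model.n_train == round(0.75 * total)

    def test_good_fit_on_default_scenario(self, fitted_model):
        # NEE is a smooth function of the drivers plus AR(1) noise of sd 0.5
        assert fitted_model.r2 > 0.6
        assert fitted_model.rmse < 1.0


class TestComputeAttributions:
    def test_additivity_on_every_day(self, attributions):
        attributions.check_additivity(rtol=1e-6)

    def test_schema_mismatch_raises(self, fitted_model, features):
        wrong = features[list(features.columns[::-1])]
        with pytest.raises(ValueError, match="schema"):
            compute_attributions(fitted_model, wrong)

    def test_depth1_tree_matches_hand_computed_leaf_deviations(self):
        # one binary signal feature, one noise feature; a single depth-1
        # tree with unit learning rate and no regularization recovers the
        # two group means, so SHAP for the split feature must equal the
        # leaf value minus the coverage-weighted mean of the two leaves.
        rng = np.random.default_rng(1)
        n = 2000
        x = (rng.random(n) < 0.5).astype(float)
        noise = rng.normal(size=n)
        idx = pd.date_range("2000-01-01", periods=n, freq="D")
        feats = pd.DataFrame({"signal": x, "noise": noise}, index=idx)
        target = pd.Series(np.where(x > 0.5, 5.0, 1.0), index=idx)
        model = train_gbm(
            feats, target, split_fraction=0.75, seed=0,
            hyperparams={"max_depth": 1, "learning_rate": 1.0,
                         "n_estimators": 1, "subsample": 1.0,
                         "colsample_bytree": 1.0, "reg_lambda": 0.0},
        )
        attr = compute_attributions(model, feats)
        train_mask = ~feats.index.isin(model.test_index)
        x_train = x[train_mask]
        p_hi = x_train.mean()
        v_hi, v_lo = 5.0, 1.0
        base = p_hi * v_hi + (1 - p_hi) * v_lo
        phi_hi = v_hi - base
        phi_lo = v_lo - base
        got = attr.shap["signal"].to_numpy()
        assert np.allclose(got[x > 0.5], phi_hi, atol=1e-4)
        assert np.allclose(got[x <= 0.5], phi_lo, atol=1e-4)
        assert np.allclose(attr.shap["noise"], 0.0, atol=1e-6)
        assert attr.base_value == pytest.approx(base, abs=1e-4)

    def test_constant_target_gives_zero_shap(self):
        rng = np.random.default_rng(2)
        idx = pd.date_range("2000-01-01", periods=1200, freq="D")
        feats = pd.DataFrame({"a": rng.normal(size=1200)}, index=idx)
        target = pd.Series(np.full(1200, 2.5), index=idx)
        model = train_gbm(feats, target, seed=0)
        attr = compute_attributions(model, feats)
        assert np.allclose(attr.shap.to_numpy(), 0.0, atol=1e-6)
        assert attr.base_value == pytest.approx(2.5, abs=1e-5)

    def test_known_drivers_outrank_noise_decoys(self):
        # NEE generated from radiation and temperature only: their summed
        # |SHAP| importance must beat pure-noise decoy features.
        for seed in range(5):
            sc = sy.SyntheticScenario(n_years=8, seed=seed, swc_half=0.001)
            sc.variables["swc"].amplitude = 0.0
            sc.variables["swc"].noise_sd = 0.0
            met = sy.generate_met(sc)
            daily = sy.generate_daily_nee(sc, met)
            rng = np.random.default_rng(100 + seed)
            frame = met[["rg", "t_air_mean"]].copy()
            frame["decoy1"] = rng.normal(size=len(frame))
            frame["decoy2"] = rng.normal(size=len(frame))
            feats = build_features(frame, [
                FeatureSpec("rg", "rg"), FeatureSpec("t", "t_air_mean"),
                FeatureSpec("decoy1", "decoy1"), FeatureSpec("decoy2", "decoy2"),
            ])
            model = train_gbm(feats, daily["nee"], seed=seed)
            attr = compute_attributions(model, feats)
            importance = attr.shap.abs().sum()
            assert min(importance["rg"], importance["t"]) > max(
                importance["decoy1"], importance["decoy2"]
            ), f"seed {seed}"


def make_attr(shap_frame):
    pred = shap_frame.sum(axis=1)
    return AttributionResult(
        shap=shap_frame, base_value=0.0, prediction=pred,
        r2=1.0, rmse=0.0, seed=0,
    )


class TestMeanDailyAttribution:
    def test_two_identical_years_equal_either_year(self):
        idx = pd.date_range("2001-01-01", "2002-12-31", freq="D")
        doy = idx.dayofyear.to_numpy(dtype=float)
        shap = pd.DataFrame({"f": np.sin(doy / 58.0)}, index=idx)
        attr = make_attr(shap)
        table = mean_daily_attribution(attr)
        year1 = shap["f"].iloc[:365].to_numpy()
        assert np.allclose(table["f"].to_numpy(), year1)

    def test_availability_window_restricts_only_that_feature(self):
        idx = pd.date_range("2001-01-01", "2004-12-31", freq="D")
        year = idx.year.to_numpy()
        shap = pd.DataFrame(
            {"a": (year - 2000).astype(float), "b": np.ones(len(idx))}, index=idx
        )
        attr = make_attr(shap)
        table = mean_daily_attribution(attr, availability={"a": (2003, 2004)})
        assert np.allclose(table["a"].dropna(), (3 + 4) / 2)
        assert np.allclose(table["b"], 1.0)


class TestFavorableRanges:
    def _attr_for(self, x, shap_vals):
        idx = pd.date_range("2000-01-01", periods=len(x), freq="D")
        shap = pd.DataFrame({"f": shap_vals}, index=idx)
        return make_attr(shap), pd.Series(x, index=idx)

    def test_parabola_yields_interval_between_roots(self):
        rng = np.random.default_rng(0)
        x = rng.uniform(0, 10, size=4000)
        attr, series = self._attr_for(x, (x - 2.0) * (x - 7.0))
        intervals = favorable_ranges(attr, series, "f", n_bins=50)
        assert len(intervals) == 1
        lo, hi = intervals[0]
        binwidth = 10 / 50 * 2
        assert lo == pytest.approx(2.0, abs=binwidth)
        assert hi == pytest.approx(7.0, abs=binwidth)

    def test_all_negative_shap_is_full_range(self):
        rng = np.random.default_rng(1)
        x = rng.uniform(0, 1, 1000)
        attr, series = self._attr_for(x, np.full(1000, -1.0))
        intervals = favorable_ranges(attr, series, "f")
        assert len(intervals) == 1
        assert intervals[0][0] == pytest.approx(x.min())
        assert intervals[0][1] == pytest.approx(x.max())

    def test_all_positive_shap_no_intervals(self):
        rng = np.random.default_rng(2)
        x = rng.uniform(0, 1, 1000)
        attr, series = self._attr_for(x, np.full(1000, 1.0))
        assert favorable_ranges(attr, series, "f") == []

    def test_insufficient_data_raises(self):
        attr, series = self._attr_for(np.arange(10.0), np.arange(10.0))
        with pytest.raises(ValueError):
            favorable_ranges(attr, series, "f")


class TestDriverShift:
    def _one_year_attr(self, values_by_feature, year=2010):
        idx = pd.date_range(f"{year}-01-01", f"{year}-12-31", freq="D")
        shap = pd.DataFrame(
            {k: v(idx.dayofyear.to_numpy()) for k, v in values_by_feature.items()},
            index=idx,
        )
        return make_attr(shap)

    def test_constant_shap_gives_zero_shift(self):
        attr = self._one_year_attr({"f": lambda d: np.full(len(d), 0.7)})
        pheno = [PhenologyResult(2010, 100, 250, 151)]
        table = sos_eos_driver_shift(attr, pheno)
        assert table.loc["f", "sos"] == pytest.approx(0.0)
        assert table.loc["f", "eos"] == pytest.approx(0.0)

    def test_step_at_sos_recovered_exactly(self):
        attr = self._one_year_attr(
            {"f": lambda d: np.where(d >= 100, -1.0, 0.0)}
        )
        pheno = [PhenologyResult(2010, 100, 250, 151)]
        table = sos_eos_driver_shift(attr, pheno)
        assert table.loc["f", "sos"] == pytest.approx(-1.0)
        assert table.loc["f", "eos"] == pytest.approx(0.0)

    def test_asymmetric_hand_built_medians(self):
        # before SOS (DOY 90..99): values 0..9 -> median 4.5
        # after SOS (DOY 101..110): values 100..109 -> median 104.5
        def f(d):
            out = np.zeros(len(d), dtype=float)
            out[(d >= 90) & (d <= 99)] = d[(d >= 90) & (d <= 99)] - 90
            out[(d >= 101) & (d <= 110)] = d[(d >= 101) & (d <= 110)] - 1
            return out

        attr = self._one_year_attr({"f": f})
        pheno = [PhenologyResult(2010, 100, 250, 151)]
        table = sos_eos_driver_shift(attr, pheno)
        assert table.loc["f", "sos"] == pytest.approx(104.5 - 4.5)

    def test_median_across_years(self):
        frames = []
        for year, level in [(2010, -1.0), (2011, -2.0), (2012, -6.0)]:
            idx = pd.date_range(f"{year}-01-01", f"{year}-12-31", freq="D")
            doy = idx.dayofyear.to_numpy()
            frames.append(
                pd.DataFrame({"f": np.where(doy >= 100, level, 0.0)}, index=idx)
            )
        attr = make_attr(pd.concat(frames))
        pheno = [PhenologyResult(y, 100, 250, 151) for y in (2010, 2011, 2012)]
        table = sos_eos_driver_shift(attr, pheno)
        assert table.loc["f", "sos"] == pytest.approx(-2.0)

    def test_year_without_full_window_skipped(self):
        attr = self._one_year_attr({"f": lambda d: np.zeros(len(d))})
        pheno = [
            PhenologyResult(2010, 5, 250, 246),   # SOS window runs off the record
            PhenologyResult(2011, 100, 250, 151),  # no attribution data at all
        ]
        with pytest.raises(ValueError, match="SOS"):
            sos_eos_driver_shift(attr, pheno)


class TestSeasonalAttributionTrends:
    def test_imposed_summer_drift_detected_only_on_that_feature(self):
        idx = pd.date_range("2000-01-01", "2015-12-31", freq="D")
        year = (idx.year - 2000).to_numpy()
        rng = np.random.default_rng(0)
        drifting = 0.05 * year + rng.normal(0, 0.02, len(idx))
        stationary = rng.normal(0, 0.5, len(idx))
        attr = make_attr(
            pd.DataFrame({"x": drifting, "y": stationary}, index=idx)
        )
        res = seasonal_attribution_trends(attr, "JJA")
        assert res["x"].significant and res["x"].sen_slope > 0
        assert not res["y"].significant


class TestStrongestInteraction:
    def test_recovers_the_modulating_feature(self):
        rng = np.random.default_rng(0)
        n = 3000
        idx = pd.date_range("2000-01-01", periods=n, freq="D")
        mod = rng.normal(size=n)
        other = rng.normal(size=n)
        shap = pd.DataFrame({"focal": 2.0 * mod + rng.normal(0, 0.1, n)}, index=idx)
        feats = pd.DataFrame(
            {"focal": rng.normal(size=n), "mod": mod, "other": other}, index=idx
        )
        attr = make_attr(shap)
        assert strongest_interacting_feature(attr, feats, "focal") == "mod"
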