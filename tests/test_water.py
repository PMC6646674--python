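import numpy as np
import pandas as pd
import pytest

from canopytraits import water


def _profile(thickness=100.0, fc=0.27, wp=0.12):
    return water.SoilProfile([water.Horizon("LA", thickness, fc, wp)])


class TestWhc:
    def test_single_horizon_arithmetic(self):
        assert water.whc(_profile()) == pytest.approx(150.0)

    def test_fc_below_wp_rejected(self):
        with pytest.raises(ValueError):
            water.Horizon("LA", 100.0, 0.12, 0.27)

    def test_zero_thickness_rejected(self):
        with pytest.raises(ValueError):
            water.Horizon("LA", 0.0, 0.27, 0.12)

    def test_platform_range_warning(self):
        with pytest.warns(UserWarning, match="envelope"):
            water.whc(water.SoilProfile([water.Horizon("LA", 30.0, 0.27, 0.12)]))  # 45 mm
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("error")
            water.whc(_profile())  # 150 mm: inside 102-275


class TestBudget:
    def test_ten_days_of_et_from_full_bucket(self):
        ledger = water.WaterLedger(184.0, 184.0)
        for _ in range(10):
            water.step_budget(ledger, 0.0, 0.0, 5.0)
        assert ledger.storage_mm == pytest.approx(134.0)

    def test_overflow_goes_to_drainage(self):
        ledger = water.WaterLedger(100.0, 90.0)
        water.step_budget(ledger, 30.0, 0.0, 0.0)
        assert ledger.storage_mm == 100.0
        assert ledger.rows[-1]["drainage_mm"] == pytest.approx(20.0)

    def test_no_flux_conserves_storage(self):
        ledger = water.WaterLedger(150.0, 80.0)
        water.step_budget(ledger, 0.0, 0.0, 0.0)
        assert ledger.storage_mm == 80.0

    def test_negative_inputs_rejected(self):
        ledger = water.WaterLedger(150.0, 80.0)
        with pytest.raises(ValueError):
            water.step_budget(ledger, -1.0, 0.0, 0.0)

    def test_daily_mass_balance_closes_over_season(self, rng):
        weather = pd.DataFrame(
            {
                "rain_mm": rng.gamma(0.4, 8.0, 200),
                "irrigation_mm": np.where(rng.random(200) < 0.05, 30.0, 0.0),
                "et_mm": rng.uniform(0.5, 6.0, 200),
            }
        )
        ledger = water.run_budget(184.0, 184.0, weather)
        frame = ledger.to_frame()
        prev = np.r_[184.0, frame["storage_mm"].to_numpy()[:-1]]
        delta = frame["storage_mm"].to_numpy() - prev
        closure = (
            frame["rain_mm"] + frame["irrigation_mm"] - frame["et_mm"] - frame["drainage_mm"]
        ).to_numpy()
        np.testing.assert_allclose(delta, closure, atol=1e-12)
        assert (frame["storage_mm"] >= 0).all() and (frame["storage_mm"] <= 184.0).all()


class TestStressFactor:
    @pytest.mark.parametrize("frac,expected", [(1.0, 1.0), (0.0, 0.0), (0.2, 0.5), (0.4, 1.0)])
    def test_piecewise_linear(self, frac, expected):
        assert water.sinclair_stress_factor(frac) == pytest.approx(expected)

    def test_bounds_and_monotonicity(self):
        fracs = np.linspace(0, 1, 50)
        factors = [water.sinclair_stress_factor(f) for f in fracs]
        assert all(0.0 <= f <= 1.0 for f in factors)
        assert np.all(np.diff(factors) >= 0)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            water.sinclair_stress_factor(1.2)


class TestIrrigationTriggers:
    @staticmethod
    def _stage(date):
        return "pre-Z39" if date < 30 else "post-Z39"

    def test_low_tension_no_triggers(self):
        series = water.TensionSeries(60, list(range(10)), [50.0] * 10)
        out = water.irrigation_triggers(series, self._stage)
        assert out.empty

    def test_pre_z39_60cm_threshold_80(self):
        series = water.TensionSeries(60, [10, 20, 25], [70.0, 85.0, 90.0])
        out = water.irrigation_triggers(series, self._stage)
        assert list(out["date"]) == [20, 25]
        assert (out["threshold_cbar"] == 80.0).all()

    def test_post_z39_60cm_threshold_100(self):
        series = water.TensionSeries(60, [40, 50], [90.0, 105.0])
        out = water.irrigation_triggers(series, self._stage)
        assert list(out["date"]) == [50]

    def test_ww_override_80_throughout(self):
        series = water.TensionSeries(60, [40], [90.0])
        out = water.irrigation_triggers(series, self._stage, well_watered=True)
        assert len(out) == 1 and out.iloc[0]["threshold_cbar"] == 80.0

    def test_censored_cap_triggers_with_flag(self):
        series = water.TensionSeries(30, [5], [250.0])
        out = water.irrigation_triggers(series, self._stage)
        assert out.iloc[0]["censored"]
        assert out.iloc[0]["tension_cbar"] == 200.0
        assert out.iloc[0]["water_stress"]

    def test_unknown_stage_rejected(self):
        series = water.TensionSeries(60, [1], [90.0])
        with pytest.raises(ValueError, match="growth period"):
            water.irrigation_triggers(series, lambda d: "Z99")


class TestShelterAccounting:
    def test_interception_efficiency_reported_value(self):
        # outside pluviometers 161-190 mm, ~15 mm under the shelter -> 92%
        eff, profile = water.interception_efficiency(
            [15.0, 14.0, 16.0, 15.0, 15.0], [161.0, 190.0]
        )
        assert round(eff) == 92
        assert profile.shape == (5,)

    def test_no_shelter_zero_efficiency(self):
        eff, _ = water.interception_efficiency([100.0], [100.0])
        assert eff == pytest.approx(0.0)

    def test_perfect_interception(self):
        eff, _ = water.interception_efficiency([0.0], [100.0])
        assert eff == 100.0

    def test_zero_outside_rain_rejected(self):
        with pytest.raises(ValueError):
            water.interception_efficiency([0.0], [0.0])

    def test_degree_day_mean_definition(self):
        assert water.degree_day(20.0, 10.0) == 15.0

    def test_identical_series_no_side_effects(self, rng):
        par = rng.uniform(10, 60, 30)
        tmax, tmin = rng.uniform(15, 25, 30), rng.uniform(5, 12, 30)
        out = water.shelter_side_effects(par, par, tmax, tmin, tmax, tmin)
        assert out["d_cum_par_pct"] == pytest.approx(0.0)
        assert out["d_degree_days_pct"] == pytest.approx(0.0)

    def test_constructed_par_reduction(self, rng):
        par_out = rng.uniform(10, 60, 120)
        par_in = 0.965 * par_out
        tmax, tmin = rng.uniform(15, 25, 120), rng.uniform(5, 12, 120)
        out = water.shelter_side_effects(par_in, par_out, tmax, tmin, tmax, tmin)
        assert out["d_cum_par_pct"] == pytest.approx(-3.5, abs=1e-9)

    def test_misaligned_series_rejected(self):
        with pytest.raises(ValueError):
            water.shelter_side_effects([1.0], [1.0, 2.0], [1.0], [1.0], [1.0], [1.0])


class TestTdrCalibration:
    def test_exact_line(self):
        x = np.array([10.0, 20.0, 30.0, 40.0])
        cal = water.calibrate_tdr(x, 0.9 * x + 2.0)
        assert cal.slope == pytest.approx(0.9)
        assert cal.intercept == pytest.approx(2.0)
        assert cal.r_squared == pytest.approx(1.0)
        assert cal(50.0) == pytest.approx(47.0)

    def test_noisy_slope_within_three_se(self, rng):
        x = rng.uniform(5, 45, 30)
        sigma = 0.5
        y = 0.8 * x + 3.0 + rng.normal(0, sigma, 30)
        cal = water.calibrate_tdr(x, y)
        se = sigma / np.sqrt(np.sum((x - x.mean()) ** 2))
        assert abs(cal.slope - 0.8) < 3 * se

    def test_two_pairs_rejected(self):
        with pytest.raises(ValueError, match=">= 3"):
            water.calibrate_tdr([1.0, 2.0], [1.0, 2.0])

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            water.calibrate_tdr([5.0, 5.0, 5.0], [1.0, 2.0, 3.0])
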