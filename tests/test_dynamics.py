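import numpy as np
import pandas as pd
import pytest

from canopytraits import dynamics
from canopytraits.core import TraitSeries, TrialDesign
from canopytraits.synthetic import gen_trait_season


def _series(days, values):
    return TraitSeries.single("P1", "GF", days, values)


class TestAuc:
    def test_triangle_area(self):
        assert dynamics.auc(_series([0, 1, 2], [0, 1, 0]), (0, 2)) == pytest.approx(1.0)

    def test_rectangle(self):
        s = _series([0, 5, 10], [3.0, 3.0, 3.0])
        assert dynamics.auc(s, (0, 10)) == pytest.approx(30.0)

    def test_against_fine_grid_riemann_oracle(self, rng):
        days = np.sort(rng.choice(np.arange(0, 100), size=6, replace=False)).astype(float)
        vals = rng.uniform(0, 2, 6)
        s = _series(days.tolist(), vals.tolist())
        window = (days[0] + 1.0, days[-1] - 1.0)
        # independent oracle: midpoint Riemann sum of the interpolant on a fine grid
        grid = np.linspace(window[0], window[1], 2_000_001)
        mid = 0.5 * (grid[:-1] + grid[1:])
        oracle = float(np.sum(np.interp(mid, days, vals)) * (grid[1] - grid[0]))
        assert dynamics.auc(s, window) == pytest.approx(oracle, abs=1e-9)

    def test_additivity_over_subintervals(self):
        s = _series([0, 3, 7, 12, 20], [0.1, 0.9, 0.4, 0.8, 0.2])
        whole = dynamics.auc(s, (1, 18))
        split = dynamics.auc(s, (1, 9)) + dynamics.auc(s, (9, 18))
        assert whole == pytest.approx(split, abs=1e-12)

    def test_linearity_in_values(self):
        days = [0, 4, 9, 15]
        v1, v2 = [0.1, 0.5, 0.3, 0.9], [0.7, 0.2, 0.6, 0.1]
        a = dynamics.auc(_series(days, v1), (0, 15))
        b = dynamics.auc(_series(days, v2), (0, 15))
        combo = dynamics.auc(_series(days, (2 * np.array(v1) + 3 * np.array(v2)).tolist()), (0, 15))
        assert combo == pytest.approx(2 * a + 3 * b, abs=1e-12)

    def test_window_outside_support_rejected(self):
        with pytest.raises(ValueError):
            dynamics.auc(_series([0, 5], [1, 1]), (0, 10))


class TestFitCurve:
    def test_linear_interp_reproduces_observations(self):
        days, vals = [0.0, 3.0, 9.0], [0.2, 0.8, 0.5]
        fit = dynamics.fit_curve(_series(days, vals), "linear-interp")
        assert fit.rmse == 0.0
        np.testing.assert_allclose(fit(days), vals)

    def test_logistic_recovers_generating_parameters(self):
        a, k, t0 = 0.9, 0.15, 100.0
        t = np.arange(40.0, 161.0, 8.0)
        v = a / (1 + np.exp(-k * (t - t0)))
        fit = dynamics.fit_curve(_series(t.tolist(), v.tolist()), "logistic")
        assert fit.parameters[0] == pytest.approx(a, rel=0.01)
        assert fit.parameters[1] == pytest.approx(k, rel=0.01)
        assert fit.parameters[2] == pytest.approx(t0, rel=0.01)

    def test_underdetermined_rejected(self):
        with pytest.raises(Exception):
            dynamics.fit_curve(_series([0.0, 1.0], [0.1, 0.2]), "logistic")

    def test_noisy_midpoint_recovery_rate(self):
        # sigma = 5% of range, n = 15 dates: midpoint within 2 days in >= 90% of seeds
        a, k, t0 = 1.0, 0.2, 100.0
        t = np.linspace(60.0, 140.0, 15)
        clean = a / (1 + np.exp(-k * (t - t0)))
        hits = 0
        for seed in range(100):
            noise = np.random.default_rng(seed).normal(0, 0.05, t.shape)
            v = clean + noise
            fit = dynamics.fit_curve((t.tolist(), v.tolist()), "logistic")
            hits += abs(fit.parameters[2] - t0) <= 2.0
        assert hits >= 90


class TestDivergenceOnset:
    def test_identical_series_never_diverge(self):
        s = _series(list(range(0, 100, 5)), [0.5] * 20)
        assert dynamics.divergence_onset(s, s, delta=0.05) is None

    def test_step_divergence_located(self):
        days = list(range(0, 101, 2))
        a = [0.8] * len(days)
        b = [0.8 if d < 40 else 0.4 for d in days]
        onset = dynamics.divergence_onset(_series(days, a), _series(days, b), delta=0.1)
        assert onset == pytest.approx(40, abs=1)

    def test_single_day_spike_filtered_by_persistence(self):
        days = list(range(0, 30))
        a = [0.5] * 30
        b = [0.5] * 30
        b[10] = 0.1
        onset = dynamics.divergence_onset(
            _series(days, a), _series(days, b), delta=0.1, persistence_days=5
        )
        assert onset is None

    def test_symmetry(self):
        sa, _ = gen_trait_season("WW N+", seed=1)
        sb, _ = gen_trait_season("WD N+", seed=2)
        a, b = sa.select(trait="GF"), sb.select(trait="GF")
        assert dynamics.divergence_onset(a, b, 0.1) == dynamics.divergence_onset(b, a, 0.1)

    def test_disjoint_supports_rejected(self):
        a = _series([0, 10], [1, 1])
        b = _series([20, 30], [1, 1])
        with pytest.raises(ValueError):
            dynamics.divergence_onset(a, b, 0.1)


class TestAgronomicArithmetic:
    def test_nabs_zero_yield(self):
        assert dynamics.nitrogen_grain_quantity(0.0, 12.0) == 0.0

    @pytest.mark.parametrize("gy,p,expected", [(8.0, 14.25, 200.0), (5.7, 10.0, 100.0)])
    def test_nabs_unit_factor(self, gy, p, expected):
        assert dynamics.nitrogen_grain_quantity(gy, p) == pytest.approx(expected)

    def test_nabs_literal_formula(self):
        assert dynamics.nitrogen_grain_quantity(5.7, 10.0, literal=True) == pytest.approx(10.0)

    def test_nabs_negative_rejected(self):
        with pytest.raises(ValueError):
            dynamics.nitrogen_grain_quantity(-1.0, 10.0)

    @pytest.mark.parametrize(
        "ref,stress,expected",
        [(11.4, 8.0, 30), (11.4, 9.7, 15), (5.0, 5.0, 0)],
    )
    def test_relative_loss_reported_values(self, ref, stress, expected):
        assert dynamics.relative_loss(ref, stress, digits=0) == expected

    def test_relative_loss_needs_positive_reference(self):
        with pytest.raises(ValueError):
            dynamics.relative_loss(0.0, 1.0)


class TestTreatmentSummary:
    def _endpoints(self, means: dict, n=6, sd=0.3, seed=0):
        rng = np.random.default_rng(seed)
        rows = []
        for (w, nitro), mu in means.items():
            for i in range(n):
                rows.append(
                    {
                        "plot_id": f"{w}{nitro}{i}",
                        "water_treatment": w,
                        "nitrogen_treatment": nitro,
                        "value": rng.normal(mu, sd),
                    }
                )
        return pd.DataFrame(rows)

    def test_same_distribution_shares_letter(self):
        df = self._endpoints({("WW", "N+"): 10.0, ("WW", "N0"): 10.0}, seed=3)
        out = dynamics.treatment_summary(df)
        assert len(set(out["letters"])) == 1

    def test_large_offset_different_letters(self):
        df = self._endpoints({("WW", "N+"): 10.0, ("WD", "N+"): 7.0}, sd=0.3, seed=4)
        out = dynamics.treatment_summary(df)
        a, b = out.set_index("group")["letters"]
        assert set(a) & set(b) == set()

    def test_single_group_gets_a(self):
        df = self._endpoints({("WW", "N+"): 10.0})
        out = dynamics.treatment_summary(df)
        assert list(out["letters"]) == ["a"]

    def test_means_and_se(self):
        df = self._endpoints({("WW", "N+"): 10.0, ("WD", "N+"): 8.0}, n=4, seed=5)
        out = dynamics.treatment_summary(df).set_index("group")
        grp = df[df["water_treatment"] == "WW"]["value"]
        assert out.loc["WW N+", "mean"] == pytest.approx(grp.mean())
        assert out.loc["WW N+", "se"] == pytest.approx(grp.std(ddof=1) / np.sqrt(4))
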