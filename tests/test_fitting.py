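"""Data conditioning and exponential-law calibration."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

import taudamage as td
from taudamage.fitting import DamageProgressionModel, default_age_grid, \
    stage_statistics, stage_years_of_play


class TestSortAndAssignAges:
    def test_ascending(self):
        out = td.sort_and_assign_ages([3, 1, 2], "ascending", [30, 50, 70])
        assert list(out["value"]) == [1, 2, 3]
        assert list(out["time"]) == [30, 50, 70]

    def test_descending(self):
        out = td.sort_and_assign_ages([3, 1, 2], "descending", [30, 50, 70])
        assert list(out["value"]) == [3, 2, 1]

    def test_sorted_input_unchanged(self):
        out = td.sort_and_assign_ages([1, 2, 3], "ascending", [30, 50, 70])
        assert list(out["value"]) == [1, 2, 3]

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            td.sort_and_assign_ages([1, 2], "ascending", [30, 50, 70])

    @given(st.lists(st.floats(0.1, 100), min_size=2, max_size=30))
    def test_sort_is_a_permutation(self, values):
        ages = list(range(len(values)))
        for direction in ("ascending", "descending"):
            out = td.sort_and_assign_ages(values, direction, ages)
            assert sorted(out["value"]) == sorted(values)

    def test_condition_observations_directions(self, rng):
        df = pd.DataFrame({"eta": rng.random(10), "v": rng.random(10),
                           "nnd": rng.random(10), "phi": rng.random(10)})
        out = td.condition_observations(df)
        assert np.all(np.diff(out["eta"]) >= 0)
        assert np.all(np.diff(out["v"]) >= 0)
        assert np.all(np.diff(out["phi"]) >= 0)
        assert np.all(np.diff(out["nnd"]) <= 0)  # NND descends with age
        np.testing.assert_allclose(out["time"], default_age_grid(10))


class TestFitExponential:
    def test_exact_recovery_noiseless(self):
        t = np.arange(5.0)
        fr = td.fit_exponential(t, 2.0 * np.exp(0.5 * t))
        assert fr.coeff == pytest.approx(2.0, rel=1e-12)
        assert fr.exponent == pytest.approx(0.5, rel=1e-12)
        assert fr.r_squared == pytest.approx(1.0)

    def test_constant_series(self):
        fr = td.fit_exponential([0, 1, 2], [3.0, 3.0, 3.0])
        assert fr.coeff == pytest.approx(3.0)
        assert fr.exponent == pytest.approx(0.0, abs=1e-14)

    def test_nonpositive_values_named(self):
        with pytest.raises(ValueError, match=r"indices \[1, 3\]"):
            td.fit_exponential([0, 1, 2, 3], [1.0, 0.0, 2.0, -1.0])

    def test_losses_agree_on_noiseless_data(self):
        t = np.linspace(0, 2, 12)
        y = 0.7 * np.exp(1.3 * t)
        a = td.fit_exponential(t, y, "log_linear_ols")
        b = td.fit_exponential(t, y, "nonlinear_ls")
        assert a.coeff == pytest.approx(b.coeff, rel=1e-6)
        assert a.exponent == pytest.approx(b.exponent, rel=1e-6)


class TestFitAll:
    @pytest.mark.parametrize("preset", ["section31_text", "table1"])
    def test_noiseless_round_trip(self, preset):
        """The pipeline's core recovery surface: refit equals generator."""
        params = td.get_preset(preset)
        obs = td.generate_trajectory(params, np.linspace(0, 1, 76))
        res = td.fit_all(obs, coalescence_source=preset)
        for got, want in ((res.params.eta_coeff, params.eta_coeff),
                          (res.params.M, params.M),
                          (res.params.v_coeff, params.v_coeff),
                          (res.params.Z, params.Z),
                          (res.params.nnd_coeff, params.nnd_coeff),
                          (res.params.Q, params.Q)):
            assert got == pytest.approx(want, rel=1e-6)
        for fr in res.fits.values():
            assert fr.r_squared == pytest.approx(1.0)

    def test_refit_of_prediction_is_idempotent(self, params):
        obs = td.generate_trajectory(params, np.linspace(0, 1, 20))
        res1 = td.fit_all(obs)
        traj = res1.predict(np.linspace(0, 1, 20))
        df = traj.to_frame()[["time", "eta", "v", "nnd"]]
        res2 = DamageProgressionModel(df).fit()
        assert res2.params.M == pytest.approx(res1.params.M, rel=1e-9)
        assert res2.params.nnd_coeff == pytest.approx(res1.params.nnd_coeff, rel=1e-9)

    def test_missing_series_named(self):
        with pytest.raises(ValueError, match="nnd"):
            DamageProgressionModel(pd.DataFrame({"time": [0, 1], "eta": [1, 2],
                                                 "v": [1, 2]}))

    def test_nonpositive_damage_value_rejected(self, params):
        obs = td.generate_trajectory(params, np.linspace(0, 1, 10))
        df = pd.DataFrame({"time": [o.time for o in obs],
                           "eta": [o.nucleation_density for o in obs],
                           "v": [o.damaged_area for o in obs],
                           "nnd": [o.nnd for o in obs]})
        df.loc[4, "v"] = 0.0
        with pytest.raises(ValueError, match="indices"):
            DamageProgressionModel(df).fit()

    def test_monte_carlo_exponent_recovery(self, params):
        """Noisy synthetic nucleation data: median fitted M within 5% of truth."""
        t = np.linspace(0, 1, 76)
        exps = []
        for seed in range(200):
            obs = td.generate_trajectory(params, t, noise_cv=0.1, seed=seed)
            fr = td.fit_exponential(t, [o.nucleation_density for o in obs])
            exps.append(fr.exponent)
        assert abs(np.median(exps) - params.M) / params.M < 0.05

    def test_r_squared_decreases_with_noise(self, params):
        t = np.linspace(0, 1, 76)
        def mean_r2(cv):
            vals = []
            for seed in range(10):
                obs = td.generate_trajectory(params, t, noise_cv=cv, seed=seed)
                vals.append(td.fit_exponential(
                    t, [o.nucleation_density for o in obs]).r_squared)
            return np.mean(vals)
        assert mean_r2(0.0) == pytest.approx(1.0)
        assert mean_r2(0.05) > mean_r2(0.4)

    def test_csv_round_trip_and_summary(self, params, tmp_path):
        obs = td.generate_trajectory(params, np.linspace(0, 1, 30))
        from taudamage.histology import write_observations_csv

        for o, t in zip(obs, np.linspace(0, 1, 30)):
            o.time = t
        write_observations_csv(obs, tmp_path / "obs.csv")
        res = DamageProgressionModel.from_csv(tmp_path / "obs.csv").fit()
        assert res.params.M == pytest.approx(params.M, rel=1e-6)
        text = res.summary()
        assert "nucleation" in text and "R^2" in text


class TestStageStatistics:
    def test_single_stage_is_overall_mean(self, rng):
        df = pd.DataFrame({"eta": rng.random(12), "v": rng.random(12)})
        out = stage_statistics(df, [0, 12])
        assert out.loc[0, "eta"] == pytest.approx(df["eta"].mean())

    def test_linear_ramp_quartile_midpoints(self):
        df = pd.DataFrame({"y": np.arange(8, dtype=float)})
        out = stage_statistics(df, [0, 2, 4, 6, 8])
        np.testing.assert_allclose(out["y"], [0.5, 2.5, 4.5, 6.5])

    def test_matches_group_by_oracle(self, rng):
        df = pd.DataFrame({"a": rng.random(20), "b": rng.random(20)})
        bounds = [0, 5, 9, 16, 20]
        out = stage_statistics(df, bounds)
        labels = np.repeat([1, 2, 3, 4], np.diff(bounds))
        oracle = df.groupby(labels).mean()
        np.testing.assert_allclose(out[["a", "b"]].to_numpy(), oracle.to_numpy())

    def test_empty_stage_rejected(self):
        df = pd.DataFrame({"y": np.arange(5.0)})
        with pytest.raises(ValueError):
            stage_statistics(df, [0, 2, 2, 5])


def test_stage_years_mapping():
    # two-level cohort staging split into four stages: 7/13 and 15/20 years
    assert [stage_years_of_play(k) for k in (1, 2, 3, 4)] == [7, 13, 15, 20]
    with pytest.raises(ValueError):
        stage_years_of_play(5)


def test_default_age_grid_spans_stage_means():
    g = default_age_grid(76)
    assert g[0] == pytest.approx(28.3) and g[-1] == pytest.approx(77.4)
    assert len(g) == 76 and np.all(np.diff(g) > 0)
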