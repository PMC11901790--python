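"""Skill scoring, qualitative bands, OAT sensitivity and the calibrator."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from greenwater.calibrate import (
    ObservationSet,
    calibrate,
    classify_nse,
    nse,
    read_observations,
    sensitivity_rank,
)


class TestNSE:
    def test_perfect_fit(self):
        assert nse([1.0, 2.0, 3.0], [1.0, 2.0, 3.0]) == 1.0

    def test_mean_predictor_scores_zero(self):
        obs = np.array([1.0, 2.0, 3.0, 6.0])
        assert nse(obs, np.full(4, obs.mean())) == pytest.approx(0.0, abs=1e-12)

    def test_hand_computed_example(self):
        # residual SS = 1, anomaly SS = 2 -> NSE = 0.5
        assert nse([1.0, 2.0, 3.0], [1.0, 2.0, 4.0]) == pytest.approx(0.5)

    @given(st.floats(-50.0, 50.0))
    def test_invariant_to_common_shift(self, c):
        obs = np.array([0.2, 0.4, 0.1, 0.6])
        sim = np.array([0.25, 0.35, 0.15, 0.5])
        assert nse(obs + c, sim + c) == pytest.approx(nse(obs, sim), abs=1e-9)

    @given(st.floats(0.1, 20.0))
    def test_invariant_to_common_scale(self, s):
        obs = np.array([0.2, 0.4, 0.1, 0.6])
        sim = np.array([0.25, 0.35, 0.15, 0.5])
        assert nse(obs * s, sim * s) == pytest.approx(nse(obs, sim), abs=1e-9)

    def test_constant_obs_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            nse([2.0, 2.0, 2.0], [1.0, 2.0, 3.0])


class TestBands:
    @pytest.mark.parametrize("value, band", [
        (0.80, "very good"),
        (0.7501, "very good"),
        (0.75, "good"),        # boundary belongs to 'good'
        (0.70, "good"),
        (0.65, "satisfactory"),
        (0.50, "satisfactory"),
        (0.49, "unsatisfactory"),
        (-3.0, "unsatisfactory"),
    ])
    def test_band_edges(self, value, band):
        assert classify_nse(value) == band


class TestSensitivity:
    @staticmethod
    def _linear_runner(params):
        return np.array([10.0 * params["p1"] + 0.1 * params["p2"] + params.get("p3", 0.0) * 0.0])

    def test_analytic_effect_sizes_order_parameters(self):
        ranking = sensitivity_rank(self._linear_runner, {"p1": 0.5, "p2": 0.5},
                                   {"p1": (0.0, 1.0), "p2": (0.0, 1.0)})
        assert list(ranking["parameter"]) == ["p1", "p2"]
        # 10%-of-range perturbation: |dy| = coefficient * 0.1
        assert ranking.loc[0, "score"] == pytest.approx(1.0)
        assert ranking.loc[1, "score"] == pytest.approx(0.01)

    def test_inert_parameter_ranked_last_with_zero_score(self):
        ranking = sensitivity_rank(self._linear_runner,
                                   {"p1": 0.5, "p2": 0.5, "p3": 0.5},
                                   {"p1": (0.0, 1.0), "p2": (0.0, 1.0), "p3": (0.0, 1.0)})
        assert ranking.iloc[-1]["parameter"] == "p3"
        assert ranking.iloc[-1]["score"] == 0.0
        assert sorted(ranking["parameter"]) == ["p1", "p2", "p3"]  # permutation

    def test_failures_recorded_and_remaining_side_used(self):
        def fragile(params):
            if params["p1"] > 0.55:
                raise RuntimeError("blow-up")
            return np.array([10.0 * params["p1"]])

        ranking = sensitivity_rank(fragile, {"p1": 0.5}, {"p1": (0.0, 1.0)})
        assert ranking.loc[0, "failures"] == 1
        assert ranking.loc[0, "score"] == pytest.approx(1.0)

    def test_nominal_outside_range_rejected(self):
        runner = lambda params: np.array([params["p1"]])
        with pytest.raises(ValueError, match="outside"):
            sensitivity_rank(runner, {"p1": 2.0}, {"p1": (0.0, 1.0)})


class _SurrogateRunner:
    """Cheap analytic stand-in for the soil model: theta(t) = f(params)."""

    def __init__(self):
        self.t = np.arange(20, dtype=float)
        self.index = pd.date_range("2019-04-15", periods=20, freq="D")

    def __call__(self, params):
        a, b = params["a"], params["b"]
        theta = pd.DataFrame(
            {20.0: 0.2 + 0.1 * a * np.exp(-self.t / 10.0),
             70.0: 0.25 + 0.05 * b * np.cos(self.t / 5.0)}, index=self.index)
        out = type("Sim", (), {})()
        out.theta = theta
        out.evap = pd.Series(a + 0 * self.t, index=self.index)
        return out


class TestCalibrate:
    def test_recovers_surrogate_truth_from_noise_free_observations(self):
        runner = _SurrogateRunner()
        truth = {"a": 0.6, "b": 0.4}
        obs_sim = runner(truth)
        obs = ObservationSet(theta=obs_sim.theta, evap=obs_sim.evap)
        res = calibrate(runner, obs, {"a": (0.0, 1.0), "b": (0.0, 1.0)},
                        nominal={"a": 0.2, "b": 0.9}, n_screen=16, seed=11)
        assert res.params["a"] == pytest.approx(0.6, abs=0.01)
        assert res.params["b"] == pytest.approx(0.4, abs=0.01)
        assert res.objective > 0.999
        for k, (lo, hi) in {"a": (0.0, 1.0), "b": (0.0, 1.0)}.items():
            assert lo <= res.params[k] <= hi
        assert all(band == "very good" for band in res.bands.values())

    def test_result_never_worse_than_nominal_start(self):
        runner = _SurrogateRunner()
        obs_sim = runner({"a": 0.6, "b": 0.4})
        obs = ObservationSet(theta=obs_sim.theta, evap=obs_sim.evap)
        nominal = {"a": 0.5, "b": 0.5}
        res = calibrate(runner, obs, {"a": (0.0, 1.0), "b": (0.0, 1.0)},
                        nominal=nominal, n_screen=4, seed=2, maxiter=10)
        sim0 = runner(nominal)
        nse0 = np.mean([nse(obs.theta[c], sim0.theta[c]) for c in obs.theta.columns])
        assert res.objective >= nse0 - 1e-12

    def test_too_few_observations_rejected(self):
        runner = _SurrogateRunner()
        obs_sim = runner({"a": 0.6, "b": 0.4})
        obs = ObservationSet(theta=obs_sim.theta.iloc[:3, :1],
                             evap=obs_sim.evap.iloc[:0])
        with pytest.raises(ValueError, match="10 observations"):
            calibrate(runner, obs, {"a": (0.0, 1.0)})


class TestObservationIO:
    def test_roundtrip_with_evaporation_rows(self, tmp_path):
        path = tmp_path / "obs.csv"
        path.write_text(
            "date,depth_cm,value\n"
            "2019-05-01,20,0.25\n2019-05-01,70,0.28\n"
            "2019-05-06,20,0.24\n2019-05-06,70,0.27\n"
            "2019-05-01,evap,1.2\n2019-05-06,evap,0.8\n")
        obs = read_observations(path)
        assert list(obs.theta.columns) == [20.0, 70.0]
        assert obs.evap.tolist() == [1.2, 0.8]

    def test_theta_outside_unit_interval_rejected(self, tmp_path):
        path = tmp_path / "obs.csv"
        path.write_text("date,depth_cm,value\n2019-05-01,20,1.25\n")
        with pytest.raises(ValueError):
            read_observations(path)
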