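"""Storage-change box statistics, dominance thresholds, interception
regression and the pruning trial."""

import numpy as np
import pandas as pd
import pytest

from greenwater.analysis import (
    cumulative_threshold,
    gwa_change_stats,
    gwi_regression,
    lai_pruning_trial,
    predict_gwi,
)
from greenwater.meteo import SeasonCalendar


def _gwc_frame(days=184, year=2019, **cols):
    idx = pd.date_range(f"{year}-04-15", periods=days, freq="D")
    base = {"P_mm": 0.0, "ET0_mm": 1.0, "GW_H_mm": 0.0, "GW_L_mm": 0.0,
            "GW_I_mm": 0.0, "GW_A_mm": 100.0, "runoff_mm": 0.0, "drainage_mm": 0.0}
    base.update(cols)
    return pd.DataFrame(base, index=idx)


class TestBoxStats:
    def test_constant_storage_gives_zero_cells(self, cal_2019):
        stats = gwa_change_stats(_gwc_frame(), cal_2019)
        nonempty = [s for s in stats if s.n > 0]
        assert nonempty
        for s in nonempty:
            assert s.median == 0.0 and s.mean == 0.0

    def test_outlier_flagged_beyond_whiskers(self, cal_2019):
        # five rain-free early-stage changes (1,2,3,4,100): hand quartiles
        # q25=2, q75=4, IQR=2 -> upper whisker limit 7 -> 100 is an outlier
        gwa = np.concatenate([[100.0], 100.0 + np.cumsum([1.0, 2.0, 3.0, 4.0, 100.0])])
        frame = _gwc_frame(days=6, GW_A_mm=gwa)
        stats = gwa_change_stats(frame, cal_2019)
        cell = next(s for s in stats if s.stage == "early" and s.rain_class == "rain-free")
        assert cell.n == 5
        assert cell.q25 == pytest.approx(2.0) and cell.q75 == pytest.approx(4.0)
        assert cell.outliers == (100.0,)
        assert cell.whisker_hi == 4.0  # largest point within 1.5 IQR of the box

    def test_whiskers_stay_within_observed_range(self, rp_forward, cal_2019):
        for s in gwa_change_stats(rp_forward.gwc, cal_2019):
            if s.n:
                assert s.whisker_lo <= s.q25 <= s.median <= s.q75 <= s.whisker_hi

    def test_every_day_lands_in_exactly_one_cell(self, rp_forward, cal_2019):
        stats = gwa_change_stats(rp_forward.gwc, cal_2019)
        assert sum(s.n + len(s.outliers) * 0 for s in stats) == len(rp_forward.gwc) - 1

    def test_short_series_rejected(self, cal_2019):
        with pytest.raises(ValueError):
            gwa_change_stats(_gwc_frame(days=1), cal_2019)


class TestThreshold:
    def test_recovers_constructed_line_intersection(self):
        # cum GW_L = x + 50 (day-one offset), cum GW_H = 2x, x = cum ET0
        # -> crossing at exactly x = 50
        gwl = np.ones(184)
        gwl[0] += 50.0
        fit = cumulative_threshold(_gwc_frame(GW_H_mm=2.0, GW_L_mm=gwl))
        assert fit.status == "crossing"
        assert fit.threshold_mm == pytest.approx(50.0, rel=1e-9)
        assert fit.slope_H == pytest.approx(2.0) and fit.slope_L == pytest.approx(1.0)
        assert fit.r_H == pytest.approx(1.0) and fit.r_L == pytest.approx(1.0)

    def test_dominance_throughout_gives_no_threshold(self):
        # transpiration above evaporation from day one with the larger slope:
        # the lines only meet at x=0, outside the sampled range
        fit = cumulative_threshold(_gwc_frame(GW_H_mm=2.0, GW_L_mm=1.0))
        assert fit.status == "none"
        assert fit.threshold_mm is None

    def test_swapping_components_mirrors_the_fit(self):
        gwl = np.ones(184)
        gwl[0] += 50.0
        a = cumulative_threshold(_gwc_frame(GW_H_mm=2.0, GW_L_mm=gwl))
        b = cumulative_threshold(_gwc_frame(GW_H_mm=gwl, GW_L_mm=2.0))
        assert b.threshold_mm == pytest.approx(a.threshold_mm)
        assert b.slope_H == pytest.approx(a.slope_L)

    def test_identical_series_undefined(self):
        fit = cumulative_threshold(_gwc_frame(GW_H_mm=1.5, GW_L_mm=1.5))
        assert fit.status == "undefined"

    def test_stride_phase_tolerance_on_smooth_series(self):
        # smooth trending components: shifting the 5-day sampling phase by
        # two days moves the fitted crossing only within fit tolerance
        t = np.arange(184, dtype=float)
        frame = _gwc_frame(ET0_mm=2.0, GW_H_mm=0.03 * t, GW_L_mm=1.5 - 0.005 * t)
        x0 = cumulative_threshold(frame, stride=5).threshold_mm
        x1 = cumulative_threshold(frame.iloc[2:], stride=5).threshold_mm
        assert x0 is not None
        assert x1 == pytest.approx(x0, rel=0.05)

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError):
            cumulative_threshold(_gwc_frame(days=8))


def _regression_frame(n, coef=(0.5, 1.0, -1.0), sigma=0.0, seed=0):
    rng = np.random.default_rng(seed)
    idx = pd.date_range("2019-04-15", periods=n, freq="D")
    P = rng.uniform(0.2, 60.0, n)
    lai = rng.uniform(0.2, 4.0, n)
    gwi = coef[0] * P + coef[1] * lai + coef[2] + rng.normal(0.0, sigma, n)
    return pd.DataFrame({"P_mm": P, "LAI": lai, "GW_I_mm": gwi}, index=idx)


class TestGWIRegression:
    def test_exact_recovery_from_noise_free_linear_law(self):
        fits = gwi_regression(_regression_frame(120))
        for fit in fits.values():
            assert fit.coef_P == pytest.approx(0.5, abs=1e-8)
            assert fit.coef_LAI == pytest.approx(1.0, abs=1e-8)
            assert fit.intercept == pytest.approx(-1.0, abs=1e-8)
            assert fit.r2 == pytest.approx(1.0, abs=1e-10)

    def test_groups_partition_rain_days(self):
        frame = _regression_frame(200)
        fits = gwi_regression(frame)
        n_groups = sum(f.n for g, f in fits.items() if g != "whole")
        assert n_groups == fits["whole"].n == len(frame)  # all days rain here

    def test_rain_free_days_excluded(self):
        frame = _regression_frame(100)
        frame.iloc[:30, frame.columns.get_loc("P_mm")] = 0.0
        fits = gwi_regression(frame)
        assert fits["whole"].n == 70

    def test_residuals_orthogonal_to_regressors(self):
        frame = _regression_frame(80, sigma=0.3)
        fit = gwi_regression(frame)["whole"]
        resid = (frame["GW_I_mm"] - predict_gwi(fit.coefs, frame["P_mm"], frame["LAI"]))
        assert float(resid @ frame["P_mm"]) == pytest.approx(0.0, abs=1e-6)
        assert float(resid @ frame["LAI"]) == pytest.approx(0.0, abs=1e-6)
        assert float(resid.sum()) == pytest.approx(0.0, abs=1e-6)

    def test_collinear_design_rejected(self):
        frame = _regression_frame(60)
        frame["LAI"] = 2.0  # constant column collides with the intercept
        with pytest.raises(ValueError, match="collinear"):
            gwi_regression(frame)

    def test_published_heavy_rain_coefficients_reproduce_worked_example(self):
        # grassland heavy-rain law evaluated at the largest moderate-rain
        # depth and unit LAI: 0.034*24.9 + 1.137*1.0 - 0.635 = 1.3486
        assert round(predict_gwi((0.034, 1.137, -0.635), 24.9, 1.0), 1) == 1.3

    def test_noise_rmse_shrinks_with_sample_size(self):
        # coefficient RMSE should fall roughly as n^(-1/2)
        rmse = []
        for n in (50, 200, 800):
            errs = []
            for rep in range(20):
                fit = gwi_regression(_regression_frame(n, sigma=1.0, seed=100 + rep),
                                     min_group_n=10**9)["whole"]
                errs.append((fit.coef_P - 0.5) ** 2 + (fit.coef_LAI - 1.0) ** 2)
            rmse.append(np.sqrt(np.mean(errs)))
        assert rmse[0] > rmse[1] > rmse[2]


class TestPruningTrial:
    MS_HEAVY = (0.034, 1.137, -0.635)

    def test_inverts_published_regression_at_design_rain(self):
        res = lai_pruning_trial(lambda P, L: predict_gwi(self.MS_HEAVY, P, L),
                                P_design=24.9, GWI_target=1.3)
        assert res.status == "ok"
        assert res.lai == pytest.approx(1.0)

    def test_zero_target_returns_grid_minimum(self):
        res = lai_pruning_trial(lambda P, L: predict_gwi((0.5, 1.0, 0.0), P, L),
                                P_design=10.0, GWI_target=0.0)
        assert res.lai == 0.0

    def test_stronger_response_lowers_recommended_lai(self):
        weak = lai_pruning_trial(lambda P, L: predict_gwi(self.MS_HEAVY, P, L),
                                 P_design=24.9, GWI_target=1.3)
        doubled = tuple(2 * c for c in self.MS_HEAVY)
        strong = lai_pruning_trial(lambda P, L: predict_gwi(doubled, P, L),
                                   P_design=24.9, GWI_target=1.3)
        assert strong.lai < weak.lai

    def test_unreachable_target_reports_attainable_extremum(self):
        res = lai_pruning_trial(lambda P, L: 0.1 * L, P_design=24.9,
                                GWI_target=50.0, lai_max=4.0)
        assert res.status == "unreachable"
        assert res.attainable_max == pytest.approx(0.4)

    def test_non_monotone_response_rejected(self):
        with pytest.raises(ValueError, match="monotone"):
            lai_pruning_trial(lambda P, L: -L, P_design=10.0, GWI_target=0.5)
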