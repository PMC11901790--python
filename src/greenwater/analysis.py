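"""Statistical layer over the daily green-water component series.

Four analyses:

* box statistics of daily changes in available storage (dGW_A) grouped
  by growth stage and rainfall class (1.5-IQR whisker convention);
* the ET0-dominance threshold: ordinary least-squares lines through
  5-day-sampled cumulative GW_H and GW_L versus cumulative ET0, whose
  intersection marks where transpiration overtakes evaporation as the
  dominant green-water expenditure;
* multivariate linear regression GW_I ~ P + LAI per rainfall group
  (light / moderate / heavy+rainstorm / whole) with t-statistics and
  two-tier significance flags;
* an LAI-pruning trial: the smallest LAI on a 0.1-step grid whose
  predicted interception still reaches a target depth at a design
  rainfall, answering how far a canopy can be thinned while keeping its
  erosion-protective interception.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .meteo import SeasonCalendar, classify_rainfall_series, growth_stage_series, merge_heavy

__all__ = [
    "BoxStats",
    "ThresholdFit",
    "RegressionFit",
    "GWIRegression",
    "PruningResult",
    "gwa_change_stats",
    "cumulative_threshold",
    "gwi_regression",
    "predict_gwi",
    "lai_pruning_trial",
]

STAGES = ("early", "middle", "late")
GWA_CLASSES = ("rain-free", "light", "moderate", "heavy+")


@dataclass(frozen=True)
class BoxStats:
    """Box-plot statistics of one (stage, rainfall-class) cell of dGW_A."""

    stage: str
    rain_class: str
    n: int
    mean: float
    median: float
    q25: float
    q75: float
    whisker_lo: float
    whisker_hi: float
    outliers: tuple


@dataclass(frozen=True)
class ThresholdFit:
    """Fitted cumulative GW_H / GW_L lines against cumulative ET0."""

    slope_H: float
    intercept_H: float
    r_H: float
    slope_L: float
    intercept_L: float
    r_L: float
    threshold_mm: float | None  # cumulative-ET0 abscissa of the crossing
    status: str                 # 'crossing', 'none' or 'undefined'


@dataclass(frozen=True)
class RegressionFit:
    """One GW_I ~ P + LAI ordinary-least-squares fit."""

    group: str
    n: int
    coef_P: float
    coef_LAI: float
    intercept: float
    r2: float
    t_P: float
    t_LAI: float
    t_const: float
    sig_P: str
    sig_LAI: str
    sig_const: str

    @property
    def coefs(self) -> tuple[float, float, float]:
        return (self.coef_P, self.coef_LAI, self.intercept)


GWIRegression = dict  # group label -> RegressionFit


@dataclass(frozen=True)
class PruningResult:
    lai: float | None
    predicted_GWI: float | None
    status: str  # 'ok', 'unreachable'
    attainable_max: float


def gwa_change_stats(gwc: pd.DataFrame, cal: SeasonCalendar) -> list[BoxStats]:
    """Box statistics of daily dGW_A per growth stage and rainfall class.

    The storage change over day t, GW_A(t) - GW_A(t-1), is attributed to
    day t's rainfall class and growth stage.  Heavy rain and rainstorm
    days are pooled.  Whiskers extend to the most extreme data point
    within 1.5 IQR of the box edges; points beyond are listed as
    outliers.  Empty cells are reported with n = 0.
    """
    if len(gwc) < 2:
        raise ValueError("need at least two days to compute storage changes")
    dgwa = gwc["GW_A_mm"].diff().iloc[1:]
    days = gwc.index[1:]
    classes = classify_rainfall_series(gwc["P_mm"].iloc[1:]).map(merge_heavy)
    stages = growth_stage_series(days, cal)

    out = []
    for stage in STAGES:
        for rc in GWA_CLASSES:
            vals = dgwa[(stages.to_numpy() == stage) & (classes.to_numpy() == rc)].to_numpy()
            if vals.size == 0:
                out.append(BoxStats(stage, rc, 0, np.nan, np.nan, np.nan, np.nan,
                                    np.nan, np.nan, ()))
                continue
            q25, med, q75 = np.percentile(vals, [25, 50, 75])
            iqr = q75 - q25
            lo_lim, hi_lim = q25 - 1.5 * iqr, q75 + 1.5 * iqr
            inside = vals[(vals >= lo_lim) & (vals <= hi_lim)]
            outliers = tuple(np.sort(vals[(vals < lo_lim) | (vals > hi_lim)]))
            out.append(BoxStats(
                stage, rc, int(vals.size), float(vals.mean()), float(med),
                float(q25), float(q75), float(inside.min()), float(inside.max()),
                outliers,
            ))
    return out


def _ols_line(x: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    slope, intercept = np.polyfit(x, y, 1)
    r = np.corrcoef(x, y)[0, 1] if np.std(y) > 0 else np.nan
    return float(slope), float(intercept), float(r)


def cumulative_threshold(gwc: pd.DataFrame, stride: int = 5) -> ThresholdFit:
    """ET0 abscissa where cumulative transpiration overtakes evaporation.

    Cumulative GW_H, GW_L and ET0 are sampled every ``stride`` days from
    the season start; a straight line is fitted through each component's
    (cum ET0, cum component) points and the intersection abscissa is
    returned when it falls inside the sampled cumulative-ET0 range.
    """
    cum = gwc[["GW_H_mm", "GW_L_mm", "ET0_mm"]].cumsum()
    samples = cum.iloc[::stride]
    if len(samples) < 3:
        raise ValueError("need at least three sampled points for the threshold fit")
    x = samples["ET0_mm"].to_numpy()
    sH, iH, rH = _ols_line(x, samples["GW_H_mm"].to_numpy())
    sL, iL, rL = _ols_line(x, samples["GW_L_mm"].to_numpy())
    if np.isclose(sH, sL) and np.isclose(iH, iL):
        return ThresholdFit(sH, iH, rH, sL, iL, rL, None, "undefined")
    if np.isclose(sH, sL):
        return ThresholdFit(sH, iH, rH, sL, iL, rL, None, "none")
    x_cross = (iL - iH) / (sH - sL)
    if x.min() <= x_cross <= x.max():
        return ThresholdFit(sH, iH, rH, sL, iL, rL, float(x_cross), "crossing")
    return ThresholdFit(sH, iH, rH, sL, iL, rL, None, "none")


def _sig_flag(p: float) -> str:
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


def _fit_group(label: str, df: pd.DataFrame) -> RegressionFit:
    X = sm.add_constant(df[["P_mm", "LAI"]].to_numpy(dtype=float), has_constant="add")
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError(f"rank-deficient design in group {label!r}: "
                         "P and LAI (with constant) are collinear")
    model = sm.OLS(df["GW_I_mm"].to_numpy(dtype=float), X).fit()
    const, bP, bLAI = model.params
    t_const, t_P, t_LAI = model.tvalues
    p_const, p_P, p_LAI = model.pvalues
    return RegressionFit(
        group=label, n=int(model.nobs), coef_P=float(bP), coef_LAI=float(bLAI),
        intercept=float(const), r2=float(model.rsquared),
        t_P=float(t_P), t_LAI=float(t_LAI), t_const=float(t_const),
        sig_P=_sig_flag(p_P), sig_LAI=_sig_flag(p_LAI), sig_const=_sig_flag(p_const),
    )


def gwi_regression(daily: pd.DataFrame, min_group_n: int = 5) -> GWIRegression:
    """GW_I ~ P + LAI ordinary least squares per rainfall group.

    ``daily`` needs columns P_mm, LAI and GW_I_mm.  Rain-free days are
    excluded; heavy-rain and rainstorm days are pooled.  Groups with
    fewer than ``min_group_n`` days are skipped; the pooled 'whole' fit
    over all rain days is always attempted.
    """
    classes = classify_rainfall_series(daily["P_mm"]).map(merge_heavy)
    rain = daily[classes != "rain-free"]
    rain_classes = classes[classes != "rain-free"]
    if len(rain) < 5:
        raise ValueError(f"need at least 5 rain days, got {len(rain)}")
    fits: GWIRegression = {}
    for group in ("light", "moderate", "heavy+"):
        sub = rain[rain_classes == group]
        if len(sub) >= min_group_n:
            fits[group] = _fit_group(group, sub)
    fits["whole"] = _fit_group("whole", rain)
    return fits


def predict_gwi(coefs: tuple[float, float, float], P: float, LAI: float) -> float:
    """Interception predicted by a fitted (coef_P, coef_LAI, intercept) law."""
    bP, bLAI, c = coefs
    return bP * P + bLAI * LAI + c


def lai_pruning_trial(
    response,
    P_design: float,
    GWI_target: float,
    lai_max: float = 6.0,
    lai_step: float = 0.1,
) -> PruningResult:
    """Smallest LAI keeping predicted interception at or above a target.

    ``response(P, LAI) -> GW_I`` may be a fitted regression (wrap
    ``predict_gwi``) or a full-model runner.  The response must be
    monotone increasing in LAI at the design rainfall (checked on the
    grid).  Scans LAI upward at ``lai_step`` resolution and returns the
    first grid value whose response reaches the target; if the target is
    unreachable the attainable maximum is reported.
    """
    grid = np.round(np.arange(0.0, lai_max + lai_step / 2, lai_step), 10)
    vals = np.array([response(P_design, l) for l in grid], dtype=float)
    if np.any(np.diff(vals) < -1e-9):
        raise ValueError("response is not monotone increasing in LAI at the design rainfall")
    reach = np.nonzero(vals >= GWI_target - 1e-12)[0]
    if reach.size == 0:
        return PruningResult(lai=None, predicted_GWI=None, status="unreachable",
                             attainable_max=float(vals.max()))
    i = int(reach[0])
    return PruningResult(lai=float(grid[i]), predicted_GWI=float(vals[i]),
                         status="ok", attainable_max=float(vals.max()))
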