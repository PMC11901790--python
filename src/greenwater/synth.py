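"""Synthetic plot-season data: weather, LAI phenology and observation sets.

The generator emulates a semi-arid loess-tableland growing season
(15 April - 15 October): season rainfall around 480-660 mm concentrated
in July-September, dominated by light and moderate events; sinusoidal
temperature and net-radiation annual cycles; and TDR-style soil-moisture
observations at 20/70/160 cm on a ~5-day calendar densified after
sizeable rain, with additive Gaussian noise.

Rainfall occurrence is a per-month Bernoulli wet-day draw; event depths
come from a two-component exponential mixture (a light-event bulk and a
heavier tail) whose monthly means are scaled so the expected season
total matches the requested value.  All randomness flows from a single
integer seed.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .calibrate import ObservationSet
from .forward import ForwardResult, run_forward, OBS_DEPTHS_CM, default_initial_theta
from .meteo import SeasonCalendar
from .richards import SolverConfig
from .templates import PlotTemplate, species_templates

__all__ = [
    "WeatherGenSpec",
    "TruthRun",
    "gen_weather",
    "gen_lai",
    "observation_calendar",
    "make_truth_run",
    "species_templates",
]

_DEF_WET_PROB = {4: 0.25, 5: 0.30, 6: 0.30, 7: 0.45, 8: 0.45, 9: 0.40, 10: 0.25}
_DEF_REL_DEPTH = {4: 3.0, 5: 5.0, 6: 6.0, 7: 10.0, 8: 10.0, 9: 8.0, 10: 4.0}


@dataclass(frozen=True)
class WeatherGenSpec:
    """Parameters of the stochastic daily weather generator."""

    seed: int = 0
    year: int = 2019
    season_total_mm: float = 560.0       # expected season rainfall
    wet_prob: dict = field(default_factory=lambda: dict(_DEF_WET_PROB))
    rel_depth: dict = field(default_factory=lambda: dict(_DEF_REL_DEPTH))
    heavy_frac: float = 0.2              # weight of the heavier exponential tail
    heavy_mult: float = 3.0              # tail mean multiplier
    t_mean: float = 15.0                 # degC annual-cycle midline
    t_amp: float = 9.0
    t_phase_doy: int = 105               # sin() zero-crossing day of year
    t_sigma: float = 1.5
    rn_mean: float = 11.0                # MJ m-2 d-1
    rn_amp: float = 5.0
    rn_sigma: float = 1.5
    u2_range: tuple = (0.5, 3.0)
    rh_base: float = 0.55
    rh_wet_boost: float = 0.20
    rh_sigma: float = 0.07

    def __post_init__(self) -> None:
        if self.season_total_mm <= 0:
            raise ValueError("season rainfall total must be positive")
        for m, p in self.wet_prob.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"wet-day probability for month {m} outside [0, 1]")


def gen_weather(spec: WeatherGenSpec) -> pd.DataFrame:
    """Generate one season of daily weather (reproducible given the seed)."""
    rng = np.random.default_rng(spec.seed)
    cal = SeasonCalendar(spec.year)
    dates = cal.dates()
    months = dates.month.to_numpy()
    doy = dates.dayofyear.to_numpy()

    # scale monthly mean depths so the expected season total matches
    expected_unit = sum(spec.wet_prob.get(m, 0.0) * spec.rel_depth.get(m, 0.0)
                        for m in months)
    scale = spec.season_total_mm / expected_unit if expected_unit > 0 else 0.0

    p_wet = np.array([spec.wet_prob.get(m, 0.0) for m in months])
    wet = rng.random(dates.size) < p_wet
    mean_depth = scale * np.array([spec.rel_depth.get(m, 0.0) for m in months])
    # exponential mixture with matched mean: bulk mean m1, tail mean mult*m1
    m1 = mean_depth / (1.0 - spec.heavy_frac + spec.heavy_frac * spec.heavy_mult)
    tail = rng.random(dates.size) < spec.heavy_frac
    depth = rng.exponential(np.where(tail, spec.heavy_mult, 1.0) * np.maximum(m1, 1e-9))
    P = np.where(wet, np.maximum(np.round(depth, 1), 0.1), 0.0)

    phase = np.sin(2.0 * np.pi * (doy - spec.t_phase_doy) / 365.0)
    T = spec.t_mean + spec.t_amp * phase + rng.normal(0.0, spec.t_sigma, dates.size)
    Rn = np.clip(spec.rn_mean + spec.rn_amp * phase
                 + rng.normal(0.0, spec.rn_sigma, dates.size), 0.5, None)
    Rn = np.where(wet, 0.7 * Rn, Rn)  # cloudy on rain days
    U2 = rng.uniform(*spec.u2_range, dates.size)
    RH = np.clip(spec.rh_base + spec.rh_wet_boost * wet
                 + rng.normal(0.0, spec.rh_sigma, dates.size), 0.2, 0.98)

    out = pd.DataFrame({
        "P_mm": P, "T_C": np.round(T, 2), "U2_ms": np.round(U2, 2),
        "Rn_MJ_m2_d": np.round(Rn, 2), "G_MJ_m2_d": 0.0, "RH": np.round(RH, 3),
    }, index=dates)
    out.index.name = "date"
    return out


def gen_lai(template: PlotTemplate, cal: SeasonCalendar) -> pd.Series:
    """Daily LAI from the template's phenology anchors (+ cutting events).

    Anchors are linearly interpolated to the daily calendar.  Each cutting
    event drops LAI by the stated retained fraction on its day, with the
    deficit fading linearly back to the phenology curve over 30 days
    (regrowth).
    """
    dates = cal.dates()
    t_anchor, v_anchor = [], []
    for month, day, v in template.lai_anchors:
        t_anchor.append(pd.Timestamp(_dt.date(cal.year, month, day)).value)
        v_anchor.append(v)
    lai = np.interp(dates.view("int64").astype(float),
                    np.array(t_anchor, dtype=float), np.array(v_anchor, dtype=float))
    for month, day, retained in template.lai_cuts:
        cut = pd.Timestamp(_dt.date(cal.year, month, day))
        i = int(dates.searchsorted(cut))
        if i <= 0 or i >= dates.size:
            continue
        deficit = (1.0 - retained) * lai[i]
        recover = 30
        fade = deficit * np.maximum(1.0 - np.arange(dates.size - i) / recover, 0.0)
        lai[i:] = np.maximum(lai[i:] - fade, 0.01)
    return pd.Series(np.round(lai, 3), index=dates, name="LAI")


def observation_calendar(weather: pd.DataFrame, every_days: int = 5,
                         rain_trigger_mm: float = 10.0) -> pd.DatetimeIndex:
    """Observation days: a fixed stride plus the day after sizeable rain."""
    idx = weather.index
    regular = idx[::every_days]
    after_rain = idx[1:][weather["P_mm"].to_numpy()[:-1] >= rain_trigger_mm]
    return regular.union(after_rain)


@dataclass
class TruthRun:
    """A forward run with known parameters plus its noisy observations."""

    template: PlotTemplate
    params: dict
    forward: ForwardResult
    observations: ObservationSet


def make_truth_run(
    template: PlotTemplate,
    weather: pd.DataFrame,
    sigma_theta: float = 0.0,
    sigma_evap: float = 0.0,
    seed: int = 0,
    solver: SolverConfig | None = None,
) -> TruthRun:
    """Run the forward model and sample synthetic observations from it.

    Water content is observed at 20/70/160 cm on the observation calendar
    and soil evaporation daily at the same dates, each with additive
    Gaussian noise of the stated standard deviations (0 reproduces the
    model output exactly).  The generating parameters are returned for
    recovery scoring.
    """
    cal = SeasonCalendar(weather.index[0].year)
    lai = gen_lai(template, cal).reindex(weather.index)
    if lai.isna().any():
        raise ValueError("weather table extends outside the growing season")
    fwd = run_forward(template, weather, lai, solver=solver)
    obs_days = observation_calendar(weather)
    rng = np.random.default_rng(seed)

    theta = fwd.theta.loc[obs_days].copy()
    if sigma_theta > 0:
        theta += rng.normal(0.0, sigma_theta, theta.shape)
    tr_floor = 1e-4
    theta = theta.clip(lower=tr_floor, upper=1.0 - tr_floor)
    evap = fwd.evap.loc[obs_days].copy()
    if sigma_evap > 0:
        evap = (evap + rng.normal(0.0, sigma_evap, evap.shape)).clip(lower=0.0)
    obs = ObservationSet(theta=theta, evap=evap)
    return TruthRun(template=template, params=template.param_dict(),
                    forward=fwd, observations=obs)
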