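"""End-to-end forward model for one plot-season.

Chains the process stages: reference evapotranspiration from daily
weather, Beer-law partition into potential transpiration/evaporation
using the plot's LAI, canopy interception of rainfall (net rainfall
drives infiltration), the Richards soil-water integration, and the
green-water component separation.  The same chain backs the pipeline,
the calibration runner and the sensitivity analysis.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import canopy as _canopy
from .gwc import separate_components
from .meteo import reference_et0, validate_weather
from .richards import SimulationResult, SolverConfig, simulate_profile
from .templates import PlotTemplate

__all__ = ["ForwardResult", "run_forward", "CalibrationRunner", "SensitivityRunner",
           "OBS_DEPTHS_CM", "default_initial_theta"]

#: observation depths (cm) representing the three soil layers
OBS_DEPTHS_CM = (20.0, 70.0, 160.0)


@dataclass
class ForwardResult:
    """All artefacts of one forward plot-season run."""

    template: PlotTemplate
    weather: pd.DataFrame
    et0: pd.Series            # mm/day
    lai: pd.Series
    canopy_daily: pd.DataFrame  # GW_I_mm, P_net_mm, LAI per day
    sim: SimulationResult
    gwc: pd.DataFrame         # daily green-water components

    @property
    def theta(self) -> pd.DataFrame:
        """Simulated water content at the standard observation depths."""
        return pd.DataFrame({d: self.sim.theta_at(d) for d in OBS_DEPTHS_CM})

    @property
    def evap(self) -> pd.Series:
        return self.sim.daily["E_mm"].rename("evap_mm")


def default_initial_theta(template: PlotTemplate, fraction_of_fc: float = 0.85) -> np.ndarray:
    """Per-layer initial water content: a spring profile near field capacity."""
    return np.array([fraction_of_fc * tf for tf in template.field_capacity()])


def run_forward(
    template: PlotTemplate,
    weather: pd.DataFrame,
    lai: pd.Series,
    theta_init=None,
    solver: SolverConfig | None = None,
    partition_convention: str = "conventional",
) -> ForwardResult:
    """Run the full forward chain for one plot over one season."""
    validate_weather(weather)
    if len(lai) != len(weather) or not (lai.index == weather.index).all():
        raise ValueError("LAI series must be daily and aligned with the weather table")
    et0 = reference_et0(weather)
    cp = template.canopy

    n = len(weather)
    tp = np.empty(n)
    ep = np.empty(n)
    gwi = np.empty(n)
    pnet = np.empty(n)
    lai_v = lai.to_numpy(dtype=float)
    p_v = weather["P_mm"].to_numpy(dtype=float)
    for i in range(n):
        part = _canopy.partition_et0(float(et0.iloc[i]), lai_v[i], cp,
                                     convention=partition_convention)
        tp[i], ep[i] = part.Tp, part.Ep
        terms = _canopy.interception(p_v[i], lai_v[i], cp)
        gwi[i], pnet[i] = terms.GW_I, terms.P_net

    canopy_daily = pd.DataFrame(
        {"GW_I_mm": gwi, "P_net_mm": pnet, "LAI": lai_v}, index=weather.index)
    forcing = pd.DataFrame(
        {"P_net_mm": pnet, "Ep_mm": ep, "Tp_mm": tp}, index=weather.index)

    if theta_init is None:
        theta_init = default_initial_theta(template)
    sim = simulate_profile(template.build_column(), forcing, theta_init, solver)
    gwc = separate_components(sim, canopy_daily, et0, weather["P_mm"])
    return ForwardResult(template=template, weather=weather, et0=et0, lai=lai,
                         canopy_daily=canopy_daily, sim=sim, gwc=gwc)


class CalibrationRunner:
    """Callable model runner mapping a parameter dict to simulated series.

    Fixes the weather, LAI and initial state of one plot-season; each call
    rebuilds the template with the free parameters overridden and returns
    the ForwardResult, whose ``theta``/``evap`` attributes feed the NSE
    scoring in :func:`greenwater.calibrate.calibrate`.
    """

    def __init__(self, template: PlotTemplate, weather: pd.DataFrame, lai: pd.Series,
                 theta_init=None, solver: SolverConfig | None = None):
        self.template = template
        self.weather = weather
        self.lai = lai
        self.theta_init = theta_init
        self.solver = solver

    def __call__(self, params: dict) -> ForwardResult:
        t = self.template.with_params(**params)
        return run_forward(t, self.weather, self.lai,
                           theta_init=self.theta_init, solver=self.solver)


class SensitivityRunner(CalibrationRunner):
    """Runner variant returning the stacked water-content output.

    The scored output is the simulated theta series at the three
    observation depths, which is what the NSE calibration compares.
    """

    def __call__(self, params: dict) -> np.ndarray:
        res = super().__call__(params)
        return res.theta.to_numpy().ravel()
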