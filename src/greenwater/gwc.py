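"""Green-water component separation and bookkeeping.

Precipitation-derived ("green") water is split into four components on a
daily calendar:

* GW_H — high-efficiency green water: actual plant transpiration (mm/day),
* GW_L — low-efficiency green water: actual soil evaporation (mm/day),
* GW_I — ineffective green water: canopy-intercepted rainfall (mm/day),
* GW_A — available green-water storage: profile soil water in excess of
  the wilting-point stock (mm), evaluated over fifteen layers (ten 10-cm
  layers over 0-100 cm, five 20-cm layers over 100-200 cm, mirroring the
  field measurement depths).

The wilting stock of each evaluation layer is the retention curve
evaluated at the wilting pressure head h3, times the layer thickness;
per-layer deficits below wilting are floored at zero since that water is
unavailable to plants.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .richards import MM_PER_CM, SimulationResult
from .soilwater import SoilColumn, vgm_retention

__all__ = [
    "default_evaluation_layers",
    "available_green_water",
    "available_green_water_series",
    "separate_components",
    "seasonal_totals",
]


def default_evaluation_layers() -> list[tuple[float, float]]:
    """The 15 storage-evaluation layers over 0-200 cm (cm bounds)."""
    layers = [(10.0 * i, 10.0 * (i + 1)) for i in range(10)]
    layers += [(100.0 + 20.0 * i, 120.0 + 20.0 * i) for i in range(5)]
    return layers


def _layer_mean_theta(theta: np.ndarray, z: np.ndarray, z0: float, z1: float) -> float:
    """Mean water content of [z0, z1] from nodal values (interpolated)."""
    zz = np.linspace(z0, z1, max(int(round(z1 - z0)) + 1, 2))
    return float(np.mean(np.interp(zz, z, theta)))


def available_green_water(
    theta: np.ndarray,
    z: np.ndarray,
    column: SoilColumn,
    layers: list[tuple[float, float]] | None = None,
) -> tuple[float, pd.DataFrame]:
    """Available green-water storage GW_A (mm) and its per-layer detail.

    ``theta`` is a nodal water-content profile on depths ``z`` (cm).
    Returns the total and a table with stored water SW_i, wilting stock
    W_w_i and the floored contribution per evaluation layer.
    """
    layers = layers or default_evaluation_layers()
    params = column.node_params()
    tr, ts = np.asarray(params[0]), np.asarray(params[1])
    theta = np.asarray(theta, dtype=float)
    if np.any(theta < tr - 1e-9) or np.any(theta > ts + 1e-9):
        raise ValueError("water-content profile outside [theta_r, theta_s]")

    records = []
    for z0, z1 in layers:
        thick_mm = (z1 - z0) * MM_PER_CM
        mean_theta = _layer_mean_theta(theta, z, z0, z1)
        mid = 0.5 * (z0 + z1)
        lay = column.layers[int(column.layer_index(mid)[0])]
        theta_w = float(vgm_retention(column.feddes.h3, lay.vgm))
        sw = mean_theta * thick_mm
        ww = theta_w * thick_mm
        records.append({
            "z_top_cm": z0, "z_bot_cm": z1,
            "SW_mm": sw, "Ww_mm": ww,
            "GWA_mm": max(sw - ww, 0.0),
        })
    detail = pd.DataFrame.from_records(records)
    return float(detail["GWA_mm"].sum()), detail


def available_green_water_series(sim: SimulationResult,
                                 layers: list[tuple[float, float]] | None = None) -> pd.Series:
    vals = [available_green_water(row, sim.z, sim.column, layers)[0] for row in sim.theta]
    return pd.Series(vals, index=sim.dates, name="GW_A_mm")


def separate_components(
    sim: SimulationResult,
    canopy_daily: pd.DataFrame,
    et0: pd.Series,
    P: pd.Series,
) -> pd.DataFrame:
    """Assemble the daily green-water component table from a season run.

    ``canopy_daily`` must carry ``GW_I_mm`` (and may carry LAI); all inputs
    must share the simulation's daily calendar.  Columns of the result:
    P_mm, ET0_mm, GW_H_mm, GW_L_mm, GW_I_mm, GW_A_mm, runoff_mm,
    drainage_mm.
    """
    for name, series in (("canopy", canopy_daily), ("ET0", et0), ("P", P)):
        idx = series.index
        if len(idx) != len(sim.dates) or not (idx == sim.dates).all():
            first = _first_mismatch(idx, sim.dates)
            raise ValueError(f"{name} series is not aligned with the simulation calendar "
                             f"(first mismatch at {first})")
    gwa = available_green_water_series(sim)
    out = pd.DataFrame({
        "P_mm": P.to_numpy(dtype=float),
        "ET0_mm": et0.to_numpy(dtype=float),
        "GW_H_mm": sim.daily["T_mm"].to_numpy(),
        "GW_L_mm": sim.daily["E_mm"].to_numpy(),
        "GW_I_mm": canopy_daily["GW_I_mm"].to_numpy(dtype=float),
        "GW_A_mm": gwa.to_numpy(),
        "runoff_mm": sim.daily["runoff_mm"].to_numpy(),
        "drainage_mm": sim.daily["drainage_mm"].to_numpy(),
    }, index=sim.dates)
    if "LAI" in canopy_daily.columns:
        out["LAI"] = canopy_daily["LAI"].to_numpy(dtype=float)
    return out


def _first_mismatch(a, b):
    for x, y in zip(a, b):
        if x != y:
            return x
    return a[-1] if len(a) != len(b) else None


def seasonal_totals(gwc: pd.DataFrame) -> pd.Series:
    """Season totals of the flux components plus the interception rate."""
    tot = gwc[["P_mm", "ET0_mm", "GW_H_mm", "GW_L_mm", "GW_I_mm", "runoff_mm", "drainage_mm"]].sum()
    tot["interception_rate"] = tot["GW_I_mm"] / tot["P_mm"] if tot["P_mm"] > 0 else np.nan
    tot["GW_A_mean_mm"] = gwc["GW_A_mm"].mean()
    return tot
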