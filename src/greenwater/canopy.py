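"""Vegetation canopy: LAI handling, Beer-law partition of reference
evapotranspiration, and the analytic rainfall-interception model.

Potential evapotranspiration is split between canopy (potential
transpiration Tp) and soil surface (potential evaporation Ep) by Beer-law
extinction with coefficient mu.  Under the conventional partition the
canopy takes the absorbed fraction,

    Tp = ET0 * (1 - exp(-mu * LAI)),    Ep = ET0 * exp(-mu * LAI),

which has the correct bare-soil limit (LAI = 0 -> all demand is
evaporation).  An ``as_printed`` convention flag swaps the two factors to
reproduce published variants that assign the transmitted fraction to the
canopy; the two potentials always sum to ET0.

Daily canopy interception of rainfall (the ineffective green-water term
GW_I) uses a saturating hyperbolic storage model,

    b    = 1 - exp(-mu * LAI)
    GW_I = a * LAI * (1 - 1 / (1 + b * P / (a * LAI)))

where ``a`` (dimensionless, typically calibrated per plot, initial value
0.25) scales the canopy storage capacity a*LAI.  GW_I grows monotonically
with P, saturates at a*LAI, and never exceeds P.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "CanopyParams",
    "ETPartition",
    "InterceptionTerms",
    "partition_et0",
    "interception",
    "read_lai",
    "interpolate_lai",
]


@dataclass(frozen=True)
class CanopyParams:
    """Canopy extinction and interception parameters."""

    mu: float     # Beer-law extinction coefficient, in (0, 1]
    a: float = 0.25  # interception storage parameter, in (0, 1]

    def __post_init__(self) -> None:
        if not 0.0 < self.mu <= 1.0:
            raise ValueError(f"extinction coefficient mu={self.mu} outside (0, 1]")
        if not 0.0 < self.a <= 1.0:
            raise ValueError(f"interception parameter a={self.a} outside (0, 1]")


@dataclass(frozen=True)
class ETPartition:
    Tp: float  # potential transpiration, mm/day
    Ep: float  # potential soil evaporation, mm/day


@dataclass(frozen=True)
class InterceptionTerms:
    b: float        # canopy cover fraction 1 - exp(-mu*LAI), dimensionless
    GW_I: float     # intercepted depth, mm/day
    P_net: float    # net rainfall reaching the soil surface, mm/day


def partition_et0(
    ET0: float,
    LAI: float,
    params: CanopyParams,
    convention: str = "conventional",
) -> ETPartition:
    """Split ET0 into potential transpiration and potential soil evaporation.

    ``convention='conventional'`` (default) assigns the Beer-law absorbed
    fraction to the canopy; ``'as_printed'`` swaps the two exponential
    factors.  Either way Tp + Ep == ET0 exactly.
    """
    if ET0 < 0 or LAI < 0:
        raise ValueError(f"negative input to partition_et0 (ET0={ET0}, LAI={LAI})")
    trans = float(np.exp(-params.mu * LAI))  # transmitted (soil-reaching) fraction
    if convention == "conventional":
        tp = ET0 * (1.0 - trans)
    elif convention == "as_printed":
        tp = ET0 * trans
    else:
        raise ValueError(f"unknown partition convention {convention!r}")
    return ETPartition(Tp=tp, Ep=ET0 - tp)


def interception(P: float, LAI: float, params: CanopyParams) -> InterceptionTerms:
    """Daily canopy interception and net rainfall.

    Continuous in both arguments: the storage capacity a*LAI vanishes as
    LAI -> 0, and the hyperbolic form vanishes as P -> 0, so GW_I = 0 is
    the exact limit for bare ground or dry days.
    """
    if P < 0 or LAI < 0:
        raise ValueError(f"negative input to interception (P={P}, LAI={LAI})")
    b = 1.0 - float(np.exp(-params.mu * LAI))
    cap = params.a * LAI
    if cap <= 0.0 or P <= 0.0:
        gwi = 0.0
    else:
        gwi = cap * (1.0 - 1.0 / (1.0 + b * P / cap))
    return InterceptionTerms(b=b, GW_I=gwi, P_net=P - gwi)


# ---------------------------------------------------------------------------
# LAI series I/O

def read_lai(path) -> pd.Series:
    """Read an LAI observation CSV (columns: date, LAI_m2_m2)."""
    df = pd.read_csv(path)
    for col in ("date", "LAI_m2_m2"):
        if col not in df.columns:
            raise ValueError(f"LAI file {path} missing column {col!r}")
    s = pd.Series(
        df["LAI_m2_m2"].to_numpy(dtype=float),
        index=pd.to_datetime(df["date"]),
        name="LAI",
    ).sort_index()
    if (s < 0).any():
        raise ValueError(f"LAI file {path} contains negative LAI")
    return s


def interpolate_lai(obs: pd.Series, dates: pd.DatetimeIndex) -> pd.Series:
    """Linear interpolation of sparse LAI observations to a daily calendar.

    Values outside the observed span are held at the nearest observation.
    """
    if obs.empty:
        raise ValueError("empty LAI observation series")
    t = obs.index.view("int64").astype(float)
    ti = dates.view("int64").astype(float)
    lai = np.interp(ti, t, obs.to_numpy(dtype=float))
    out = pd.Series(lai, index=dates, name="LAI")
    if (out < 0).any():
        raise ValueError("interpolated LAI is negative")
    return out
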