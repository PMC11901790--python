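"""Atmospheric forcing: ingestion, reference evapotranspiration, rainfall
classes and the growing-season calendar.

Daily meteorology drives everything downstream.  Reference
evapotranspiration (ET0) follows the FAO-56 Penman-Monteith combination
equation at daily resolution,

    ET0 = [0.408 Δ (Rn - G) + γ 900/(T+273) U2 (e_a - e_d)]
          / [Δ + γ (1 + 0.34 U2)]

with radiation terms in MJ m-2 d-1 and ET0 in mm d-1.  Humidity is
ingested as relative humidity and converted to vapour pressures with the
Tetens saturation formula at the daily mean air temperature.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "DailyMeteo",
    "PenmanTerms",
    "SeasonCalendar",
    "RAIN_CLASSES",
    "penman_monteith_et0",
    "reference_et0",
    "classify_rainfall",
    "classify_rainfall_series",
    "merge_heavy",
    "growth_stage",
    "growth_stage_series",
    "read_weather",
    "write_weather",
]

#: default station elevation (m a.s.l.) used for the psychrometric constant;
#: representative of loess-tableland terrace plots.
DEFAULT_ELEVATION_M = 1220.0

WEATHER_COLUMNS = ["date", "P_mm", "T_C", "U2_ms", "Rn_MJ_m2_d", "G_MJ_m2_d", "RH"]


@dataclass(frozen=True)
class DailyMeteo:
    """One day of atmospheric forcing.

    Radiation fields are stored in MJ m-2 d-1 (converted at ingestion if the
    source is in J m-2 d-1) so the 0.408 coefficient of the combination
    equation applies directly.
    """

    date: _dt.date
    P: float        # precipitation, mm/day
    T_air: float    # mean air temperature, degC
    U2: float       # wind speed at 2 m, m/s
    Rn: float       # net radiation, MJ m-2 d-1
    G: float = 0.0  # soil heat flux, MJ m-2 d-1 (0 at daily scale by default)
    RH: float = 0.5  # relative humidity, fraction

    def __post_init__(self) -> None:
        for name in ("P", "T_air", "U2", "Rn", "G", "RH"):
            v = getattr(self, name)
            if v is None or not np.isfinite(v):
                raise ValueError(f"missing or non-finite field {name!r} on {self.date}")
        if self.P < 0:
            raise ValueError(f"negative precipitation on {self.date}")
        if self.U2 < 0:
            raise ValueError(f"negative wind speed on {self.date}")
        if not 0.0 <= self.RH <= 1.0:
            raise ValueError(f"RH outside [0, 1] on {self.date}")


@dataclass(frozen=True)
class PenmanTerms:
    """Intermediate terms and the result of the combination equation."""

    delta: float  # slope of saturation vapour-pressure curve, kPa/K
    gamma: float  # psychrometric constant, kPa/K
    e_a: float    # saturation vapour pressure, kPa
    e_d: float    # actual vapour pressure, kPa
    ET0: float    # reference evapotranspiration, mm/day


def saturation_vapour_pressure(T: float | np.ndarray) -> float | np.ndarray:
    """Tetens saturation vapour pressure (kPa) at air temperature T (degC)."""
    return 0.6108 * np.exp(17.27 * np.asarray(T, dtype=float) / (np.asarray(T, dtype=float) + 237.3))


def svp_slope(T: float | np.ndarray) -> float | np.ndarray:
    """Slope of the saturation vapour-pressure curve (kPa/K) at T (degC)."""
    T = np.asarray(T, dtype=float)
    return 4098.0 * saturation_vapour_pressure(T) / (T + 237.3) ** 2


def psychrometric_constant(elevation_m: float = DEFAULT_ELEVATION_M) -> float:
    """Psychrometric constant (kPa/K) from barometric pressure at elevation."""
    pressure = 101.3 * ((293.0 - 0.0065 * elevation_m) / 293.0) ** 5.26
    return 0.000665 * pressure


def penman_monteith_et0(met: DailyMeteo, elevation_m: float = DEFAULT_ELEVATION_M) -> PenmanTerms:
    """Daily FAO-56 Penman-Monteith reference evapotranspiration.

    Returns the intermediate terms alongside ET0 for inspection; ET0 is
    clipped at zero when the combined numerator is negative (e.g. strong
    nocturnal-type energy deficit), since negative reference demand has no
    meaning in the green-water budget.
    """
    delta = float(svp_slope(met.T_air))
    gamma = psychrometric_constant(elevation_m)
    e_a = float(saturation_vapour_pressure(met.T_air))
    e_d = met.RH * e_a
    num = 0.408 * delta * (met.Rn - met.G) + gamma * (900.0 / (met.T_air + 273.0)) * met.U2 * (e_a - e_d)
    den = delta + gamma * (1.0 + 0.34 * met.U2)
    et0 = max(num / den, 0.0)
    return PenmanTerms(delta=delta, gamma=gamma, e_a=e_a, e_d=e_d, ET0=et0)


def reference_et0(weather: pd.DataFrame, elevation_m: float = DEFAULT_ELEVATION_M) -> pd.Series:
    """Vectorised ET0 (mm/day) over a validated weather table."""
    T = weather["T_C"].to_numpy(dtype=float)
    delta = svp_slope(T)
    gamma = psychrometric_constant(elevation_m)
    e_a = saturation_vapour_pressure(T)
    e_d = weather["RH"].to_numpy(dtype=float) * e_a
    u2 = weather["U2_ms"].to_numpy(dtype=float)
    rn = weather["Rn_MJ_m2_d"].to_numpy(dtype=float)
    g = weather["G_MJ_m2_d"].to_numpy(dtype=float)
    num = 0.408 * delta * (rn - g) + gamma * (900.0 / (T + 273.0)) * u2 * (e_a - e_d)
    den = delta + gamma * (1.0 + 0.34 * u2)
    return pd.Series(np.maximum(num / den, 0.0), index=weather.index, name="ET0")


# ---------------------------------------------------------------------------
# rainfall classes

#: daily-depth class bounds (mm/24 h), right-open except the top class
RAIN_CLASSES = ("rain-free", "light", "moderate", "heavy", "rainstorm")
_RAIN_EDGES = (0.1, 10.0, 25.0, 50.0)


def classify_rainfall(P: float) -> str:
    """Class of a daily rainfall depth.

    Bounds follow the operational daily-depth convention: rain-free below
    0.1 mm, light [0.1, 10), moderate [10, 25), heavy [25, 50), rainstorm
    >= 50 mm per 24 h.
    """
    if P < 0 or not np.isfinite(P):
        raise ValueError(f"invalid precipitation depth {P!r}")
    idx = int(np.searchsorted(_RAIN_EDGES, P, side="right"))
    return RAIN_CLASSES[idx]


def classify_rainfall_series(P: pd.Series) -> pd.Series:
    p = P.to_numpy(dtype=float)
    if np.any(p < 0) or not np.all(np.isfinite(p)):
        raise ValueError("precipitation series contains negative or non-finite values")
    idx = np.searchsorted(_RAIN_EDGES, p, side="right")
    return pd.Series(np.asarray(RAIN_CLASSES, dtype=object)[idx], index=P.index, name="rain_class")


def merge_heavy(rain_class: str) -> str:
    """Collapse heavy and rainstorm into one 'heavy+' group (regression grouping)."""
    return "heavy+" if rain_class in ("heavy", "rainstorm") else rain_class


# ---------------------------------------------------------------------------
# season calendar

@dataclass(frozen=True)
class SeasonCalendar:
    """Growing-season calendar (15 Apr - 15 Oct) with three growth stages.

    Stage boundaries are month/day anchored: early [15 Apr, 15 May],
    middle [16 May, 31 Aug], late [1 Sep, 15 Oct].
    """

    year: int

    @property
    def season_start(self) -> _dt.date:
        return _dt.date(self.year, 4, 15)

    @property
    def season_end(self) -> _dt.date:
        return _dt.date(self.year, 10, 15)

    @property
    def early_end(self) -> _dt.date:
        return _dt.date(self.year, 5, 15)

    @property
    def middle_end(self) -> _dt.date:
        return _dt.date(self.year, 8, 31)

    def dates(self) -> pd.DatetimeIndex:
        return pd.date_range(self.season_start, self.season_end, freq="D")

    def __len__(self) -> int:
        return (self.season_end - self.season_start).days + 1


def _as_date(d) -> _dt.date:
    if isinstance(d, pd.Timestamp):
        return d.date()
    if isinstance(d, _dt.datetime):
        return d.date()
    return d


def growth_stage(date, cal: SeasonCalendar) -> str:
    """Growth stage ('early'/'middle'/'late') of a season day."""
    d = _as_date(date)
    if d < cal.season_start or d > cal.season_end:
        raise ValueError(f"date {d} outside the growing season {cal.season_start}..{cal.season_end}")
    if d <= cal.early_end:
        return "early"
    if d <= cal.middle_end:
        return "middle"
    return "late"


def growth_stage_series(dates: pd.DatetimeIndex, cal: SeasonCalendar) -> pd.Series:
    return pd.Series([growth_stage(d, cal) for d in dates], index=dates, name="stage")


# ---------------------------------------------------------------------------
# I/O

def read_weather(path) -> pd.DataFrame:
    """Read and validate a daily weather CSV.

    Expected columns: date (ISO-8601), P_mm, T_C, U2_ms, Rn_MJ_m2_d,
    G_MJ_m2_d, RH.  Dates must be strictly increasing with no gaps.
    """
    df = pd.read_csv(path)
    missing = [c for c in WEATHER_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"weather file {path} missing columns {missing}")
    df["date"] = pd.to_datetime(df["date"])
    df = df.set_index("date")
    validate_weather(df, source=str(path))
    return df


def validate_weather(df: pd.DataFrame, source: str = "<weather>") -> None:
    if df.isna().any().any():
        col = df.columns[df.isna().any()][0]
        day = df.index[df[col].isna()][0]
        raise ValueError(f"{source}: missing field {col!r} on {day.date()}")
    gaps = df.index.to_series().diff().dropna()
    if not (gaps == pd.Timedelta(days=1)).all():
        raise ValueError(f"{source}: dates are not strictly daily without gaps")
    if (df["P_mm"] < 0).any():
        raise ValueError(f"{source}: negative precipitation")
    if (df["U2_ms"] < 0).any():
        raise ValueError(f"{source}: negative wind speed")
    if ((df["RH"] < 0) | (df["RH"] > 1)).any():
        raise ValueError(f"{source}: RH outside [0, 1]")


def write_weather(df: pd.DataFrame, path) -> None:
    out = df.copy()
    out.insert(0, "date", out.index.strftime("%Y-%m-%d"))
    out.to_csv(path, index=False)
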