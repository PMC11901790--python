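"""Model skill, sensitivity ranking and parameter calibration.

Skill is scored with the Nash-Sutcliffe efficiency,

    NSE = 1 - sum((obs - sim)^2) / sum((obs - mean(obs))^2),

banded qualitatively (very good > 0.75; good in (0.65, 0.75];
satisfactory in [0.50, 0.65]; unsatisfactory below 0.50).

Sensitivity uses one-at-a-time perturbations of each calibrated
parameter by +/-10 % of its admissible range around a nominal point;
the score of a parameter is the mean absolute change it induces in the
simulated water-content output, and parameters are ranked by descending
score with ties broken by input order.

Calibration maximises the mean NSE over the water-content depth series
(evaporation skill is reported but not optimised) with derivative-free
search: Latin-hypercube screening over the bounds followed by
Nelder-Mead refinement from the best screened point.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.stats import qmc

__all__ = [
    "ObservationSet",
    "CalibrationResult",
    "nse",
    "classify_nse",
    "sensitivity_rank",
    "calibrate",
    "read_observations",
]


@dataclass(frozen=True)
class ObservationSet:
    """Dated observations used for calibration.

    ``theta``: wide table (date index, one column per observation depth in
    cm) of volumetric water content; ``evap``: daily soil-evaporation
    observations (mm/day), may be empty.
    """

    theta: pd.DataFrame
    evap: pd.Series

    def __post_init__(self) -> None:
        vals = self.theta.to_numpy(dtype=float)
        if vals.size and (np.any(vals <= 0) or np.any(vals >= 1)):
            raise ValueError("water-content observations must lie in (0, 1)")

    @property
    def n(self) -> int:
        return int(self.theta.size + self.evap.size)


@dataclass
class CalibrationResult:
    params: dict
    nse_theta: dict           # per-depth NSE
    nse_evap: float | None
    bands: dict               # per-series qualitative band
    objective: float          # mean theta-NSE achieved
    n_evaluations: int
    converged: bool
    sensitivity: pd.DataFrame | None = None


def nse(obs, sim) -> float:
    """Nash-Sutcliffe efficiency of paired series (1 = perfect)."""
    obs = np.asarray(obs, dtype=float)
    sim = np.asarray(sim, dtype=float)
    if obs.shape != sim.shape or obs.size < 2:
        raise ValueError("obs and sim must be paired series of length >= 2")
    denom = float(np.sum((obs - obs.mean()) ** 2))
    if denom == 0.0:
        raise ValueError("NSE undefined for constant observations")
    return 1.0 - float(np.sum((obs - sim) ** 2)) / denom


def classify_nse(value: float) -> str:
    """Qualitative simulation-skill band of an NSE value."""
    if not np.isfinite(value):
        raise ValueError(f"non-finite NSE {value!r}")
    if value > 0.75:
        return "very good"
    if value > 0.65:
        return "good"
    if value >= 0.50:
        return "satisfactory"
    return "unsatisfactory"


def sensitivity_rank(
    runner,
    nominal: dict,
    ranges: dict,
    frac: float = 0.1,
) -> pd.DataFrame:
    """One-at-a-time sensitivity ranking of model parameters.

    ``runner(params) -> ndarray-like`` must return the simulated output to
    score (e.g. the stacked water-content series).  Each parameter is
    perturbed by +/- ``frac`` of its range width (clipped to the range) and
    scored by the mean absolute output change relative to the nominal run,
    averaged over the feasible perturbations.  Returns a DataFrame ordered
    by descending score with columns parameter/score/rank/failures.
    """
    base = np.asarray(runner(dict(nominal)), dtype=float).ravel()
    records = []
    for order, (name, (lo, hi)) in enumerate(ranges.items()):
        if not lo < hi:
            raise ValueError(f"invalid range for {name!r}: ({lo}, {hi})")
        x0 = nominal[name]
        if not lo <= x0 <= hi:
            raise ValueError(f"nominal {name}={x0} outside its range ({lo}, {hi})")
        deltas, failures = [], 0
        for sign in (-1.0, +1.0):
            x = float(np.clip(x0 + sign * frac * (hi - lo), lo, hi))
            if x == x0:
                continue
            trial = dict(nominal)
            trial[name] = x
            try:
                out = np.asarray(runner(trial), dtype=float).ravel()
                deltas.append(float(np.mean(np.abs(out - base))))
            except Exception:  # model failure under this perturbation
                failures += 1
        score = float(np.mean(deltas)) if deltas else 0.0
        records.append({"parameter": name, "score": score, "order": order, "failures": failures})
    df = pd.DataFrame.from_records(records)
    df = df.sort_values(["score", "order"], ascending=[False, True], kind="stable")
    df["rank"] = np.arange(1, len(df) + 1)
    return df.drop(columns="order").reset_index(drop=True)


def _objective(runner, obs: ObservationSet, names, x) -> float:
    """1 - mean theta-NSE for a parameter vector (large on failure)."""
    try:
        sim = runner(dict(zip(names, x)))
    except Exception:
        return 1e6
    scores = []
    for col in obs.theta.columns:
        s = sim.theta[col].reindex(obs.theta.index)
        scores.append(nse(obs.theta[col], s))
    return 1.0 - float(np.mean(scores))


def calibrate(
    runner,
    obs: ObservationSet,
    bounds: dict,
    nominal: dict | None = None,
    n_screen: int = 64,
    seed: int = 20190415,
    maxiter: int = 200,
) -> CalibrationResult:
    """Calibrate free parameters against water-content observations.

    ``runner(params) -> object with .theta (DataFrame) and .evap (Series)``
    aligned (or alignable) with the observation calendar.  ``bounds`` maps
    the free parameter names to (lo, hi); ``nominal`` optionally seeds the
    search (and is always screened so the result is never worse than the
    nominal start).  Returns the best parameters, per-series NSE with
    qualitative bands, and the achieved objective.
    """
    if obs.n < 10:
        raise ValueError(f"need at least 10 observations to calibrate, got {obs.n}")
    names = list(bounds)
    lo = np.array([bounds[k][0] for k in names], dtype=float)
    hi = np.array([bounds[k][1] for k in names], dtype=float)
    if np.any(lo >= hi):
        raise ValueError("invalid calibration bounds")

    sampler = qmc.LatinHypercube(d=len(names), seed=seed)
    cand = qmc.scale(sampler.random(n_screen), lo, hi)
    if nominal is not None:
        cand = np.vstack([np.array([nominal[k] for k in names], dtype=float), cand])

    n_eval = 0
    best_x, best_f = None, np.inf
    for x in cand:
        f = _objective(runner, obs, names, x)
        n_eval += 1
        if f < best_f:
            best_x, best_f = x, f

    def penalised(x):
        if np.any(x < lo) or np.any(x > hi):
            return best_f + 10.0 + float(np.sum(np.maximum(lo - x, 0) + np.maximum(x - hi, 0)))
        return _objective(runner, obs, names, x)

    res = minimize(penalised, best_x, method="Nelder-Mead",
                   options={"maxiter": maxiter, "xatol": 1e-4, "fatol": 1e-6})
    n_eval += res.nfev
    if res.fun <= best_f:
        best_x, best_f = np.clip(res.x, lo, hi), float(res.fun)
    else:
        warnings.warn("optimizer stagnation: returning best screened point", RuntimeWarning)

    params = dict(zip(names, best_x))
    sim = runner(dict(params))
    nse_theta = {col: nse(obs.theta[col], sim.theta[col].reindex(obs.theta.index))
                 for col in obs.theta.columns}
    nse_evap = None
    if len(obs.evap) >= 2 and obs.evap.nunique() > 1:
        nse_evap = nse(obs.evap, sim.evap.reindex(obs.evap.index))
    bands = {k: classify_nse(v) for k, v in nse_theta.items()}
    if nse_evap is not None:
        bands["evap"] = classify_nse(nse_evap)
    return CalibrationResult(
        params=params, nse_theta=nse_theta, nse_evap=nse_evap, bands=bands,
        objective=1.0 - best_f, n_evaluations=n_eval, converged=bool(res.success),
    )


def read_observations(path) -> ObservationSet:
    """Read an observation CSV with columns date, depth_cm (or 'evap'), value."""
    df = pd.read_csv(path)
    for col in ("date", "depth_cm", "value"):
        if col not in df.columns:
            raise ValueError(f"observation file {path} missing column {col!r}")
    df["date"] = pd.to_datetime(df["date"])
    is_evap = df["depth_cm"].astype(str).str.lower() == "evap"
    evap = df[is_evap].set_index("date")["value"].rename("evap_mm")
    theta = (df[~is_evap]
             .assign(depth_cm=lambda d: d["depth_cm"].astype(float))
             .pivot_table(index="date", columns="depth_cm", values="value"))
    return ObservationSet(theta=theta, evap=evap)
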