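"""Mass-conservative 1-D Richards solver for the plot soil column.

Vertical unsaturated flow over 0-200 cm with a root-uptake sink,

    d theta/dt = d/dz [ K(h) (dh/dz - 1) ] - S(z, t)

with z positive downward (so gravity drives flow toward larger z),
pressure head h in cm and conductivity in cm/d.  The discretisation is
the mixed-form modified Picard scheme (cell-centred finite volumes,
implicit in time): each Picard iteration solves a tridiagonal system for
the new heads, and at convergence the discrete water balance holds to
the iteration tolerance, which keeps seasonal mass-balance errors far
below the fluxes of interest.

Boundary conditions
-------------------
Top: atmospheric.  The target surface flux is net rainfall minus
moisture-limited soil evaporation.  The boundary switches from flux
control to head control when the surface saturates (excess becomes
instant runoff; no ponding storage on the terraces) or when the surface
dries to the minimum allowed head.
Bottom: unit-gradient free drainage (q = K(h) at the bottom node), or a
sealed no-flux boundary for closed-column experiments.

Time stepping is adaptive within each 1-day forcing interval: the step
grows when Picard converges quickly, shrinks otherwise, and a
non-convergent step is retried with a smaller step before the run is
abandoned with the failing day reported.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._kernel import picard_substep
from .soilwater import (
    SoilColumn,
    actual_evaporation,
    feddes_alpha,
    vgm_head,
)

__all__ = ["SolverConfig", "SimulationResult", "RichardsNonConvergence", "simulate_profile"]

MM_PER_CM = 10.0


class RichardsNonConvergence(RuntimeError):
    """Raised when Picard iteration fails at the minimum time step."""

    def __init__(self, day_index: int, date) -> None:
        super().__init__(f"Richards solver failed to converge on day {day_index} ({date})")
        self.day_index = day_index
        self.date = date


@dataclass(frozen=True)
class SolverConfig:
    """Numerical settings of the Richards integration."""

    picard_tol: float = 1e-6      # max |dh| between Picard iterates, cm
    max_picard: int = 50
    dt_init: float = 0.05         # d
    dt_min: float = 1e-7          # d
    dt_max: float = 0.5           # d
    h_pond: float = 0.0           # surface head limit before runoff, cm
    h_dry: float = -1.0e6         # minimum allowed surface head, cm
    surface_layer_cm: float = 10.0  # depth over which "surface" theta is averaged
    evap_form: str = "increasing"   # moisture-limited evaporation ramp form
    bottom_bc: str = "free_drainage"  # or "no_flux"

    def __post_init__(self) -> None:
        if self.bottom_bc not in ("free_drainage", "no_flux"):
            raise ValueError(f"unknown bottom boundary {self.bottom_bc!r}")


@dataclass
class SimulationResult:
    """Daily profile states and flux bookkeeping of one season run.

    All depths/fluxes in the ``daily`` table are in mm; nodal states keep
    the solver's cm units for heads and cm3/cm3 for water contents.
    """

    z: np.ndarray                  # node centres, cm
    dates: pd.DatetimeIndex
    h: np.ndarray                  # (ndays, nnodes) end-of-day pressure head, cm
    theta: np.ndarray              # (ndays, nnodes) end-of-day water content
    daily: pd.DataFrame            # per-day fluxes and storage, mm
    theta_init: np.ndarray
    column: SoilColumn

    @property
    def storage_init_mm(self) -> float:
        return float(np.sum(self.theta_init) * self.column.dz * MM_PER_CM)

    def mass_balance_error(self) -> float:
        """Relative seasonal closure error of the water balance.

        |sum(inflow) - sum(outflow) - d storage| over the larger of total
        surface input and |d storage|.
        """
        d = self.daily
        inflow = d["infiltration_mm"].sum()
        outflow = d["drainage_mm"].sum() + d["E_mm"].sum() + d["T_mm"].sum()
        dstore = d["storage_mm"].iloc[-1] - self.storage_init_mm
        denom = max(d["P_net_mm"].sum() + abs(dstore), 1e-9)
        return abs(inflow - outflow - dstore) / denom

    def theta_at(self, depth_cm: float) -> pd.Series:
        """Daily water content interpolated at one observation depth."""
        vals = np.array([np.interp(depth_cm, self.z, row) for row in self.theta])
        return pd.Series(vals, index=self.dates, name=f"theta_{depth_cm:g}cm")


class _NodeHydraulics:
    """Per-node van Genuchten-Mualem evaluation with shared powers."""

    def __init__(self, column: SoilColumn):
        tr, ts, a, n, Ks, l = column.node_params()
        self.tr = np.asarray(tr, dtype=float)
        self.ts = np.asarray(ts, dtype=float)
        self.a = np.asarray(a, dtype=float)
        self.n = np.asarray(n, dtype=float)
        self.m = 1.0 - 1.0 / self.n
        self.Ks = np.asarray(Ks, dtype=float)
        self.l = np.asarray(l, dtype=float)

    def __call__(self, h: np.ndarray):
        """Return (theta, capacity, conductivity) at nodal heads h."""
        neg = h < 0.0
        hn = np.where(neg, h, -1.0)  # placeholder magnitude where saturated
        ahn = np.abs(self.a * hn) ** self.n
        base = 1.0 + ahn
        se = base ** (-self.m)
        theta = np.where(neg, self.tr + (self.ts - self.tr) * se, self.ts)
        cap = (self.ts - self.tr) * self.n * self.m * (ahn / np.abs(hn)) / base * se
        # tiny floor keeps the system non-singular when fully saturated;
        # at convergence dh -> 0 so it does not bias the balance
        cap = np.maximum(np.where(neg, cap, 0.0), 1e-12)
        sec = np.where(neg, np.minimum(se, 1.0), 1.0)
        K = self.Ks * sec ** self.l * (1.0 - (1.0 - sec ** (1.0 / self.m)) ** self.m) ** 2
        return theta, cap, K

    def boundary_K(self, h_surf: float) -> float:
        """Conductivity of the surface material at an imposed boundary head."""
        _, _, K = self(np.full(1, h_surf))
        return float(K[0])


def _root_cell_density(column: SoilColumn, z: np.ndarray) -> np.ndarray:
    """Root density on cell centres, renormalised so sum(beta)*dz = 1."""
    beta = column.roots.interp(z)
    total = beta.sum() * column.dz
    if total <= 0:
        raise ValueError("root profile has no mass on the column grid")
    return beta / total


def simulate_profile(
    column: SoilColumn,
    forcing: pd.DataFrame,
    theta_init,
    config: SolverConfig | None = None,
) -> SimulationResult:
    """Integrate the column over a season of daily forcing.

    ``forcing`` must be date-indexed with columns ``P_net_mm``, ``Ep_mm``
    and ``Tp_mm`` (net rainfall, potential evaporation, potential
    transpiration).  ``theta_init`` is the initial water content: a scalar,
    one value per layer, or one value per node.
    """
    cfg = config or SolverConfig()
    for col in ("P_net_mm", "Ep_mm", "Tp_mm"):
        if col not in forcing.columns:
            raise ValueError(f"forcing table missing column {col!r}")
    z = column.node_centers()
    dz = column.dz
    nn = z.size
    hyd = _NodeHydraulics(column)

    theta0 = _expand_theta(column, theta_init, nn)
    if np.any(theta0 <= hyd.tr) or np.any(theta0 > hyd.ts + 1e-12):
        raise ValueError("initial water content outside (theta_r, theta_s]")
    h = np.asarray(vgm_head(theta0, column.node_params()), dtype=float)

    beta_cells = _root_cell_density(column, z)
    surf_mask = z <= cfg.surface_layer_cm
    lay0 = column.surface_layer()
    K_bc = {"head_pond": hyd.boundary_K(cfg.h_pond), "head_dry": hyd.boundary_K(cfg.h_dry)}

    n_days = len(forcing)
    out_h = np.empty((n_days, nn))
    out_theta = np.empty((n_days, nn))
    cols = ["P_net_mm", "Ep_mm", "Tp_mm", "infiltration_mm", "runoff_mm",
            "drainage_mm", "E_mm", "T_mm", "storage_mm"]
    daily = np.zeros((n_days, len(cols)))
    p_all = forcing["P_net_mm"].to_numpy(dtype=float)
    ep_all = forcing["Ep_mm"].to_numpy(dtype=float)
    tp_all = forcing["Tp_mm"].to_numpy(dtype=float)

    dt = cfg.dt_init
    theta_now, _, _ = hyd(h)
    for di in range(n_days):
        p_rate = p_all[di] / MM_PER_CM  # cm/d, constant over the day
        ep_day = ep_all[di] / MM_PER_CM
        tp_day = tp_all[di] / MM_PER_CM
        inf = run = drain = evap = transp = 0.0

        t = 0.0
        while t < 1.0 - 1e-12:
            dt = min(dt, 1.0 - t, cfg.dt_max)
            # moisture-limited evaporation from the surface-layer average
            th_surf = float(theta_now[surf_mask].mean())
            er_rate = actual_evaporation(ep_day, th_surf, lay0.theta_f, lay0.theta_c,
                                         form=cfg.evap_form)
            # root extraction sink, per unit depth
            sink = tp_day * beta_cells * feddes_alpha(h, column.feddes)
            q_target = p_rate - er_rate

            step = _substep(h, theta_now, dt, q_target, sink, hyd, K_bc, dz, cfg)
            while step is None:
                dt *= 0.3
                if dt < cfg.dt_min:
                    raise RichardsNonConvergence(di, forcing.index[di])
                step = _substep(h, theta_now, dt, q_target, sink, hyd, K_bc, dz, cfg)
            h, theta_now, q_top, q_bot, iters = step

            # evaporation actually extracted: reduced only in the dry-limit case
            evap_act = er_rate if q_target >= 0 or q_top <= q_target + 1e-15 else p_rate - q_top
            evap_act = max(evap_act, 0.0)
            # gross infiltration + runoff partition the rain; inf - evap = q_top
            inf += (q_top + evap_act) * dt
            if q_target > 0:
                run += max(q_target - q_top, 0.0) * dt
            drain += q_bot * dt
            evap += evap_act * dt
            transp += sink.sum() * dz * dt
            t += dt
            if iters <= 5:
                dt *= 1.35
            elif iters >= 15:
                dt *= 0.7

        theta_end = np.clip(theta_now, hyd.tr, hyd.ts)
        out_h[di] = h
        out_theta[di] = theta_end
        daily[di] = [
            p_all[di], ep_all[di], tp_all[di],
            inf * MM_PER_CM, run * MM_PER_CM, drain * MM_PER_CM,
            evap * MM_PER_CM, transp * MM_PER_CM,
            float(theta_end.sum() * dz * MM_PER_CM),
        ]

    daily_df = pd.DataFrame(daily, columns=cols, index=forcing.index)
    return SimulationResult(z=z, dates=pd.DatetimeIndex(forcing.index), h=out_h,
                            theta=out_theta, daily=daily_df, theta_init=theta0,
                            column=column)


def _expand_theta(column: SoilColumn, theta_init, nn: int) -> np.ndarray:
    theta_init = np.atleast_1d(np.asarray(theta_init, dtype=float))
    if theta_init.size == 1:
        return np.full(nn, theta_init[0])
    if theta_init.size == len(column.layers):
        idx = column.layer_index(column.node_centers())
        return theta_init[idx]
    if theta_init.size == nn:
        return theta_init.copy()
    raise ValueError(
        f"theta_init must be scalar, per-layer ({len(column.layers)}) or per-node ({nn})"
    )


def _substep(h_old, theta_old, dt, q_target, sink, hyd: _NodeHydraulics, K_bc, dz,
             cfg: SolverConfig):
    """One implicit step with modified-Picard iteration and BC switching.

    Thin wrapper over the compiled kernel; returns ``(h_new, theta_new,
    q_top_actual, q_bottom, iterations)`` or None on non-convergence.
    """
    h, theta, q_top, q_bot, iters, ok = picard_substep(
        h_old, theta_old, dt, q_target, sink,
        hyd.tr, hyd.ts, hyd.a, hyd.n, hyd.m, hyd.Ks, hyd.l,
        K_bc["head_pond"], K_bc["head_dry"], dz,
        cfg.picard_tol, cfg.max_picard, cfg.h_pond, cfg.h_dry,
        cfg.bottom_bc == "free_drainage",
    )
    if not ok:
        return None
    return h, theta, float(q_top), float(q_bot), int(iters)
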