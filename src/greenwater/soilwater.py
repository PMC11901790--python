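"""Soil hydraulics for a layered 0-200 cm column.

Closed-form van Genuchten-Mualem retention and conductivity,

    Se(h) = [1 + |alpha h|^n]^(-m),        m = 1 - 1/n
    theta(h) = theta_r + (theta_s - theta_r) Se(h)
    K(h) = Ks Se^l [1 - (1 - Se^(1/m))^m]^2

with pressure head h in cm (negative under suction), depth positive
downward, conductivity in cm/d.  Root water uptake is reduced by the
piecewise-linear Feddes stress function with thresholds h1 > h2 > h3
(wilting), and distributed over depth by a normalised root-density
profile beta(z) with unit integral over the rooting depth.

Surface evaporation is moisture-limited by a two-anchor linear reduction
between the capillary-rupture water content theta_c (evaporation stops)
and 0.65 * field capacity (evaporation at the potential rate).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "VGMParams",
    "FeddesParams",
    "RootProfile",
    "SoilLayer",
    "SoilColumn",
    "vgm_retention",
    "vgm_conductivity",
    "vgm_capacity",
    "vgm_head",
    "feddes_alpha",
    "normalize_root_density",
    "exponential_root_profile",
    "actual_transpiration",
    "actual_evaporation",
]


@dataclass(frozen=True)
class VGMParams:
    """van Genuchten-Mualem hydraulic parameters for one soil layer."""

    theta_r: float   # residual water content, cm3/cm3
    theta_s: float   # saturated water content, cm3/cm3
    alpha: float     # inverse air-entry suction, 1/cm
    n: float         # pore-size distribution parameter (> 1)
    Ks: float        # saturated conductivity, cm/d
    l: float = 0.5   # pore-connectivity exponent

    def __post_init__(self) -> None:
        if not 0.0 <= self.theta_r < self.theta_s <= 1.0:
            raise ValueError(f"require 0 <= theta_r < theta_s <= 1, got {self.theta_r}, {self.theta_s}")
        if self.alpha <= 0:
            raise ValueError(f"alpha must be positive, got {self.alpha}")
        if self.n <= 1:
            raise ValueError(f"n must exceed 1, got {self.n}")
        if self.Ks <= 0:
            raise ValueError(f"Ks must be positive, got {self.Ks}")

    @property
    def m(self) -> float:
        return 1.0 - 1.0 / self.n


@dataclass(frozen=True)
class FeddesParams:
    """Pressure-head thresholds (cm, negative) of the root-uptake stress function."""

    h1: float  # anoxia-side threshold: uptake ramps up from 0 at h=0 to 1 at h1
    h2: float  # onset of water stress
    h3: float  # permanent wilting

    def __post_init__(self) -> None:
        if not self.h3 < self.h2 < self.h1 <= 0.0:
            raise ValueError(f"require h3 < h2 < h1 <= 0, got {self.h3}, {self.h2}, {self.h1}")


def _p_arrays(params):
    """Broadcastable parameter arrays from a VGMParams or per-node arrays."""
    if isinstance(params, VGMParams):
        return (params.theta_r, params.theta_s, params.alpha, params.n, params.Ks, params.l)
    return params  # tuple of arrays (theta_r, theta_s, alpha, n, Ks, l)


def vgm_effective_saturation(h, params):
    tr, ts, a, n, Ks, l = _p_arrays(params)
    h = np.asarray(h, dtype=float)
    m = 1.0 - 1.0 / np.asarray(n, dtype=float)
    ah = np.abs(a * np.minimum(h, 0.0))
    return (1.0 + ah ** n) ** (-m)


def vgm_retention(h, params):
    """Water content theta (cm3/cm3) at pressure head h (cm)."""
    tr, ts, a, n, Ks, l = _p_arrays(params)
    se = vgm_effective_saturation(h, params)
    return tr + (ts - tr) * se


def vgm_capacity(h, params):
    """Specific moisture capacity C = d theta / d h (1/cm); zero at saturation."""
    tr, ts, a, n, Ks, l = _p_arrays(params)
    h = np.asarray(h, dtype=float)
    n = np.asarray(n, dtype=float)
    m = 1.0 - 1.0 / n
    hn = np.minimum(h, 0.0)
    ah = np.abs(a * hn)
    # d theta/dh = (ts-tr) * m*n*a*ah^(n-1) * (1+ah^n)^(-m-1), h < 0
    c = (ts - tr) * m * n * a * ah ** (n - 1.0) * (1.0 + ah ** n) ** (-m - 1.0)
    return np.where(h < 0.0, c, 0.0)


def vgm_conductivity(h, params):
    """Unsaturated hydraulic conductivity K (cm/d) at pressure head h (cm)."""
    tr, ts, a, n, Ks, l = _p_arrays(params)
    n = np.asarray(n, dtype=float)
    m = 1.0 - 1.0 / n
    se = vgm_effective_saturation(h, params)
    se = np.clip(se, 1e-12, 1.0)
    k = Ks * se ** l * (1.0 - (1.0 - se ** (1.0 / m)) ** m) ** 2
    return np.clip(k, 0.0, Ks)


def vgm_head(theta, params):
    """Inverse retention: pressure head h (cm) at water content theta."""
    tr, ts, a, n, Ks, l = _p_arrays(params)
    theta = np.asarray(theta, dtype=float)
    n = np.asarray(n, dtype=float)
    m = 1.0 - 1.0 / n
    se = (theta - tr) / (ts - tr)
    if np.any(se <= 0.0) or np.any(se > 1.0 + 1e-12):
        raise ValueError("theta outside the open interval (theta_r, theta_s]")
    se = np.clip(se, 1e-12, 1.0)
    with np.errstate(divide="ignore"):
        h = -(se ** (-1.0 / m) - 1.0) ** (1.0 / n) / a
    return np.where(se >= 1.0, 0.0, h)


def feddes_alpha(h, f: FeddesParams):
    """Feddes root-uptake stress factor in [0, 1] at pressure head h (cm)."""
    h = np.asarray(h, dtype=float)
    out = np.zeros_like(h)
    wet = (h >= f.h1) & (h <= 0.0)
    out[wet] = h[wet] / f.h1
    plateau = (h >= f.h2) & (h < f.h1)
    out[plateau] = 1.0
    stress = (h >= f.h3) & (h < f.h2)
    out[stress] = (h[stress] - f.h3) / (f.h2 - f.h3)
    return out if out.ndim else float(out)


# ---------------------------------------------------------------------------
# root profile

@dataclass(frozen=True)
class RootProfile:
    """Normalised root-density profile beta(z) on a depth grid (cm, downward)."""

    z: np.ndarray        # depths, cm
    beta: np.ndarray     # normalised density, 1/cm; trapezoid integral = 1
    Lr: float            # rooting depth, cm

    def interp(self, z_nodes: np.ndarray) -> np.ndarray:
        b = np.interp(z_nodes, self.z, self.beta, left=self.beta[0], right=0.0)
        b[z_nodes > self.Lr] = 0.0
        return b


def normalize_root_density(z, beta_raw, Lr: float | None = None) -> RootProfile:
    """Normalise a measured root-density function to unit trapezoid integral."""
    z = np.asarray(z, dtype=float)
    beta_raw = np.asarray(beta_raw, dtype=float)
    if np.any(beta_raw < 0):
        raise ValueError("root density must be non-negative")
    total = np.trapezoid(beta_raw, z)
    if total <= 0:
        raise ValueError("root-density profile is identically zero")
    return RootProfile(z=z, beta=beta_raw / total, Lr=float(Lr if Lr is not None else z[-1]))


def exponential_root_profile(scale_cm: float, Lr: float = 200.0, dz: float = 1.0) -> RootProfile:
    """Exponential-decay root profile beta'(z) = exp(-z/scale) over [0, Lr]."""
    z = np.arange(0.0, Lr + dz / 2, dz)
    return normalize_root_density(z, np.exp(-z / scale_cm), Lr=Lr)


# ---------------------------------------------------------------------------
# column assembly

@dataclass(frozen=True)
class SoilLayer:
    """One soil layer with hydraulics and evaporation anchors."""

    z_top: float   # cm
    z_bot: float   # cm
    vgm: VGMParams
    theta_f: float  # field moisture capacity, cm3/cm3
    theta_c: float  # capillary-rupture water content, cm3/cm3

    def __post_init__(self) -> None:
        if not self.theta_c < self.theta_f <= self.vgm.theta_s:
            raise ValueError(
                f"require theta_c < theta_f <= theta_s, got {self.theta_c}, {self.theta_f}, {self.vgm.theta_s}"
            )


@dataclass(frozen=True)
class SoilColumn:
    """Layered 0-200 cm column: hydraulics, uptake stress and roots."""

    layers: tuple[SoilLayer, ...]
    feddes: FeddesParams
    roots: RootProfile
    dz: float = 2.0  # node spacing, cm

    def __post_init__(self) -> None:
        zs = 0.0
        for lay in self.layers:
            if abs(lay.z_top - zs) > 1e-9:
                raise ValueError("soil layers must be contiguous from the surface")
            zs = lay.z_bot
        if abs(zs - self.depth) > 1e-9:
            raise ValueError("soil layers must cover the full column depth")

    @property
    def depth(self) -> float:
        return self.layers[-1].z_bot

    def node_centers(self) -> np.ndarray:
        n = int(round(self.depth / self.dz))
        return (np.arange(n) + 0.5) * self.dz

    def layer_index(self, z) -> np.ndarray:
        """Layer index for each depth (cm)."""
        z = np.atleast_1d(np.asarray(z, dtype=float))
        bounds = np.array([lay.z_bot for lay in self.layers])
        return np.minimum(np.searchsorted(bounds, z, side="left"), len(self.layers) - 1)

    def node_params(self):
        """Per-node VGM parameter arrays aligned with node_centers()."""
        idx = self.layer_index(self.node_centers())
        def take(attr):
            vals = np.array([getattr(lay.vgm, attr) for lay in self.layers])
            return vals[idx]
        return (take("theta_r"), take("theta_s"), take("alpha"), take("n"), take("Ks"), take("l"))

    def surface_layer(self) -> SoilLayer:
        return self.layers[0]


def actual_transpiration(Tp: float, h_nodes: np.ndarray, z_nodes: np.ndarray,
                         roots: RootProfile, f: FeddesParams):
    """Actual transpiration rate and its nodal sink distribution.

    The sink density follows the normalised root profile weighted by the
    Feddes stress factor, s(z) = Tp * beta(z) * alpha(h(z)); the column
    total Sr = Tp * integral(beta * alpha) never exceeds Tp.

    Returns ``(Sr, sink)`` with Sr in the units of Tp and ``sink`` the nodal
    extraction density (per cm of depth) on the node grid.
    """
    if Tp < 0:
        raise ValueError("negative potential transpiration")
    beta = roots.interp(z_nodes)
    norm = np.trapezoid(beta, z_nodes)  # re-normalise on the quadrature grid
    if norm <= 0:
        raise ValueError("root profile has no mass on the node grid")
    alpha = feddes_alpha(h_nodes, f)
    sink = Tp * (beta / norm) * np.asarray(alpha)
    sr = float(np.trapezoid(sink, z_nodes))
    return min(sr, Tp), sink


def actual_evaporation(Ep: float, theta_surf: float, theta_f: float, theta_c: float,
                       form: str = "increasing") -> float:
    """Moisture-limited actual soil evaporation.

    At or above 0.65 * theta_f evaporation proceeds at the potential rate;
    below theta_c it stops.  In between the default ``'increasing'`` form
    interpolates linearly upward from 0 at theta_c; the ``'as_printed'``
    form uses the complementary (downward) ramp found in some texts.
    """
    if Ep < 0:
        raise ValueError("negative potential evaporation")
    if theta_c >= theta_f:
        raise ValueError("require theta_c < theta_f")
    hi = 0.65 * theta_f
    if theta_surf >= hi:
        return Ep
    if theta_surf < theta_c:
        return 0.0
    frac = (theta_surf - theta_c) / (hi - theta_c)
    if form == "as_printed":
        frac = (hi - theta_surf) / (hi - theta_c)
    elif form != "increasing":
        raise ValueError(f"unknown evaporation reduction form {form!r}")
    return Ep * min(max(frac, 0.0), 1.0)
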