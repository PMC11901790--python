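"""Named plot templates: per-species parameter sets for the four
long-term revegetation plots (two woodlands, two grasslands) on
loess-tableland terraces.

Each template bundles the calibrated soil hydraulic parameters of the
upper two measured layers (0-40 and 40-100 cm), the Feddes uptake
thresholds, the canopy extinction and interception parameters, a
root-profile decay scale and an LAI phenology curve.  The deep layer
(100-200 cm) inherits the 40-100 cm hydraulics, the residual content of
the top layer defaults to the measured 40-100 cm value, and saturated
conductivity is uniform with depth; all are overridable.

Field capacity is anchored at the retention curve evaluated at -330 cm
of suction and the capillary-rupture content at 45 % of field capacity;
both enter only the surface-evaporation reduction rule.

The thirteen template scalars exposed through ``param_dict`` /
``with_params`` are the calibration/sensitivity parameter set:
theta_r2, theta_s1, theta_s2, alpha1, alpha2, n1, n2, Ks1, mu, a,
h1, h2, h3.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

from .canopy import CanopyParams
from .soilwater import (
    FeddesParams,
    SoilColumn,
    SoilLayer,
    VGMParams,
    exponential_root_profile,
    vgm_retention,
)

__all__ = ["PlotTemplate", "species_templates", "PARAM_NAMES", "PARAM_RANGES"]

PARAM_NAMES = (
    "theta_r2", "theta_s1", "theta_s2", "alpha1", "alpha2",
    "n1", "n2", "Ks1", "mu", "a", "h1", "h2", "h3",
)

#: admissible ranges used for screening, sensitivity perturbation and
#: calibration bounds.  Zero-excluding lower bounds keep perturbed
#: parameters physically valid; head upper bounds stay strictly negative
#: to preserve the threshold ordering under perturbation.
PARAM_RANGES = {
    "theta_r2": (0.01, 0.08),
    "theta_s1": (0.25, 0.80),
    "theta_s2": (0.25, 0.80),
    "alpha1": (0.002, 0.1),
    "alpha2": (0.002, 0.1),
    "n1": (1.101, 2.0),
    "n2": (1.101, 2.0),
    "Ks1": (0.1, 750.0),
    "mu": (0.01, 1.0),
    "a": (0.01, 1.0),
    "h1": (-2000.0, -10.0),
    "h2": (-10000.0, -20.0),
    "h3": (-60000.0, -30.0),
}

#: suction (cm) anchoring field capacity on the retention curve
FIELD_CAPACITY_HEAD = -330.0
#: capillary-rupture content as a fraction of field capacity
THETA_C_FRACTION = 0.45


@dataclass(frozen=True)
class PlotTemplate:
    """Complete parameterisation of one vegetated plot."""

    species: str
    theta_r2: float
    theta_s1: float
    theta_s2: float
    alpha1: float
    alpha2: float
    n1: float
    n2: float
    Ks1: float
    mu: float
    a: float
    h1: float
    h2: float
    h3: float
    root_scale_cm: float = 30.0      # e-folding depth of the root profile
    root_depth_cm: float = 200.0
    lai_anchors: tuple = ()          # ((month, day, LAI), ...) phenology nodes
    lai_cuts: tuple = ()             # ((month, day, retained_fraction), ...)
    evergreen: bool = False
    l_pore: float = 0.5

    def param_dict(self) -> dict:
        return {k: getattr(self, k) for k in PARAM_NAMES}

    def with_params(self, **overrides) -> "PlotTemplate":
        unknown = set(overrides) - set(PARAM_NAMES)
        if unknown:
            raise ValueError(f"unknown template parameters {sorted(unknown)}")
        return replace(self, **overrides)

    @property
    def canopy(self) -> CanopyParams:
        return CanopyParams(mu=self.mu, a=self.a)

    def build_column(self, dz: float = 2.0) -> SoilColumn:
        """Assemble the 0-200 cm soil column for this plot."""
        vgm1 = VGMParams(theta_r=self.theta_r2, theta_s=self.theta_s1,
                         alpha=self.alpha1, n=self.n1, Ks=self.Ks1, l=self.l_pore)
        vgm2 = VGMParams(theta_r=self.theta_r2, theta_s=self.theta_s2,
                         alpha=self.alpha2, n=self.n2, Ks=self.Ks1, l=self.l_pore)
        layers = []
        for z0, z1, vgm in ((0.0, 40.0, vgm1), (40.0, 100.0, vgm2), (100.0, 200.0, vgm2)):
            tf = float(vgm_retention(FIELD_CAPACITY_HEAD, vgm))
            layers.append(SoilLayer(z_top=z0, z_bot=z1, vgm=vgm,
                                    theta_f=tf, theta_c=THETA_C_FRACTION * tf))
        return SoilColumn(
            layers=tuple(layers),
            feddes=FeddesParams(h1=self.h1, h2=self.h2, h3=self.h3),
            roots=exponential_root_profile(self.root_scale_cm, Lr=self.root_depth_cm),
            dz=dz,
        )

    def field_capacity(self) -> tuple[float, ...]:
        return tuple(lay.theta_f for lay in self.build_column().layers)


def species_templates() -> dict[str, PlotTemplate]:
    """The four shipped plot templates, keyed by species label."""
    return {t.species: t for t in (
        PlotTemplate(
            species="R. pseudoacacia",
            theta_r2=0.0420, theta_s1=0.4818, theta_s2=0.5069,
            alpha1=0.0246, alpha2=0.0376, n1=1.2022, n2=1.1965, Ks1=55.4,
            mu=0.46, a=0.09, h1=-265.7, h2=-885.4, h3=-26134.8,
            root_scale_cm=45.0,
            lai_anchors=((4, 15, 0.3), (5, 15, 1.6), (7, 1, 3.2), (8, 31, 3.4),
                         (9, 30, 2.4), (10, 15, 0.9)),
        ),
        PlotTemplate(
            species="P. orientalis",
            theta_r2=0.0630, theta_s1=0.4612, theta_s2=0.4957,
            alpha1=0.0144, alpha2=0.0138, n1=1.1945, n2=1.2272, Ks1=58.1,
            mu=0.33, a=0.28, h1=-392.6, h2=-1205.2, h3=-20285.4,
            root_scale_cm=40.0, evergreen=True,
            lai_anchors=((4, 15, 2.3), (6, 15, 3.0), (8, 31, 3.5), (10, 15, 2.8)),
        ),
        PlotTemplate(
            species="I. cylindrica",
            theta_r2=0.0565, theta_s1=0.4928, theta_s2=0.4872,
            alpha1=0.0167, alpha2=0.0174, n1=1.1620, n2=1.1448, Ks1=43.2,
            mu=0.36, a=0.16, h1=-442.5, h2=-1202.4, h3=-9125.6,
            root_scale_cm=22.0,
            lai_anchors=((4, 15, 0.2), (5, 31, 1.2), (8, 15, 2.6), (9, 15, 2.3),
                         (10, 15, 1.2)),
        ),
        PlotTemplate(
            species="M. sativa",
            theta_r2=0.0538, theta_s1=0.4778, theta_s2=0.4972,
            alpha1=0.0208, alpha2=0.0228, n1=1.2258, n2=1.2459, Ks1=88.9,
            # stress thresholds ordered so wilting (h3) is the most negative
            mu=0.49, a=0.16, h1=-658.8, h2=-1148.6, h3=-1992.6,
            root_scale_cm=25.0,
            lai_anchors=((4, 15, 0.4), (6, 10, 2.4), (8, 10, 2.6), (9, 20, 2.2),
                         (10, 15, 1.4)),
            lai_cuts=((6, 20, 0.35), (8, 15, 0.35)),
        ),
    )}
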