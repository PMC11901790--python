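"""van Genuchten-Mualem hydraulics, Feddes stress, roots, reduction rules."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from greenwater.soilwater import (
    FeddesParams,
    VGMParams,
    actual_evaporation,
    actual_transpiration,
    exponential_root_profile,
    feddes_alpha,
    normalize_root_density,
    vgm_capacity,
    vgm_conductivity,
    vgm_head,
    vgm_retention,
)

# calibrated top-layer hydraulics of the R. pseudoacacia plot
P1 = VGMParams(theta_r=0.0420, theta_s=0.4818, alpha=0.0246, n=1.2022, Ks=55.4)
FED = FeddesParams(h1=-265.7, h2=-885.4, h3=-26134.8)


class TestRetention:
    def test_saturation_at_zero_head(self):
        assert vgm_retention(0.0, P1) == pytest.approx(P1.theta_s)

    def test_residual_asymptote(self):
        # fast asymptote for a steep retention curve
        steep = VGMParams(theta_r=0.06, theta_s=0.40, alpha=0.01, n=2.0, Ks=10.0)
        assert vgm_retention(-1e7, steep) == pytest.approx(0.06, abs=1e-5)
        # the flat loess curve approaches theta_r from above, monotonically
        assert (P1.theta_r < vgm_retention(-1e9, P1) < vgm_retention(-1e6, P1))

    def test_closed_form_at_minus_100cm(self):
        # independent evaluation of the retention closed form
        m = 1.0 - 1.0 / 1.2022
        se = (1.0 + (0.0246 * 100.0) ** 1.2022) ** (-m)
        expected = 0.0420 + (0.4818 - 0.0420) * se
        assert vgm_retention(-100.0, P1) == pytest.approx(expected, rel=1e-12)

    @given(st.floats(-1e5, -0.01), st.floats(0.01, 1e4))
    def test_monotone_in_suction(self, h, dh):
        assert vgm_retention(h - dh, P1) <= vgm_retention(h, P1)

    @given(st.floats(-1e5, -0.1))
    def test_head_inverts_retention(self, h):
        theta = float(vgm_retention(h, P1))
        assert float(vgm_head(theta, P1)) == pytest.approx(h, rel=1e-6)

    def test_capacity_is_retention_derivative(self):
        h = -250.0
        eps = 1e-4
        fd = (vgm_retention(h + eps, P1) - vgm_retention(h - eps, P1)) / (2 * eps)
        assert vgm_capacity(h, P1) == pytest.approx(float(fd), rel=1e-6)

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            VGMParams(theta_r=0.5, theta_s=0.4, alpha=0.02, n=1.5, Ks=10.0)
        with pytest.raises(ValueError):
            VGMParams(theta_r=0.05, theta_s=0.4, alpha=0.02, n=0.9, Ks=10.0)


class TestConductivity:
    def test_saturated_value(self):
        assert vgm_conductivity(0.0, P1) == pytest.approx(P1.Ks)

    def test_mualem_closed_form_midrange(self):
        m = 1.0 - 1.0 / 1.2022
        se = (1.0 + (0.0246 * 300.0) ** 1.2022) ** (-m)
        expected = 55.4 * se ** 0.5 * (1.0 - (1.0 - se ** (1.0 / m)) ** m) ** 2
        assert vgm_conductivity(-300.0, P1) == pytest.approx(expected, rel=1e-10)

    @given(st.floats(-5e4, -0.01, exclude_max=True))
    def test_bounded_and_monotone(self, h):
        k = float(vgm_conductivity(h, P1))
        assert 0.0 < k <= P1.Ks
        assert float(vgm_conductivity(h - 100.0, P1)) <= k


class TestFeddes:
    @pytest.mark.parametrize("h, expected", [
        (0.0, 0.0),                       # saturated: anoxia shuts uptake
        ((-265.7) / 2, 0.5),              # wet-side linear ramp
        ((-265.7 - 885.4) / 2, 1.0),      # optimal plateau
        ((-885.4 - 26134.8) / 2, 0.5),    # stress-side midpoint
        (-30000.0, 0.0),                  # below wilting
    ])
    def test_piecewise_branches(self, h, expected):
        assert feddes_alpha(h, FED) == pytest.approx(expected, rel=1e-9)

    @given(st.floats(-6e4, 0.0))
    def test_bounded(self, h):
        assert 0.0 <= feddes_alpha(h, FED) <= 1.0

    def test_threshold_ordering_enforced(self):
        with pytest.raises(ValueError):
            FeddesParams(h1=-100.0, h2=-50.0, h3=-1000.0)


class TestRootProfile:
    def test_uniform_density_normalises_to_inverse_depth(self):
        rp = normalize_root_density(np.linspace(0, 200, 101), np.ones(101))
        assert np.allclose(rp.beta, 1.0 / 200.0)

    def test_exponential_profile_matches_analytic_normalisation(self):
        rp = exponential_root_profile(30.0, Lr=200.0, dz=0.25)
        # beta(0) = (1/s) / (1 - exp(-L/s)) for the continuous profile
        expected0 = (1.0 / 30.0) / (1.0 - np.exp(-200.0 / 30.0))
        assert rp.beta[0] == pytest.approx(expected0, rel=1e-3)
        assert np.trapezoid(rp.beta, rp.z) == pytest.approx(1.0, abs=1e-8)

    def test_all_zero_profile_rejected(self):
        with pytest.raises(ValueError):
            normalize_root_density([0.0, 100.0], [0.0, 0.0])


class TestActualFluxes:
    def test_unstressed_uptake_equals_potential(self):
        z = np.linspace(1.0, 199.0, 100)
        roots = exponential_root_profile(30.0)
        h = np.full(100, (FED.h1 + FED.h2) / 2)  # plateau everywhere
        sr, sink = actual_transpiration(3.0, h, z, roots, FED)
        assert sr == pytest.approx(3.0, rel=1e-9)
        assert np.all(sink >= 0)

    def test_fully_stressed_uptake_is_zero(self):
        z = np.linspace(1.0, 199.0, 100)
        roots = exponential_root_profile(30.0)
        sr, sink = actual_transpiration(3.0, np.full(100, -5e4), z, roots, FED)
        assert sr == 0.0
        assert np.all(sink == 0.0)

    def test_stepwise_stress_matches_manual_quadrature(self):
        z = np.array([0.0, 50.0, 100.0, 150.0, 200.0])
        roots = normalize_root_density(z, np.ones_like(z))
        h = np.array([-500.0, -500.0, -30000.0, -30000.0, -30000.0])
        sr, _ = actual_transpiration(2.0, h, z, roots, FED)
        alpha = feddes_alpha(h, FED)
        expected = 2.0 * np.trapezoid(roots.beta * alpha, z)
        assert sr == pytest.approx(float(expected), rel=1e-9)

    @pytest.mark.parametrize("theta, frac", [
        (0.7 * 0.30, 1.0),                     # at/above 0.65 theta_f: potential
        (0.05, 0.0),                           # below theta_c: shut off
        ((0.10 + 0.65 * 0.30) / 2, 0.5),       # midpoint of the linear ramp
    ])
    def test_evaporation_reduction_branches(self, theta, frac):
        er = actual_evaporation(2.0, theta, theta_f=0.30, theta_c=0.10)
        assert er == pytest.approx(2.0 * frac, rel=1e-9)

    def test_as_printed_ramp_is_complementary(self):
        mid = (0.10 + 0.65 * 0.30) / 2
        inc = actual_evaporation(2.0, mid, 0.30, 0.10, form="increasing")
        dec = actual_evaporation(2.0, mid, 0.30, 0.10, form="as_printed")
        assert inc + dec == pytest.approx(2.0)
        at_cutoff = actual_evaporation(2.0, 0.10, 0.30, 0.10, form="as_printed")
        assert at_cutoff == pytest.approx(2.0)  # printed ramp peaks when dry

    @given(st.floats(0.0, 0.5))
    def test_evaporation_bounded_by_potential(self, theta):
        assert 0.0 <= actual_evaporation(2.0, theta, 0.30, 0.10) <= 2.0
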