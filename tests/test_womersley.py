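"""Tests for the analytical elastic/rigid tube solutions."""

import math

import numpy as np
import pytest
from numpy.testing import assert_allclose
from scipy.optimize import root
from scipy.special import jv

from vesselflow.errors import ConfigError, OutOfDomainError
from vesselflow.womersley import (
    WomersleyCase,
    elastic_solution,
    frequency_equation_residuals,
    moens_korteweg_speed,
    oscillatory_axial_amplitude,
    rigid_solution,
    womersley_number,
    _f10,
)


@pytest.fixture(scope="module")
def case():
    """The pulsatile verification cylinder: R = 3 mm, alpha = 3, k_p = -50 Pa/m."""
    return WomersleyCase(
        R=3e-3, omega=4.0, rho=1000.0, mu=4e-3, k_p=-50.0,
        Y=20e3, h=0.3e-3, sigma=0.5, rho_wall=1000.0,
    )


class TestWomersleyNumber:
    def test_verification_case_is_three(self):
        # R = 3 mm, period pi/2 s -> omega = 4 rad/s, blood-like fluid
        assert womersley_number(3e-3, 2 * np.pi / (np.pi / 2), 1000.0, 4e-3) == pytest.approx(
            3.0, rel=1e-15
        )

    def test_linearity_in_radius(self):
        a1 = womersley_number(1e-3, 4.0, 1000.0, 4e-3)
        assert womersley_number(2e-3, 4.0, 1000.0, 4e-3) == pytest.approx(2 * a1, rel=1e-14)

    def test_low_frequency_limit(self):
        assert womersley_number(3e-3, 1e-9, 1000.0, 4e-3) < 1e-4

    def test_nonpositive_inputs_rejected(self):
        with pytest.raises(ConfigError):
            womersley_number(3e-3, -1.0, 1000.0, 4e-3)


class TestElasticFactor:
    def test_moens_korteweg_hand_value(self, case):
        # c0 = sqrt(Yh/(2 rho R)) = sqrt(20e3*3e-4/(2*1000*3e-3)) = 1 m/s
        assert case.c0 == pytest.approx(1.0, rel=1e-14)
        assert moens_korteweg_speed(20e3, 0.3e-3, 1000.0, 3e-3) == pytest.approx(1.0, rel=1e-14)

    def test_frequency_equation_residuals_vanish(self, case):
        g = _f10(case.Lambda)
        k = case.wall_mass_ratio
        lam = case.Y * case.h / ((1 - case.sigma**2) * case.rho * case.c**2 * case.R)
        r_ax, r_rad = frequency_equation_residuals(case.M, lam, g, k, case.sigma)
        assert abs(r_ax) < 1e-12
        assert abs(r_rad) < 1e-12

    def test_independent_root_finder_agrees(self, case):
        """Re-solve the two shell equations from a perturbed start with a
        generic nonlinear solver; it must land on the same (M, lam)."""
        g = _f10(case.Lambda)
        k = case.wall_mass_ratio
        lam0 = case.Y * case.h / ((1 - case.sigma**2) * case.rho * case.c**2 * case.R)

        def fun(x):
            M = x[0] + 1j * x[1]
            lam = x[2] + 1j * x[3]
            r1, r2 = frequency_equation_residuals(M, lam, g, k, case.sigma)
            return [r1.real, r1.imag, r2.real, r2.imag]

        x0 = [case.M.real * 1.1 + 0.05, case.M.imag * 0.9 - 0.02, lam0.real * 1.1, lam0.imag * 0.9]
        sol = root(fun, x0, tol=1e-14)
        assert sol.success
        assert sol.x[0] + 1j * sol.x[1] == pytest.approx(case.M, rel=1e-8)
        assert sol.x[2] + 1j * sol.x[3] == pytest.approx(lam0, rel=1e-8)

    def test_inviscid_massless_limit_recovers_moens_korteweg(self):
        # large alpha, negligible wall mass: M -> 1 - sigma/2, c -> c0
        case = WomersleyCase(
            R=3e-3, omega=4e4, rho=1000.0, mu=4e-3, k_p=-50.0,
            Y=20e3, h=0.3e-3, sigma=0.5, rho_wall=1e-6,
        )
        assert case.alpha == pytest.approx(300.0)
        assert case.M == pytest.approx(1 - case.sigma / 2, abs=5e-3)
        assert abs(case.c) == pytest.approx(case.c0, rel=1e-2)

    def test_stiffening_increases_wave_speed(self, case):
        stiffer = WomersleyCase(
            R=3e-3, omega=4.0, rho=1000.0, mu=4e-3, k_p=-50.0,
            Y=100 * 20e3, h=0.3e-3, sigma=0.5, rho_wall=1000.0,
        )
        assert abs(stiffer.c) > abs(case.c)
        # M is dimensionless in (alpha, sigma, wall mass): unchanged by Y
        assert stiffer.M == pytest.approx(case.M, rel=1e-12)


class TestElasticSolution:
    def test_wall_value_matches_slip_expression(self, case):
        """At r = R the oscillatory axial velocity reduces to
        (H/(rho c)) (1 - M) e^{i omega (t - z/c)} identically in t."""
        ts = np.linspace(0.0, case.period, 7)
        for t in ts:
            _, w, _ = elastic_solution(case, case.R, 0.0, t)
            expected = (
                case.H / (case.rho * case.c) * (1 - case.M)
                * np.exp(1j * case.omega * t)
            ).real
            assert w == pytest.approx(expected, abs=1e-16 + 1e-12 * abs(expected))

    def test_radial_velocity_vanishes_on_axis(self, case):
        for t in np.linspace(0, case.period, 5):
            _, _, u = elastic_solution(case, 0.0, 0.0, t)
            assert u == 0.0

    def test_axial_profile_flat_at_axis(self, case):
        eps = 1e-7 * case.R
        _, w0, _ = elastic_solution(case, 0.0, 0.0, 0.3)
        _, we, _ = elastic_solution(case, eps, 0.0, 0.3)
        assert abs(we - w0) < 1e-9 * max(abs(w0), 1e-30)

    def test_no_drive_means_no_flow(self):
        quiet = WomersleyCase(
            R=3e-3, omega=4.0, rho=1000.0, mu=4e-3, k_p=0.0, k_s=0.0, p0=7.0,
            Y=20e3, h=0.3e-3, sigma=0.5,
        )
        p, w, u = elastic_solution(quiet, 1e-3, 0.01, 0.3)
        assert p == pytest.approx(7.0, abs=1e-12)
        assert w == pytest.approx(0.0, abs=1e-18)
        assert u == pytest.approx(0.0, abs=1e-18)

    def test_outside_radius_rejected(self, case):
        with pytest.raises(OutOfDomainError):
            elastic_solution(case, 1.01 * case.R, 0.0, 0.0)

    def test_steady_component_is_poiseuille(self):
        steady = WomersleyCase(
            R=3e-3, omega=4.0, rho=1000.0, mu=4e-3, k_p=0.0, k_s=-100.0,
            Y=20e3, h=0.3e-3, sigma=0.5,
        )
        _, w, _ = elastic_solution(steady, 0.0, 0.0, 0.0)
        assert w == pytest.approx(100.0 * (3e-3) ** 2 / (4 * 4e-3), rel=1e-13)

    def test_bessel_power_series_oracle(self, case):
        """scipy's complex J0 cross-validated by the truncated power series
        J0(x) = sum_k (-x^2/4)^k / (k!)^2 for the arguments in use."""
        for arg in [case.Lambda, case.Lambda * 0.95, case.Lambda * 0.5]:
            series = sum((-(arg**2) / 4.0) ** k / float(math.factorial(k)) ** 2 for k in range(40))
            assert jv(0, arg) == pytest.approx(series, rel=1e-12)


class TestBoundaryVelocityRatioConsistency:
    def test_ratio_equals_amplitude_quotient(self, case):
        """The closed-form boundary velocity ratio must equal the quotient of
        oscillatory axial amplitudes sampled at r = R and r = R - dr."""
        from vesselflow.boundaries import boundary_velocity_ratio

        for dE in (0.01, 0.05, 0.10):
            dr = dE * case.R
            direct = boundary_velocity_ratio(case.M, case.Lambda, dE, reduction="complex")
            sampled = oscillatory_axial_amplitude(case, case.R) / oscillatory_axial_amplitude(
                case, case.R - dr
            )
            assert direct == pytest.approx(sampled, rel=1e-12)


class TestRigidSolution:
    def test_no_slip_at_wall(self, case):
        for t in np.linspace(0, case.period, 5):
            w = rigid_solution(case, case.R, 0.0, t)
            assert abs(w) < 1e-16

    def test_steady_centerline_value(self):
        steady = WomersleyCase(R=3e-3, omega=4.0, rho=1000.0, mu=4e-3, k_s=-100.0)
        w = rigid_solution(steady, 0.0, 0.0, 0.0)
        assert w == pytest.approx(100.0 * (3e-3) ** 2 / (4 * 4e-3), rel=1e-13)

    def test_elastic_profile_with_unit_elasticity_factor_is_rigid(self, case):
        """Forcing M = 1 in the elastic oscillatory profile reproduces the
        rigid profile (the rigid wall is the M -> 1 limit, since
        H/(rho c) = i k_p/(rho omega) is independent of c)."""
        import copy

        frozen = copy.copy(case)
        frozen.M = 1.0 + 0.0j
        r = np.linspace(0, case.R, 9)
        for t in (0.1, 0.6):
            _, w_el, _ = elastic_solution(frozen, r, 0.0, t)
            w_rig = rigid_solution(case, r, 0.0, t)
            assert_allclose(w_el, w_rig, atol=1e-15)
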