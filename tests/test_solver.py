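"""Flow-level tests of the simulation driver and boundary operators."""

import numpy as np
import pytest
from numpy.testing import assert_allclose

from vesselflow import (
    ElasticWallModel,
    classify_and_link,
    voxelize_cylinder,
)
from vesselflow.errors import DivergenceError, StabilityError
from vesselflow.solver import PressureBC, Simulation, VelocityBC
from vesselflow.lattice import equilibrium


def closed_box_domain(n=14):
    """Cuboid fluid region fully enclosed by walls (no inlet/outlet)."""
    mask = np.zeros((n, n, n), dtype=bool)
    mask[2:-2, 2:-2, 2:-2] = True
    return classify_and_link(mask, open_ends=False)


class TestConservationAndFixedPoints:
    def test_closed_box_mass_conservation(self, spec_blood):
        """Bounceback walls and BGK collisions keep total mass constant to
        round-off over a thousand steps of a perturbed state."""
        dom = closed_box_domain()
        sim = Simulation(dom, spec_blood)
        rng = np.random.default_rng(11)
        u = rng.uniform(-0.01, 0.01, size=(len(sim.stream_ids), 3))
        rho = rng.uniform(0.99, 1.01, size=len(sim.stream_ids))
        sim.f[sim.stream_ids] = equilibrium(rho, u)
        m0 = sim.total_mass()
        sim.step(1000)
        assert abs(sim.total_mass() - m0) / m0 <= 1e-12

    def test_rest_state_is_fixed_point_with_boundaries(self, spec_blood):
        """Cylinder with equal-pressure ends and elastic walls stays at rest."""
        dom = voxelize_cylinder(6, 12, spec_blood)
        sim = Simulation(
            dom, spec_blood, wall=ElasticWallModel(F=0.85),
            inlet=PressureBC(0.0), outlet=PressureBC(0.0),
        )
        sim.step(200)
        assert sim.last_umax < 1e-14
        assert_allclose(sim.rho[sim.stream_ids], 1.0, atol=1e-14)

    def test_zero_waveform_decays_to_rest(self, spec_blood):
        dom = voxelize_cylinder(6, 12, spec_blood)
        sim = Simulation(
            dom, spec_blood, inlet=VelocityBC(0.0), outlet=PressureBC(0.0),
        )
        # kick the interior, then let the zero drive damp it out
        rng = np.random.default_rng(3)
        u = rng.uniform(-0.005, 0.005, size=(len(sim.stream_ids), 3))
        sim.f[sim.stream_ids] = equilibrium(np.ones(len(sim.stream_ids)), u)
        sim.step(2500)
        assert sim.last_umax < 1e-5

    def test_determinism(self, spec_blood):
        dom = voxelize_cylinder(5, 10, spec_blood)

        def run():
            sim = Simulation(dom, spec_blood, inlet=PressureBC(0.1), outlet=PressureBC(0.0))
            sim.step(100)
            return sim.f.copy()

        assert (run() == run()).all()

    def test_nan_raises_divergence_with_step(self, spec_blood):
        dom = voxelize_cylinder(5, 10, spec_blood)
        sim = Simulation(dom, spec_blood, inlet=PressureBC(0.1), outlet=PressureBC(0.0))
        sim.step(3)
        sim.f[sim.stream_ids[10], :] = np.nan
        with pytest.raises(DivergenceError, match="4"):
            sim.step(1)

    def test_mach_guard_trips(self, spec_blood):
        dom = voxelize_cylinder(5, 10, spec_blood)
        sim = Simulation(dom, spec_blood, inlet=PressureBC(500.0), outlet=PressureBC(0.0))
        with pytest.raises(StabilityError):
            sim.step(500)


class TestPoiseuille:
    def test_bounceback_profile_parabolic(self, poiseuille_pair_r10, spec_blood):
        """Pressure-driven pipe flow relaxes to a parabolic profile.  The
        staircase wall makes the effective no-slip radius slightly smaller
        than nominal, so the profile is compared in shape (parabola fit) and
        against the nominal-radius oracle at a first-order tolerance."""
        sim = poiseuille_pair_r10["bounceback"]
        dom = sim.domain
        u = sim.velocity_field(physical=True)[..., 2]
        m = dom.shape[0] // 2
        prof = u[:, m, dom.shape[2] // 2]
        x = (np.arange(dom.shape[0]) + 0.5 - dom.shape[0] / 2) * spec_blood.dx
        sel = np.isfinite(prof)
        # parabola fit w = a (Reff^2 - r^2): shape error under 1.5% of peak
        coef = np.polyfit(x[sel] ** 2, prof[sel], 1)
        fit = np.polyval(coef, x[sel] ** 2)
        assert np.max(np.abs(prof[sel] - fit)) / prof[sel].max() < 0.015
        # nominal-radius analytic oracle: first-order staircase accuracy
        mu = 4e-3
        L_eff = 39 * spec_blood.dx
        k = 0.6 / L_eff
        Rm = 10 * spec_blood.dx
        w_an = k * (Rm**2 - x[sel] ** 2) / (4 * mu)
        assert np.max(np.abs(prof[sel] - w_an)) / w_an.max() < 0.10

    def test_flux_scales_with_pressure_difference(self, poiseuille_pair_r10, spec_blood):
        """Volume flux against Hagen-Poiseuille at the nominal radius; the
        R^4 sensitivity to the effective staircase radius dominates the
        deviation (~10% at R = 10 dx)."""
        sim = poiseuille_pair_r10["bounceback"]
        u = sim.velocity_field(physical=True)[..., 2]
        kz = sim.domain.shape[2] // 2
        Q = np.nansum(u[:, :, kz]) * spec_blood.dx**2
        mu = 4e-3
        Rm = 10 * spec_blood.dx
        Q_an = np.pi * Rm**4 * (0.6 / (39 * spec_blood.dx)) / (8 * mu)
        assert Q == pytest.approx(Q_an, rel=0.12)

    def test_refinement_reduces_profile_error(self, spec_blood):
        """Max profile error vs the nominal-radius parabola decreases
        monotonically under grid refinement (first-order staircase walls)."""
        errs = []
        for R, L, steps in ((5, 20, 1500), (10, 20, 4000), (20, 20, 12000)):
            dom = voxelize_cylinder(R, L, spec_blood)
            dp = 0.6 * (10.0 / R) ** 2 / 2  # keep lattice velocity moderate
            sim = Simulation(dom, spec_blood, inlet=PressureBC(dp), outlet=PressureBC(0.0))
            sim.step(steps)
            u = sim.velocity_field(physical=True)[..., 2]
            m = dom.shape[0] // 2
            prof = u[:, m, dom.shape[2] // 2]
            x = (np.arange(dom.shape[0]) + 0.5 - dom.shape[0] / 2) * spec_blood.dx
            sel = np.isfinite(prof)
            mu = 4e-3
            k = dp / ((L - 1) * spec_blood.dx)
            w_an = k * ((R * spec_blood.dx) ** 2 - x[sel] ** 2) / (4 * mu)
            errs.append(np.max(np.abs(prof[sel] - w_an)) / w_an.max())
        assert errs[0] > errs[1] > errs[2]

    def test_elastic_f0_profile_parabolic_with_shifted_wall(self, poiseuille_pair_r10):
        """The elastic condition at F = 0, dr = dx enforces zero velocity at
        the wall nodes (one link beyond bounceback's halfway surface), so the
        profile is parabolic with a slightly larger effective radius."""
        sim = poiseuille_pair_r10["elastic_f0"]
        dom = sim.domain
        u = sim.velocity_field(physical=False)[..., 2]
        m = dom.shape[0] // 2
        prof = u[:, m, dom.shape[2] // 2]
        x = np.arange(dom.shape[0]) + 0.5 - dom.shape[0] / 2
        sel = np.isfinite(prof)
        coef = np.polyfit(x[sel] ** 2, prof[sel], 1)
        fit = np.polyval(coef, x[sel] ** 2)
        assert np.max(np.abs(prof[sel] - fit)) / prof[sel].max() < 0.015
        Reff = np.sqrt(-coef[1] / coef[0])
        assert 9.5 < Reff < 11.5


class TestVelocityInlet:
    def test_constant_waveform_develops_poiseuille(self, spec_blood):
        """Steady parabolic inflow: downstream profile is parabolic and the
        imposed flux is conserved along the pipe."""
        R, L = 8, 40
        dom = voxelize_cylinder(R, L, spec_blood)
        U0 = 0.008  # m/s, peak
        sim = Simulation(
            dom, spec_blood, inlet=VelocityBC(U0), outlet=PressureBC(0.0),
        )
        sim.step(4000)
        u = sim.velocity_field(physical=True)[..., 2]
        kz = 3 * L // 4
        m = dom.shape[0] // 2
        prof = u[:, m, kz]
        x = np.arange(dom.shape[0]) + 0.5 - dom.shape[0] / 2
        sel = np.isfinite(prof)
        coef = np.polyfit(x[sel] ** 2, prof[sel], 1)
        fit = np.polyval(coef, x[sel] ** 2)
        assert np.max(np.abs(prof[sel] - fit)) / prof[sel].max() < 0.02
        # flux conservation between inlet-adjacent and downstream planes
        Q_in = np.nansum(u[:, :, 3])
        Q_dn = np.nansum(u[:, :, kz])
        assert Q_dn == pytest.approx(Q_in, rel=0.02)


class TestOscillatoryPressureDrive:
    def test_rigid_womersley_profile(self, spec_blood):
        """Oscillatory pressure difference across a rigid pipe reproduces the
        rigid Womersley solution mid-domain.  The staircase wall's
        effective-radius bias (~0.3 dx) bounds the accuracy at R = 10 dx to
        roughly ten percent of the phase peak, as for steady Poiseuille."""
        from vesselflow.womersley import WomersleyCase, rigid_solution

        R, L = 10, 40
        dom = voxelize_cylinder(R, L, spec_blood)
        Rm = R * spec_blood.dx
        alpha = 3.0
        mu, rho = 4e-3, 1000.0
        omega = alpha**2 * (mu / rho) / Rm**2
        case = WomersleyCase(R=Rm, omega=omega, rho=rho, mu=mu, k_p=-500.0)
        L_eff = (L - 1) * spec_blood.dx
        T = case.period

        def dp(t):
            ramp = min(t / (0.5 * T), 1.0)
            # uniform-gradient convention: gradient k_p cos(omega t)
            return -ramp * case.k_p * L_eff * np.cos(omega * t)

        sim = Simulation(dom, spec_blood, inlet=PressureBC(dp), outlet=PressureBC(0.0))
        steps_per_period = T / spec_blood.dt
        sim.step(int(round(3 * steps_per_period)))
        errs = []
        for frac in (0.125, 0.375, 0.625):
            target = int(round((3 + frac) * steps_per_period))
            sim.step(target - sim.step_index)
            t = sim.step_index * spec_blood.dt
            u = sim.velocity_field(physical=True)[..., 2]
            m = dom.shape[0] // 2
            prof = u[:, m, dom.shape[2] // 2]
            x = (np.arange(dom.shape[0]) + 0.5 - dom.shape[0] / 2) * spec_blood.dx
            sel = np.isfinite(prof)
            w_an = rigid_solution(case, np.abs(x[sel]), 0.0, t)
            errs.append(np.max(np.abs(prof[sel] - w_an)) / np.max(np.abs(w_an)))
        assert max(errs) < 0.12
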