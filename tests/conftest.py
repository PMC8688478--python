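"""Shared fixtures.

The expensive pulsatile verification runs (elastic + rigid cylinder at
R = 24 lattice units) are session-scoped so the acceptance tests and the
qualitative wall-shear-stress comparison share two simulations.
"""

import pytest

from vesselflow import build_units, voxelize_cylinder
from vesselflow.solver import PressureBC, Simulation
from vesselflow.verification import VerificationConfig, run_verification_case


@pytest.fixture(scope="session")
def spec_blood():
    """Blood-like fluid on a 0.1 mm lattice at tau = 0.8."""
    return build_units(dx=1e-4, tau=0.8, nu_physical=4e-6, rho_physical=1000.0)


@pytest.fixture(scope="session")
def verification_runs():
    """Matched elastic and rigid pulsatile cylinder runs (R = 24 dx, alpha = 3)."""
    out = {}
    for mode in ("elastic", "rigid"):
        cfg = VerificationConfig(wall_mode=mode)
        report, sim = run_verification_case(cfg, return_sim=True)
        out[mode] = {"report": report, "sim": sim, "config": cfg}
    return out


@pytest.fixture(scope="session")
def poiseuille_pair_r10(spec_blood):
    """Steady pressure-driven pipe flow at R = 10 dx: bounceback vs the
    elastic condition in its rigid limit (F = 0, dr = dx)."""
    from vesselflow import ElasticWallModel

    dom = voxelize_cylinder(10, 40, spec_blood)
    sims = {}
    for name, wall in (("bounceback", None), ("elastic_f0", ElasticWallModel(F=0.0))):
        sim = Simulation(dom, spec_blood, wall=wall, inlet=PressureBC(0.6), outlet=PressureBC(0.0))
        sim.step(4000)
        sims[name] = sim
    return sims


@pytest.fixture(scope="session")
def poiseuille_wss_r12(spec_blood):
    """Steady pipe flow at R = 12 dx for the wall-shear-stress check."""
    dom = voxelize_cylinder(12, 36, spec_blood)
    sim = Simulation(dom, spec_blood, wall=None, inlet=PressureBC(0.6), outlet=PressureBC(0.0))
    sim.step(4000)
    return sim
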