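"""D3Q19 single-relaxation-time lattice core.

The discretization follows the standard D3Q19 stencil: one rest direction,
six axis directions and twelve edge-diagonal directions.  All solver state is
kept in lattice units (dx = dt = 1, reference density rho0 = 1); the
:class:`LatticeSpec` carries the conversion factors back to SI.

Population layout convention used throughout the package: the 19 populations
are the *last* axis of an array, i.e. a field of populations has shape
``(..., 19)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigError, InvalidStateError, StabilityError

# --- D3Q19 stencil ---------------------------------------------------------
# Order: rest; axis directions i = 1-6; edge diagonals i = 7-18.
C = np.array(
    [
        (0, 0, 0),
        (1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0), (0, 0, 1), (0, 0, -1),
        (1, 1, 0), (-1, -1, 0), (1, -1, 0), (-1, 1, 0),
        (1, 0, 1), (-1, 0, -1), (1, 0, -1), (-1, 0, 1),
        (0, 1, 1), (0, -1, -1), (0, 1, -1), (0, -1, 1),
    ],
    dtype=np.int64,
)

W = np.array([1.0 / 3.0] + [1.0 / 18.0] * 6 + [1.0 / 36.0] * 12)

#: index of the direction opposite to each direction (c_opp = -c_i)
OPPOSITE = np.array(
    [int(np.flatnonzero((C == -C[i]).all(axis=1))[0]) for i in range(19)],
    dtype=np.int64,
)

CS = 1.0 / np.sqrt(3.0)  # lattice speed of sound
CS2 = 1.0 / 3.0

Q = 19


@dataclass(frozen=True)
class LatticeSpec:
    """Lattice discretization constants and physical<->lattice unit conversion.

    Parameters
    ----------
    dx : float
        Lattice spacing in metres.
    dt : float
        Time step in seconds.
    tau : float
        BGK relaxation time in lattice units (must exceed 1/2).
    rho_physical : float
        Physical density (kg/m^3) mapped to lattice density 1.
    """

    dx: float
    dt: float
    tau: float
    rho_physical: float = 1000.0
    cs: float = field(default=CS, init=False)
    weights: np.ndarray = field(default_factory=lambda: W, init=False, repr=False)
    velocities: np.ndarray = field(default_factory=lambda: C, init=False, repr=False)

    def __post_init__(self):
        if self.dx <= 0 or self.dt <= 0:
            raise ConfigError(f"dx and dt must be positive, got dx={self.dx}, dt={self.dt}")
        if self.tau <= 0.5:
            raise ConfigError(
                f"tau={self.tau} implies nonpositive lattice viscosity (tau must exceed 1/2)"
            )

    @property
    def nu_lattice(self) -> float:
        """Kinematic viscosity in lattice units, nu = Cs^2 (tau - 1/2)."""
        return CS2 * (self.tau - 0.5)

    @property
    def nu_physical(self) -> float:
        """Kinematic viscosity in m^2/s."""
        return self.nu_lattice * self.dx**2 / self.dt

    # unit conversion factors ------------------------------------------------
    @property
    def velocity_scale(self) -> float:
        """m/s per lattice velocity unit."""
        return self.dx / self.dt

    @property
    def pressure_scale(self) -> float:
        """Pa per lattice pressure unit (also the stress scale)."""
        return self.rho_physical * self.velocity_scale**2

    def pressure_to_density(self, p_physical, p_ref=0.0):
        """Lattice density imposing physical pressure ``p_physical`` (Pa).

        ``p_ref`` is the physical pressure mapped to the reference density 1.
        """
        return 1.0 + (np.asarray(p_physical) - p_ref) / (self.pressure_scale * CS2)

    def density_to_pressure(self, rho_lattice, p_ref=0.0):
        """Physical pressure (Pa) of lattice density; p = Cs^2 rho about the reference."""
        return (np.asarray(rho_lattice) - 1.0) * CS2 * self.pressure_scale + p_ref


def build_units(dx: float, tau: float, nu_physical: float, rho_physical: float = 1000.0) -> LatticeSpec:
    """Choose the time step so the lattice reproduces a physical viscosity.

    dt = Cs^2 (tau - 1/2) dx^2 / nu_physical, which makes
    ``spec.nu_physical == nu_physical`` to round-off.
    """
    if dx <= 0:
        raise ConfigError(f"dx must be positive, got {dx}")
    if tau <= 0.5:
        raise ConfigError(f"tau={tau} gives nonphysical (<=0) viscosity; need tau > 1/2")
    if nu_physical <= 0:
        raise ConfigError(f"nu_physical must be positive, got {nu_physical}")
    dt = CS2 * (tau - 0.5) * dx**2 / nu_physical
    return LatticeSpec(dx=dx, dt=dt, tau=tau, rho_physical=rho_physical)


# --- kinetic functions ------------------------------------------------------

def equilibrium(rho, u, spec: LatticeSpec | None = None) -> np.ndarray:
    """Second-order Maxwell-Boltzmann equilibrium populations.

    f_i^eq = w_i rho (1 + c.u/Cs^2 + (c.u)^2/(2 Cs^4) - |u|^2/(2 Cs^2))

    Parameters
    ----------
    rho : array_like, shape (...)
        Density, strictly positive.
    u : array_like, shape (..., 3) or (3,)
        Velocity in lattice units, |u| < Cs.

    Returns
    -------
    ndarray, shape (..., 19)
    """
    rho = np.asarray(rho, dtype=float)
    u = np.asarray(u, dtype=float)
    if np.any(rho <= 0):
        raise InvalidStateError("equilibrium requires rho > 0")
    u2 = np.sum(u * u, axis=-1)
    if np.any(u2 >= CS2):
        raise StabilityError("equilibrium requires |u| < Cs (lattice speed of sound)")
    cu = u @ C.T.astype(float)  # (..., 19)
    feq = W * rho[..., None] * (1.0 + 3.0 * cu + 4.5 * cu**2 - 1.5 * u2[..., None])
    return feq


def macroscopics(f) -> tuple[np.ndarray, np.ndarray]:
    """Density and velocity moments of populations ``f`` of shape (..., 19).

    rho = sum_i f_i ; u = sum_i f_i c_i / rho.
    """
    f = np.asarray(f, dtype=float)
    rho = f.sum(axis=-1)
    if np.any(rho <= 0):
        bad = np.argwhere(np.atleast_1d(rho) <= 0)
        raise InvalidStateError(f"nonpositive density at site(s) {bad[:5].tolist()}")
    u = (f @ C.astype(float)) / rho[..., None]
    return rho, u


@dataclass
class FluidState:
    """Populations on a periodic box plus derived macroscopic fields.

    Used by the reference (pure numpy) collide-and-stream path for small
    property checks; production runs use :class:`vesselflow.solver.Simulation`.
    """

    f: np.ndarray  # (nx, ny, nz, 19)
    step: int = 0

    @property
    def rho(self) -> np.ndarray:
        return self.f.sum(axis=-1)

    @property
    def u(self) -> np.ndarray:
        return macroscopics(self.f)[1]

    @property
    def pressure(self) -> np.ndarray:
        """Lattice pressure p = Cs^2 rho."""
        return CS2 * self.rho

    @classmethod
    def equilibrium_box(cls, shape, rho=1.0, u=(0.0, 0.0, 0.0)) -> "FluidState":
        feq = equilibrium(np.full(shape, float(rho)), np.broadcast_to(u, shape + (3,)))
        return cls(f=np.array(feq), step=0)


def collide_stream(state: FluidState, spec: LatticeSpec, mach_guard: float = 0.1) -> FluidState:
    """One BGK collide + periodic-streaming step of a :class:`FluidState` box.

    This is the reference implementation of Eq.-(1)-style evolution on a fully
    periodic domain (no boundaries); wall/inlet/outlet handling lives in the
    solver and boundaries modules.
    """
    from .errors import DivergenceError

    f = state.f
    if not np.all(np.isfinite(f)):
        raise DivergenceError(state.step)
    rho, u = macroscopics(f)
    umax = np.sqrt(np.max(np.sum(u * u, axis=-1)))
    if umax >= mach_guard * CS:
        raise StabilityError(
            f"low-Mach guard: max |u| = {umax:.4g} >= {mach_guard:.3g}*Cs at step {state.step}"
        )
    feq = equilibrium(rho, u)
    fpost = f - (1.0 / spec.tau) * (f - feq)
    fnew = np.empty_like(fpost)
    for i in range(Q):
        fnew[..., i] = np.roll(fpost[..., i], shift=tuple(C[i]), axis=(0, 1, 2))
    return FluidState(f=fnew, step=state.step + 1)
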