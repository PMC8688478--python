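"""Analytical Womersley solutions for pulsatile flow in rigid and elastic tubes.

These closed-form solutions are the verification oracle for the solver: the
elastic-tube fields (pressure, axial and radial velocity) for a single
pressure-gradient harmonic, and the classical rigid-tube profile.

Model
-----
Long-wave, linearized, axisymmetric flow of an incompressible Newtonian fluid
in a thin-walled, untethered (free) elastic tube.  All oscillatory quantities
carry the factor exp(i omega (t - (z - z0)/c)) with complex wave speed c; the
physical fields are the real parts.  The axial velocity is

    w(r,z,t) = k_s (r^2 - R^2)/(4 mu)
             + Re{ (H/(rho c)) [1 - M J0(Lambda r/R)/J0(Lambda)] e^{i omega (t-(z-z0)/c)} }

with Lambda = i^{3/2} alpha, alpha = R sqrt(omega rho / mu).  The elasticity
factor M and wave speed c follow from the thin-shell frequency equation (see
:func:`elastic_factor`); in the inviscid, massless-wall limit M -> 1 - sigma/2
and c -> c0 = sqrt(Y h / (2 rho R)), the Moens-Korteweg speed.

The oscillatory pressure amplitude H is tied to the configured oscillatory
pressure-gradient amplitude k_p through H = i c k_p / omega, which makes the
axial gradient of the oscillatory pressure equal k_p e^{i omega (t-(z-z0)/c)}.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import jv

from .errors import ConfigError, OutOfDomainError, SingularParameterError

__all__ = [
    "WomersleyCase",
    "womersley_number",
    "moens_korteweg_speed",
    "elastic_factor",
    "frequency_equation_residuals",
    "elastic_solution",
    "oscillatory_axial_amplitude",
    "rigid_solution",
]


def womersley_number(R: float, omega: float, rho: float, mu: float) -> float:
    """alpha = R sqrt(omega rho / mu)."""
    if min(R, omega, rho, mu) <= 0:
        raise ConfigError("womersley_number requires positive R, omega, rho, mu")
    return R * np.sqrt(omega * rho / mu)


def moens_korteweg_speed(Y: float, h: float, rho: float, R: float) -> float:
    """Long-wave reference wave speed c0 = sqrt(Y h / (2 rho R))."""
    if min(Y, h, rho, R) <= 0:
        raise ConfigError("moens_korteweg_speed requires positive Y, h, rho, R")
    return np.sqrt(Y * h / (2.0 * rho * R))


def _j0(x):
    v = jv(0, x)
    if np.any(np.abs(v) < 1e-12):
        raise SingularParameterError(f"J0 evaluated at (near-)zero: argument {x}")
    return v


def _f10(Lambda: complex) -> complex:
    """Womersley's function F10 = 2 J1(Lambda) / (Lambda J0(Lambda))."""
    return 2.0 * jv(1, Lambda) / (Lambda * _j0(Lambda))


def frequency_equation_residuals(M, lam, g, k, sigma):
    """Residuals of the two nondimensional thin-shell boundary equations.

    Axial wall momentum and radial wall equilibrium, with
    lam = Y h / ((1 - sigma^2) rho c^2 R), k = rho_wall h / (rho R) and
    g = F10(alpha):

        r_ax  = 2 k (1 - M) + M g - 2 lam (1 - M) + lam sigma (1 - M g)
        r_rad = 1 - lam (1 - M g)/2 + lam sigma (1 - M)

    Both vanish at a solution of the frequency equation.
    """
    r_ax = 2 * k * (1 - M) + M * g - 2 * lam * (1 - M) + lam * sigma * (1 - M * g)
    r_rad = 1 - lam * (1 - M * g) / 2 + lam * sigma * (1 - M)
    return r_ax, r_rad


def _solve_frequency_equation(g: complex, k: float, sigma: float) -> tuple[complex, complex]:
    """Solve the thin-shell frequency equation for (M, lam).

    Eliminating lam between the two residual equations gives a quadratic in M:

        a2 M^2 + a1 M + a0 = 0
        a2 = -g^2 + 2 g k + 2 g sigma - 4 k sigma
        a1 = -2 g k - 4 g sigma + g + 8 k sigma - 2 k + 4
        a0 = -4 k sigma + 2 k + 2 sigma - 4

    Of the two roots, the physical (Young-mode) branch is the one that tends
    to the inviscid massless-wall limit M = 1 - sigma/2 for alpha -> inf,
    k -> 0; it is selected as the root closest to that limit.
    """
    a2 = -(g**2) + 2 * g * k + 2 * g * sigma - 4 * k * sigma
    a1 = -2 * g * k - 4 * g * sigma + g + 8 * k * sigma - 2 * k + 4
    a0 = -4 * k * sigma + 2 * k + 2 * sigma - 4
    roots = np.roots([a2, a1, a0])
    M = roots[np.argmin(np.abs(roots - (1.0 - sigma / 2.0)))]
    lam = 2.0 / ((1.0 - M * g) - 2.0 * sigma * (1.0 - M))
    return complex(M), complex(lam)


@dataclass
class WomersleyCase:
    """Parameters of a single-harmonic pulsatile tube-flow case.

    Fluid: density ``rho`` (kg/m^3), dynamic viscosity ``mu`` (Pa s).
    Geometry: radius ``R`` (m), entry coordinate ``z0`` (m).
    Drive: static background pressure ``p0`` (Pa), static gradient ``k_s``
    (Pa/m), oscillatory gradient amplitude ``k_p`` (Pa/m), angular frequency
    ``omega`` (rad/s).
    Wall (optional, needed for the elastic solution): Young's modulus ``Y``
    (Pa), thickness ``h`` (m), Poisson ratio ``sigma``, density ``rho_wall``
    (kg/m^3).

    Derived complex quantities (computed on construction when wall parameters
    are present): elasticity factor ``M``, wave speed ``c`` (m/s), oscillatory
    pressure amplitude ``H = i c k_p / omega`` (Pa).
    """

    R: float
    omega: float
    rho: float = 1000.0
    mu: float = 4.0e-3
    k_p: float = 0.0
    k_s: float = 0.0
    p0: float = 0.0
    z0: float = 0.0
    Y: float | None = None
    h: float | None = None
    sigma: float = 0.5
    rho_wall: float = 1000.0

    alpha: float = field(init=False)
    Lambda: complex = field(init=False)
    M: complex | None = field(init=False, default=None)
    c: complex | None = field(init=False, default=None)
    H: complex | None = field(init=False, default=None)

    def __post_init__(self):
        self.alpha = womersley_number(self.R, self.omega, self.rho, self.mu)
        self.Lambda = 1j**1.5 * self.alpha
        if self.Y is not None:
            if self.h is None or self.h <= 0 or self.Y <= 0:
                raise ConfigError("elastic wall requires positive Y and h")
            if not abs(self.sigma) < 1.0:
                raise ConfigError(f"Poisson ratio must satisfy |sigma| < 1, got {self.sigma}")
            self.M, self.c = elastic_factor(self)
            self.H = 1j * self.c * self.k_p / self.omega

    @property
    def period(self) -> float:
        return 2.0 * np.pi / self.omega

    @property
    def c0(self) -> float:
        """Moens-Korteweg long-wave reference speed."""
        if self.Y is None:
            raise ConfigError("c0 requires wall parameters (Y, h)")
        return moens_korteweg_speed(self.Y, self.h, self.rho, self.R)

    @property
    def wall_mass_ratio(self) -> float:
        """k = rho_wall h / (rho R), the nondimensional wall inertia."""
        if self.h is None:
            raise ConfigError("wall_mass_ratio requires wall thickness h")
        return self.rho_wall * self.h / (self.rho * self.R)


def elastic_factor(case: WomersleyCase) -> tuple[complex, complex]:
    """Elasticity factor M and complex wave speed c of the free elastic tube.

    Solves the thin-walled-shell frequency equation (quadratic in M after
    eliminating the stiffness parameter) on the Young-mode branch, then
    recovers c from lam = Y h / ((1 - sigma^2) rho c^2 R).  The branch reduces
    to the Moens-Korteweg speed c0 as alpha -> inf (massless wall).
    """
    if case.Y is None or case.h is None:
        raise ConfigError("elastic_factor requires wall parameters Y and h")
    g = _f10(case.Lambda)
    k = case.wall_mass_ratio
    M, lam = _solve_frequency_equation(g, k, case.sigma)
    B = case.Y * case.h / (1.0 - case.sigma**2)
    c = np.sqrt(B / (case.rho * case.R * lam))
    if c.real < 0:
        c = -c
    return M, c


def _phase(case: WomersleyCase, z, t):
    return np.exp(1j * case.omega * (np.asarray(t) - (np.asarray(z) - case.z0) / case.c))


def _check_radius(case, r):
    r = np.asarray(r, dtype=float)
    if np.any(r > case.R * (1 + 1e-12)):
        raise OutOfDomainError(f"radial position beyond tube radius R={case.R}")
    return r


def oscillatory_axial_amplitude(case: WomersleyCase, r) -> np.ndarray:
    """Complex amplitude of the oscillatory axial velocity at radius r.

    (H/(rho c)) [1 - M J0(Lambda r/R) / J0(Lambda)]; the physical field is
    Re{amplitude * e^{i omega (t-(z-z0)/c)}}.
    """
    if case.M is None:
        raise ConfigError("oscillatory amplitude requires an elastic case (wall parameters)")
    r = _check_radius(case, r)
    j0L = _j0(case.Lambda)
    return (case.H / (case.rho * case.c)) * (1.0 - case.M * jv(0, case.Lambda * r / case.R) / j0L)


def elastic_solution(case: WomersleyCase, r, z, t):
    """Pressure, axial and radial velocity of the elastic-tube solution.

    Returns (p, w_axial, u_radial), real fields in SI units, including the
    steady Poiseuille component k_s (r^2 - R^2)/(4 mu).
    """
    if case.M is None:
        raise ConfigError("elastic_solution requires wall parameters (Y, h)")
    r = _check_radius(case, r)
    z = np.asarray(z, dtype=float)
    t = np.asarray(t, dtype=float)
    E = _phase(case, z, t)
    j0L = _j0(case.Lambda)

    p = (case.H * E).real + case.p0 + case.k_s * (z - case.z0)
    w_st = case.k_s / (4.0 * case.mu) * (r**2 - case.R**2)
    w_osc = (case.H / (case.rho * case.c)) * (1.0 - case.M * jv(0, case.Lambda * r / case.R) / j0L)
    w = w_st + (w_osc * E).real
    u_amp = (
        case.H * 1j * case.omega * case.R / (2.0 * case.rho * case.c**2)
        * (r / case.R - case.M * 2.0 * jv(1, case.Lambda * r / case.R) / (case.Lambda * j0L))
    )
    u = (u_amp * E).real
    return p, w, u


def rigid_solution(case: WomersleyCase, r, z, t):
    """Axial velocity of the rigid-tube Womersley solution.

    Steady Poiseuille part plus the classical oscillatory profile for a
    uniform oscillatory pressure gradient of amplitude k_p:

        w_osc = Re{ (i k_p/(rho omega)) [1 - J0(Lambda r/R)/J0(Lambda)] e^{i omega t'} }

    where t' carries the same phase convention as the elastic case (the wave
    factor is used when wall parameters are present so rigid and elastic runs
    share one drive; for a wall-less case the gradient is spatially uniform).
    """
    r = _check_radius(case, r)
    z = np.asarray(z, dtype=float)
    t = np.asarray(t, dtype=float)
    if case.c is not None:
        E = _phase(case, z, t)
    else:
        E = np.exp(1j * case.omega * t) * np.ones_like(z)
    j0L = _j0(case.Lambda)
    w_st = case.k_s / (4.0 * case.mu) * (r**2 - case.R**2)
    amp = (1j * case.k_p / (case.rho * case.omega)) * (1.0 - jv(0, case.Lambda * r / case.R) / j0L)
    return w_st + (amp * E).real


def rigid_pressure(case: WomersleyCase, z, t):
    """Pressure of the rigid-tube oscillatory solution at axial position z.

    p = p0 + k_s (z - z0) + Re{(k_p/(i omega/c ...))}; for the uniform-gradient
    convention the oscillatory pressure is integrated directly:
    p_osc = Re{ k_p (z - z0) e^{i omega t} } for a wall-less case, or the
    elastic-case pressure wave when wall parameters are present (shared drive).
    """
    z = np.asarray(z, dtype=float)
    t = np.asarray(t, dtype=float)
    if case.H is not None:
        return (case.H * _phase(case, z, t)).real + case.p0 + case.k_s * (z - case.z0)
    return case.p0 + case.k_s * (z - case.z0) + (case.k_p * (z - case.z0) * np.exp(1j * case.omega * t)).real
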