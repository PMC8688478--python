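"""Boundary operators and the elastic-wall slip model.

The elastic-wall condition assigns the wall node a slip velocity that mimics
a vessel wall dilating a distance Delta_r beyond the last fluid node.  With
the boundary velocity ratio F = U_R / U_f (the ratio of the analytic
oscillatory axial velocity at the dilated wall location to that one
Delta_r inside), linear interpolation between the fluid node and the dilated
wall location puts, at the wall node (one lattice spacing out),

    U_w = ((F dx + Delta_r - dx) / Delta_r) U_f .

F itself follows from the elastic-tube Womersley solution,

    F = (1 - M) / (1 - M J0(Lambda (1 - Delta_r/R)) / J0(Lambda)) ,

a complex ratio reduced to a scalar (modulus by default).  F = 0 is the
rigid limit, F = 1 the plug (free-slip-like) limit.

The wall-node populations are then assembled Guo-extrapolation style:
equilibrium at (rho_f, U_w) plus the fluid neighbour's non-equilibrium part
(the Delta = 1 near-wall branch); see :mod:`vesselflow._kernels`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import jv

from .errors import ConfigError, SingularParameterError
from .womersley import WomersleyCase, _j0

logger = logging.getLogger(__name__)

__all__ = [
    "ElasticWallModel",
    "gzs_wall_velocity",
    "elastic_wall_velocity",
    "slip_coefficient",
    "radial_extension",
    "boundary_velocity_ratio",
    "f_ratio_map",
]


def gzs_wall_velocity(U_boundary, U_f, Delta: float):
    """Guo-extrapolation wall-node velocity, near-wall branch.

    U_w = (U_boundary + (Delta - 1) U_f) / Delta, valid for
    0.75 <= Delta <= 1 (the far branch Delta < 0.75 is out of scope).
    """
    if not 0.75 <= Delta <= 1.0:
        raise ConfigError(
            f"Delta={Delta} outside the near-wall branch [0.75, 1] of the "
            "extrapolation scheme (far branch not implemented)"
        )
    U_boundary = np.asarray(U_boundary, dtype=float)
    U_f = np.asarray(U_f, dtype=float)
    return (U_boundary + (Delta - 1.0) * U_f) / Delta


def slip_coefficient(F: float, dx: float, dr: float) -> float:
    """Scalar coefficient of the slip formula, U_w = coef * U_f.

    coef = (F dx + dr - dx) / dr.  dr below dx is floored to dx (the formula
    degenerates there; the floor yields its natural boundary value
    U_w = F U_f) with a logged warning.
    """
    if dx <= 0:
        raise ConfigError(f"dx must be positive, got {dx}")
    if not 0.0 <= F <= 1.0:
        raise ConfigError(f"boundary velocity ratio F={F} outside [0, 1]")
    if dr < dx:
        logger.warning("radial extension dr=%g < dx=%g; floored to dx", dr, dx)
        dr = dx
    return (F * dx + dr - dx) / dr


def elastic_wall_velocity(U_f, F: float, dx: float, dr: float):
    """Wall-node slip velocity U_w = ((F dx + dr - dx)/dr) U_f (collinear with U_f)."""
    return slip_coefficient(F, dx, dr) * np.asarray(U_f, dtype=float)


def radial_extension(p, wall: "ElasticWallModel", R: float, dx: float | None = None):
    """Radial extension dr (m) from transmural pressure.

    Raw value from the pressure-dilation relation
    dr = (1 - sigma^2) R^2 (p - P0) / (Y h); when ``dx`` is given the value
    is clamped to [dx, 0.10 R], the admissible range of the slip formula.
    """
    if wall.young_modulus is None or wall.thickness is None:
        raise ConfigError("radial_extension requires wall Y and h")
    if wall.young_modulus <= 0 or wall.thickness <= 0:
        raise ConfigError("wall Y and h must be positive")
    if not abs(wall.poisson) < 1.0:
        raise ConfigError(f"|poisson ratio| must be < 1, got {wall.poisson}")
    dr = (1.0 - wall.poisson**2) * R**2 * (np.asarray(p, dtype=float) - wall.p0) / (
        wall.young_modulus * wall.thickness
    )
    if dx is not None:
        dr = np.clip(dr, dx, 0.10 * R)
    return dr


@dataclass
class ElasticWallModel:
    """Wall material state for the elastic boundary condition.

    Parameters
    ----------
    F : float
        Boundary velocity ratio in [0, 1] (0 = rigid limit, 1 = plug limit).
    dr : float or None
        Static radial extension in metres.  ``None`` uses the floor value
        dx, for which the slip velocity is simply F * U_f.
    mode : {"static", "dynamic"}
        ``static`` precomputes one slip coefficient; ``dynamic`` re-evaluates
        dr per wall site each step from the neighbour pressure through the
        pressure-dilation relation (requires Y, h, R).
    young_modulus, thickness, poisson, p0 : wall material parameters (SI),
        needed for dynamic mode and for the dilation relation.
    R : float or None
        Vessel radius (m) used by the dilation relation and its clamp.
    """

    F: float
    dr: float | None = None
    mode: str = "static"
    young_modulus: float | None = None
    thickness: float | None = None
    poisson: float = 0.5
    p0: float = 0.0
    R: float | None = None

    def __post_init__(self):
        if not 0.0 <= self.F <= 1.0:
            raise ConfigError(f"boundary velocity ratio F={self.F} outside [0, 1]")
        if self.mode not in ("static", "dynamic"):
            raise ConfigError(f"unknown dr mode {self.mode!r}")
        if self.mode == "dynamic" and (
            self.young_modulus is None or self.thickness is None or self.R is None
        ):
            raise ConfigError("dynamic dr mode requires young_modulus, thickness and R")

    def static_coefficient(self, dx: float) -> float:
        """Slip coefficient for static mode (dr defaults to the dx floor)."""
        dr = self.dr if self.dr is not None else dx
        return slip_coefficient(self.F, dx, dr)

    def dynamic_coefficients(self, p, dx: float):
        """Per-site slip coefficients from neighbour pressures (dynamic mode)."""
        dr = radial_extension(p, self, self.R, dx=dx)
        return (self.F * dx + dr - dx) / dr


def boundary_velocity_ratio(M: complex, Lambda: complex, dr_over_R: float, reduction: str = "modulus"):
    """Boundary velocity ratio F from the elastic-tube Womersley solution.

    F = (1 - M) / (1 - M J0(Lambda (1 - dr/R)) / J0(Lambda)) — the ratio of
    the oscillatory axial velocity at the dilated wall location to that at
    the fluid node dr inside it.  ``reduction`` selects the scalar form of
    the complex ratio: "modulus" (default, phase-robust), "real", or
    "complex" to return the full ratio.
    """
    if not 0.0 <= dr_over_R < 1.0:
        raise ConfigError(f"dr_over_R={dr_over_R} outside [0, 1)")
    if dr_over_R == 0.0:
        # numerator and denominator coincide identically
        return 1.0 if reduction != "complex" else 1.0 + 0.0j
    j0L = _j0(Lambda)
    denom = 1.0 - M * jv(0, Lambda * (1.0 - dr_over_R)) / j0L
    if abs(denom) < 1e-14:
        raise SingularParameterError(
            f"boundary velocity ratio singular at dr/R={dr_over_R} (denominator ~ 0)"
        )
    Fc = (1.0 - M) / denom
    if reduction == "modulus":
        return abs(Fc)
    if reduction == "real":
        return Fc.real
    if reduction == "complex":
        return Fc
    raise ConfigError(f"unknown reduction {reduction!r}")


def f_ratio_map(
    R: float,
    alpha_grid,
    dE_grid,
    Y: float = 20e3,
    h: float | None = None,
    sigma: float = 0.5,
    rho_wall: float = 1000.0,
    rho: float = 1000.0,
    mu: float = 4.0e-3,
    reduction: str = "modulus",
    alpha_floor: float = 1e-2,
) -> pd.DataFrame:
    """Map of the boundary velocity ratio over (Womersley number, dilation).

    Rows are fractional dilations Delta_E = dr/R, columns Womersley numbers.
    Each entry evaluates :func:`boundary_velocity_ratio` with (M, Lambda)
    from the frequency equation at that alpha (alpha below ``alpha_floor``
    is evaluated at the floor: the quasi-steady limit; the dE = 0 row is 1
    identically).  Deterministic for fixed grids.
    """
    alpha_grid = np.asarray(alpha_grid, dtype=float)
    dE_grid = np.asarray(dE_grid, dtype=float)
    if np.any(~np.isfinite(alpha_grid)) or np.any(~np.isfinite(dE_grid)):
        raise ConfigError("grids must be finite")
    if h is None:
        h = 0.1 * R
    out = np.empty((dE_grid.size, alpha_grid.size))
    for j, alpha in enumerate(alpha_grid):
        a_eval = max(float(alpha), alpha_floor)
        # recover omega giving this Womersley number for the material case
        omega = a_eval**2 * mu / (rho * R**2)
        case = WomersleyCase(
            R=R, omega=omega, rho=rho, mu=mu, Y=Y, h=h, sigma=sigma, rho_wall=rho_wall
        )
        for i, dE in enumerate(dE_grid):
            try:
                out[i, j] = boundary_velocity_ratio(case.M, case.Lambda, float(dE), reduction)
            except SingularParameterError:
                out[i, j] = np.nan
    df = pd.DataFrame(out, index=pd.Index(dE_grid, name="dE"), columns=pd.Index(alpha_grid, name="alpha"))
    return df
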