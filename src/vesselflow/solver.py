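"""Time-stepping driver coupling the D3Q19 kernels to a voxel domain.

A :class:`Simulation` owns the flat population arrays over the *valid* sites
of a :class:`~vesselflow.geometry.VoxelDomain` (fluid, inlet, outlet, plus
wall sites in elastic mode), the pull-streaming neighbour table, and the
boundary operators:

* rigid walls: halfway bounceback (wall sites carry no populations);
* elastic walls: wall sites are reconstructed each step from their
  designated fluid neighbour with the slip velocity U_w = coef * U_f;
* inlet/outlet planes: non-equilibrium-extrapolation imposition of either a
  target pressure (density) or a target velocity profile.

Everything is deterministic: identical configuration yields bit-identical
trajectories.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np

from . import _kernels
from .boundaries import ElasticWallModel
from .errors import ConfigError, DivergenceError, StabilityError
from .geometry import FLUID, INLET, OUTLET, WALL, VoxelDomain
from .lattice import C, CS, OPPOSITE, W, LatticeSpec

_CMAT = C.astype(np.float64)
_CXF = C[:, 0].astype(np.float64)
_CYF = C[:, 1].astype(np.float64)
_CZF = C[:, 2].astype(np.float64)


@dataclass
class PressureBC:
    """Fixed (possibly time-dependent) pressure on an inlet/outlet plane.

    ``p_of_t`` maps physical time (s) to pressure (Pa), or is a constant.
    """

    p_of_t: Callable[[float], float] | float

    def pressure(self, t: float) -> float:
        if callable(self.p_of_t):
            return float(self.p_of_t(t))
        return float(self.p_of_t)


@dataclass
class VelocityBC:
    """Prescribed axial velocity on an inlet plane.

    ``u_of_t`` maps physical time (s) to the peak axial speed (m/s);
    ``weights`` scales it per inlet site (default: parabolic profile,
    1 - (r/R)^2 normalized to peak 1, computed from the inlet-plane
    geometry).
    """

    u_of_t: Callable[[float], float] | float
    weights: np.ndarray | str = "parabolic"

    def speed(self, t: float) -> float:
        if callable(self.u_of_t):
            return float(self.u_of_t(t))
        return float(self.u_of_t)


def parabolic_weights(points_inplane: np.ndarray) -> np.ndarray:
    """Poiseuille-like inlet weighting 1 - (r/R)^2, peak-normalized.

    ``points_inplane``: (n, 2) lattice coordinates of the inlet sites in the
    plane.  The centroid estimates the axis; the largest site radius plus
    half a lattice spacing estimates R.
    """
    ctr = points_inplane.mean(axis=0)
    r = np.linalg.norm(points_inplane - ctr, axis=1)
    R = r.max() + 0.5 if r.max() > 0 else 1.0
    w = 1.0 - (r / R) ** 2
    return w / w.max()


class Simulation:
    """D3Q19 BGK simulation on a classified voxel domain.

    Parameters
    ----------
    domain : VoxelDomain
    spec : LatticeSpec
    wall : ElasticWallModel or None
        ``None`` selects rigid (halfway-bounceback) walls.
    inlet, outlet : PressureBC, VelocityBC or None
        Boundary drive at the axis-extreme planes.
    p_ref : float
        Physical pressure (Pa) mapped to the reference lattice density 1.
    mach_guard : float
        Abort threshold as a fraction of the lattice speed of sound.
    """

    def __init__(
        self,
        domain: VoxelDomain,
        spec: LatticeSpec,
        wall: ElasticWallModel | None = None,
        inlet: PressureBC | VelocityBC | None = None,
        outlet: PressureBC | VelocityBC | None = None,
        p_ref: float = 0.0,
        mach_guard: float = 0.1,
    ):
        self.domain = domain
        self.spec = spec
        self.wall = wall
        self.inlet = inlet
        self.outlet = outlet
        self.p_ref = float(p_ref)
        self.mach_guard = float(mach_guard)
        self.step_index = 0
        self.elastic = wall is not None
        self.fallback_count = 0

        flags = domain.flags
        valid = domain.fluid_mask
        if self.elastic:
            valid = valid | (flags == WALL)
        self._valid_mask = valid

        self.site_index = np.full(flags.shape, -1, dtype=np.int64)
        coords = np.argwhere(valid)
        self.site_coords = coords
        self.n_sites = len(coords)
        self.site_index[coords[:, 0], coords[:, 1], coords[:, 2]] = np.arange(self.n_sites)

        site_flags = flags[coords[:, 0], coords[:, 1], coords[:, 2]]
        self.stream_ids = np.flatnonzero(
            (site_flags == FLUID) | (site_flags == INLET) | (site_flags == OUTLET)
        ).astype(np.int64)

        # pull-streaming sources: nbr[k, i] = valid id at x_k - c_i, else -1
        shape = np.array(flags.shape)
        self.nbr = np.full((self.n_sites, 19), -1, dtype=np.int64)
        for i in range(19):
            src = coords - C[i]
            ok = np.all((src >= 0) & (src < shape), axis=1)
            idx = src[ok]
            self.nbr[ok, i] = self.site_index[idx[:, 0], idx[:, 1], idx[:, 2]]

        # wall reconstruction tables (elastic mode)
        if self.elastic:
            ws = domain.wall_sites
            self.wall_ids = self.site_index[ws[:, 0], ws[:, 1], ws[:, 2]]
            nbr_pos = ws + C[domain.wall_neighbor_dir]
            self.wall_nbr_ids = self.site_index[nbr_pos[:, 0], nbr_pos[:, 1], nbr_pos[:, 2]]
            if np.any(self.wall_nbr_ids < 0):
                raise ConfigError("wall site with invalid designated neighbour")
            coef = wall.static_coefficient(spec.dx)
            self.wall_coef = np.full(len(ws), coef, dtype=np.float64)
        else:
            self.wall_ids = np.empty(0, dtype=np.int64)
            self.wall_nbr_ids = np.empty(0, dtype=np.int64)
            self.wall_coef = np.empty(0, dtype=np.float64)

        self._setup_plane("inlet", INLET, inlet)
        self._setup_plane("outlet", OUTLET, outlet)

        # post-collision populations; equilibrium rest start (its post-collision
        # image is itself)
        self.f = np.tile(W, (self.n_sites, 1))
        self.f_next = np.empty_like(self.f)
        self.rho = np.ones(self.n_sites)
        self.ux = np.zeros(self.n_sites)
        self.uy = np.zeros(self.n_sites)
        self.uz = np.zeros(self.n_sites)
        self.last_umax = 0.0

    # ------------------------------------------------------------------
    def _setup_plane(self, name, label, bc):
        flags = self.domain.flags
        pos = np.argwhere(flags == label)
        ids = (
            self.site_index[pos[:, 0], pos[:, 1], pos[:, 2]]
            if len(pos)
            else np.empty(0, dtype=np.int64)
        )
        axis = self.domain.axis
        step = 1 if label == INLET else -1
        nbr_ids = np.empty(0, dtype=np.int64)
        weights = None
        if len(pos):
            inner = pos.copy()
            inner[:, axis] += step
            nbr_ids = self.site_index[inner[:, 0], inner[:, 1], inner[:, 2]]
            if np.any(nbr_ids < 0):
                raise ConfigError(f"{name} plane has no interior fluid neighbour")
            if isinstance(bc, VelocityBC):
                lateral = [a for a in range(3) if a != axis]
                pts = pos[:, lateral].astype(float) + 0.5
                if isinstance(bc.weights, str):
                    if bc.weights != "parabolic":
                        raise ConfigError(f"unknown weight spec {bc.weights!r}")
                    weights = parabolic_weights(pts)
                else:
                    weights = np.asarray(bc.weights, dtype=float)
                    if weights.shape != (len(pos),):
                        raise ConfigError(
                            f"{name} weights shape {weights.shape} != ({len(pos)},)"
                        )
        setattr(self, f"{name}_ids", ids)
        setattr(self, f"{name}_nbr_ids", nbr_ids)
        setattr(self, f"{name}_weights", weights)

    # ------------------------------------------------------------------
    @property
    def time(self) -> float:
        """Physical time of the current state (s)."""
        return self.step_index * self.spec.dt

    def total_mass(self) -> float:
        """Total lattice mass over population-carrying (non-wall) sites."""
        return float(self.f[self.stream_ids].sum())

    def step(self, n: int = 1) -> None:
        """Advance ``n`` time steps."""
        spec = self.spec
        omega = 1.0 / spec.tau
        guard2 = (self.mach_guard * CS) ** 2
        for _ in range(n):
            t_next = (self.step_index + 1) * spec.dt
            try:
                umax2, mass = _kernels.stream_collide(
                    self.f, self.f_next, self.nbr, self.stream_ids, OPPOSITE,
                    _CXF, _CYF, _CZF, W, omega,
                    self.rho, self.ux, self.uy, self.uz,
                )
            except (ZeroDivisionError, FloatingPointError) as exc:
                raise DivergenceError(self.step_index + 1) from exc
            if not np.isfinite(mass):
                raise DivergenceError(self.step_index + 1)
            if umax2 >= guard2:
                raise StabilityError(
                    f"low-Mach guard: max |u| = {np.sqrt(umax2):.4g} lattice units "
                    f">= {self.mach_guard:.3g}*Cs at step {self.step_index + 1}"
                )
            self.last_umax = float(np.sqrt(umax2))
            if self.elastic and len(self.wall_ids):
                if self.wall.mode == "dynamic":
                    p_nbr = spec.density_to_pressure(self.rho[self.wall_nbr_ids], self.p_ref)
                    self.wall_coef = self.wall.dynamic_coefficients(p_nbr, spec.dx)
                _kernels.wall_construct(
                    self.f, self.f_next, self.nbr, self.wall_ids, self.wall_nbr_ids,
                    OPPOSITE, _CXF, _CYF, _CZF, W, spec.tau, self.wall_coef,
                )
            for name, bc in (("inlet", self.inlet), ("outlet", self.outlet)):
                ids = getattr(self, f"{name}_ids")
                if bc is None or not len(ids):
                    continue
                nbr_ids = getattr(self, f"{name}_nbr_ids")
                if isinstance(bc, PressureBC):
                    rho_t = float(spec.pressure_to_density(bc.pressure(t_next), self.p_ref))
                    _kernels.impose_pressure(
                        self.f, self.f_next, self.nbr, ids, nbr_ids, OPPOSITE,
                        _CXF, _CYF, _CZF, W, spec.tau, rho_t,
                    )
                elif isinstance(bc, VelocityBC):
                    u_lat = bc.speed(t_next) / spec.velocity_scale
                    prof = u_lat * getattr(self, f"{name}_weights")
                    zeros = np.zeros_like(prof)
                    comps = [zeros, zeros, zeros]
                    comps[self.domain.axis] = prof
                    _kernels.impose_velocity(
                        self.f, self.f_next, self.nbr, ids, nbr_ids, OPPOSITE,
                        _CXF, _CYF, _CZF, W, spec.tau,
                        np.ascontiguousarray(comps[0]),
                        np.ascontiguousarray(comps[1]),
                        np.ascontiguousarray(comps[2]),
                    )
                else:
                    raise ConfigError(f"unsupported boundary object {bc!r} at {name}")
                # refresh stored moments at imposed sites (the bulk kernel
                # recorded their pre-imposition state)
                fs = self.f_next[ids]
                r = fs.sum(axis=1)
                mom = fs @ _CMAT
                self.rho[ids] = r
                self.ux[ids] = mom[:, 0] / r
                self.uy[ids] = mom[:, 1] / r
                self.uz[ids] = mom[:, 2] / r
            self.f, self.f_next = self.f_next, self.f
            self.step_index += 1

    # ------------------------------------------------------------------
    def velocity_field(self, physical: bool = True) -> np.ndarray:
        """(nx, ny, nz, 3) velocity field; NaN outside population sites."""
        out = np.full(self.domain.shape + (3,), np.nan)
        c = self.site_coords[self.stream_ids]
        scale = self.spec.velocity_scale if physical else 1.0
        out[c[:, 0], c[:, 1], c[:, 2], 0] = self.ux[self.stream_ids] * scale
        out[c[:, 0], c[:, 1], c[:, 2], 1] = self.uy[self.stream_ids] * scale
        out[c[:, 0], c[:, 1], c[:, 2], 2] = self.uz[self.stream_ids] * scale
        return out

    def density_field(self) -> np.ndarray:
        """(nx, ny, nz) lattice density; NaN outside population sites."""
        out = np.full(self.domain.shape, np.nan)
        c = self.site_coords[self.stream_ids]
        out[c[:, 0], c[:, 1], c[:, 2]] = self.rho[self.stream_ids]
        return out

    def pressure_field(self) -> np.ndarray:
        """(nx, ny, nz) physical pressure (Pa); NaN outside population sites."""
        rho = self.density_field()
        return self.spec.density_to_pressure(rho, self.p_ref)
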