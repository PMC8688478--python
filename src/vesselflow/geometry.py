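"""Voxelized flow domains: classification, wall-link topology, wall normals.

Sites live on a Cartesian grid with cell-centered coordinates
x = (i + 0.5) dx (0-based indices).  Each site carries one label:

===========  =====
label        value
===========  =====
SOLID        0
FLUID        1
WALL         2
INLET        3
OUTLET       4
===========  =====

Wall sites form exactly one shell: the non-fluid sites with at least one
fluid neighbour along a lattice direction.  Wall normals are estimated
locally from the lattice-weighted sum of fluid-link directions — no global
surface knowledge is used, mirroring the locality of the boundary scheme.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import h5py
from scipy import ndimage

from .errors import GeometryError, ParseError, TopologyError, UnboundedDomainError
from .lattice import C, W, LatticeSpec

SOLID, FLUID, WALL, INLET, OUTLET = 0, 1, 2, 3, 4
_LABELS = {SOLID, FLUID, WALL, INLET, OUTLET}

_DOMAIN_FORMAT_VERSION = 1


@dataclass
class VoxelDomain:
    """A classified voxel domain plus wall-link topology.

    Attributes
    ----------
    flags : (nx, ny, nz) uint8
        Per-site label.
    wall_sites : (nw, 3) int
        Grid indices of wall sites.
    wall_links : (nw, 19) bool
        For each wall site, which lattice directions point at fluid
        (including inlet/outlet) sites.
    normals : (nw, 3) float
        Unit outward normal estimate per wall site (zero where the weighted
        link sum cancels exactly).
    wall_neighbor_dir : (nw,) int
        Index of the designated fluid-neighbour direction: the fluid link
        best aligned with the inward normal.
    axis : int
        Flow axis (0, 1 or 2).
    dx : float
        Lattice spacing in metres.
    origin : (3,) float
        Physical coordinate of the grid corner (cell centers at
        origin + (i + 0.5) dx).
    """

    flags: np.ndarray
    wall_sites: np.ndarray
    wall_links: np.ndarray
    normals: np.ndarray
    wall_neighbor_dir: np.ndarray
    axis: int = 2
    dx: float = 1.0
    origin: np.ndarray = field(default_factory=lambda: np.zeros(3))

    @property
    def shape(self):
        return self.flags.shape

    @property
    def fluid_mask(self):
        """Sites carrying fluid populations (fluid, inlet and outlet)."""
        return (self.flags == FLUID) | (self.flags == INLET) | (self.flags == OUTLET)

    def site_count(self, label):
        return int(np.count_nonzero(self.flags == label))

    def cell_centers_1d(self, axis):
        """Physical cell-center coordinates along one grid axis."""
        n = self.shape[axis]
        return self.origin[axis] + (np.arange(n) + 0.5) * self.dx

    def __eq__(self, other):
        if not isinstance(other, VoxelDomain):
            return NotImplemented
        return (
            np.array_equal(self.flags, other.flags)
            and np.array_equal(self.wall_sites, other.wall_sites)
            and np.array_equal(self.wall_links, other.wall_links)
            and np.array_equal(self.normals, other.normals)
            and np.array_equal(self.wall_neighbor_dir, other.wall_neighbor_dir)
            and self.axis == other.axis
            and self.dx == other.dx
            and np.array_equal(self.origin, other.origin)
        )


def _shift(mask, c):
    """Mask shifted so entry x holds mask[x - c]; out-of-range -> False."""
    out = np.zeros_like(mask)
    src = [slice(None)] * 3
    dst = [slice(None)] * 3
    for a in range(3):
        if c[a] > 0:
            dst[a] = slice(c[a], None)
            src[a] = slice(None, -c[a])
        elif c[a] < 0:
            dst[a] = slice(None, c[a])
            src[a] = slice(-c[a], None)
    out[tuple(dst)] = mask[tuple(src)]
    return out


def classify_and_link(
    mask: np.ndarray,
    spec: LatticeSpec | None = None,
    axis: int = 2,
    open_ends: bool = True,
    dx: float | None = None,
    origin=(0.0, 0.0, 0.0),
) -> VoxelDomain:
    """Classify a binary fluid-occupancy mask into a :class:`VoxelDomain`.

    The fluid must form a single connected component (face connectivity) and
    must not touch the bounding box on the lateral faces; when ``open_ends``
    is true the fluid planes at the two axis extremes are tagged inlet (low
    side) and outlet.  Wall sites are the non-fluid sites adjacent (along any
    of the 18 propagation directions) to fluid, and the outward normal at
    each wall site is

        n = -normalize( sum_{i : fluid link} w_i c_i ).
    """
    mask = np.asarray(mask, dtype=bool)
    if mask.ndim != 3:
        raise GeometryError(f"mask must be 3D, got shape {mask.shape}")
    if not mask.any():
        raise GeometryError("empty fluid mask")
    nlab = ndimage.label(mask)[1]
    if nlab != 1:
        raise TopologyError(f"fluid region has {nlab} connected components (need exactly 1)")
    lateral = [a for a in range(3) if a != axis]
    for a in lateral:
        lo = np.take(mask, 0, axis=a)
        hi = np.take(mask, -1, axis=a)
        if lo.any() or hi.any():
            raise UnboundedDomainError(
                f"fluid touches the lateral bounding box on axis {a}; no wall shell fits"
            )

    flags = np.where(mask, FLUID, SOLID).astype(np.uint8)

    # wall shell: non-fluid sites with >=1 fluid neighbour along c_1..c_18
    has_fluid_link = np.zeros_like(mask)
    for i in range(1, 19):
        has_fluid_link |= _shift(mask, C[i])
    wall = has_fluid_link & ~mask
    flags[wall] = WALL

    if open_ends:
        ax_any = mask.any(axis=tuple(lateral))
        planes = np.flatnonzero(ax_any)
        lo_plane, hi_plane = planes[0], planes[-1]
        sl = [slice(None)] * 3
        sl[axis] = lo_plane
        inlet_plane = flags[tuple(sl)]
        inlet_plane[inlet_plane == FLUID] = INLET
        sl[axis] = hi_plane
        outlet_plane = flags[tuple(sl)]
        outlet_plane[outlet_plane == FLUID] = OUTLET

    wall_sites = np.argwhere(flags == WALL)
    nw = len(wall_sites)
    wall_links = np.zeros((nw, 19), dtype=bool)
    fluidlike = flags != SOLID
    fluidlike &= flags != WALL
    shape = np.array(mask.shape)
    for i in range(1, 19):
        nb = wall_sites + C[i]
        ok = np.all((nb >= 0) & (nb < shape), axis=1)
        idx = nb[ok]
        wall_links[ok, i] = fluidlike[idx[:, 0], idx[:, 1], idx[:, 2]]

    # outward normal from the weighted sum over fluid links
    link_sum = (wall_links[:, :, None] * (W[None, :, None] * C[None, :, :])).sum(axis=1)
    norm = np.linalg.norm(link_sum, axis=1)
    normals = np.zeros_like(link_sum)
    nz = norm > 0
    normals[nz] = -link_sum[nz] / norm[nz, None]

    # designated fluid neighbour: fluid link best aligned with the inward normal
    cn = C.astype(float)
    cn_unit = cn / np.maximum(np.linalg.norm(cn, axis=1), 1.0)[:, None]
    score = -(normals @ cn_unit.T)  # alignment with inward direction
    score[~wall_links] = -np.inf
    wall_neighbor_dir = np.argmax(score, axis=1).astype(np.int64)
    if nw and not wall_links[np.arange(nw), wall_neighbor_dir].all():
        raise TopologyError("wall site without any fluid link (classification bug)")

    return VoxelDomain(
        flags=flags,
        wall_sites=wall_sites.astype(np.int64),
        wall_links=wall_links,
        normals=normals,
        wall_neighbor_dir=wall_neighbor_dir,
        axis=axis,
        dx=float(dx if dx is not None else (spec.dx if spec is not None else 1.0)),
        origin=np.asarray(origin, dtype=float),
    )


def voxelize_cylinder(
    radius_lattice: float,
    length_lattice: int,
    spec: LatticeSpec | None = None,
    axis: int = 2,
) -> VoxelDomain:
    """Voxelize an axis-aligned circular cylinder.

    Fluid sites are cell centers with in-plane distance < R from the axis;
    the axis passes through a cell-center column so the discrete cross
    section has full 4-fold symmetry and a site exactly on the centerline.
    The two axis-extreme fluid planes are tagged inlet (low coordinate) and
    outlet.
    """
    R = float(radius_lattice)
    L = int(length_lattice)
    if R <= 0.5 or L < 1:
        raise GeometryError(
            f"degenerate cylinder: R={R} lattice units, L={L} (no fluid site fits)"
        )
    half = int(np.ceil(R)) + 2
    n_lat = 2 * half + 1
    center = half + 0.5  # cell-center coordinate of the axis column

    coords = np.arange(n_lat) + 0.5
    xg, yg = np.meshgrid(coords - center, coords - center, indexing="ij")
    disk = xg**2 + yg**2 < R**2

    # build along z, then move the flow axis into place; solid caps at both ends
    mask = np.zeros((n_lat, n_lat, L + 2), dtype=bool)
    mask[:, :, 1 : L + 1] = disk[:, :, None]
    mask = np.moveaxis(mask, 2, axis)

    dom = classify_and_link(
        mask,
        spec=spec,
        axis=axis,
        open_ends=True,
        dx=spec.dx if spec is not None else 1.0,
    )
    return dom


def cylinder_axis_center(domain: VoxelDomain):
    """In-plane lattice coordinates of the cylinder axis for domains built by
    :func:`voxelize_cylinder` (cell-center coordinate of the central column)."""
    lateral = [a for a in range(3) if a != domain.axis]
    return np.array([domain.shape[a] / 2.0 for a in lateral])


# --- persistence -----------------------------------------------------------

def write_domain(domain: VoxelDomain, path) -> None:
    """Write a domain to an HDF5 container (documented layout, version 1).

    Datasets: ``flags`` (uint8), ``normals``, ``wall_sites``, ``wall_links``,
    ``wall_neighbor_dir``; attributes: ``dx``, ``axis``, ``origin``,
    ``version``.
    """
    with h5py.File(path, "w") as f:
        f.attrs["version"] = _DOMAIN_FORMAT_VERSION
        f.attrs["dx"] = domain.dx
        f.attrs["axis"] = domain.axis
        f.attrs["origin"] = domain.origin
        f.create_dataset("flags", data=domain.flags, dtype=np.uint8)
        f.create_dataset("wall_sites", data=domain.wall_sites)
        f.create_dataset("wall_links", data=domain.wall_links)
        f.create_dataset("normals", data=domain.normals)
        f.create_dataset("wall_neighbor_dir", data=domain.wall_neighbor_dir)


def read_domain(path) -> VoxelDomain:
    """Read a domain written by :func:`write_domain`; bit-exact round trip."""
    try:
        with h5py.File(path, "r") as f:
            version = int(f.attrs.get("version", -1))
            if version != _DOMAIN_FORMAT_VERSION:
                raise ParseError(
                    f"domain file version {version} not supported (expected {_DOMAIN_FORMAT_VERSION})"
                )
            flags = f["flags"][...]
            bad = set(np.unique(flags)) - _LABELS
            if bad:
                raise ParseError(f"unknown site flag value(s) {sorted(bad)} in {path}")
            dom = VoxelDomain(
                flags=flags,
                wall_sites=f["wall_sites"][...],
                wall_links=f["wall_links"][...].astype(bool),
                normals=f["normals"][...],
                wall_neighbor_dir=f["wall_neighbor_dir"][...],
                axis=int(f.attrs["axis"]),
                dx=float(f.attrs["dx"]),
                origin=np.asarray(f.attrs["origin"], dtype=float),
            )
    except (OSError, KeyError) as exc:
        raise ParseError(f"malformed domain file {path}: {exc}") from exc
    return dom
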