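"""Run configuration, field output and state persistence.

Configurations are flat, typed key-value YAML mappings with an explicit
``schema_version`` key; all physical quantities carry SI units in their key
names.  Field output is legacy-VTK structured points (physical units) and/or
CSV point lists; both are byte-deterministic for fixed inputs.
"""

from __future__ import annotations

import io as _io
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import yaml

from .errors import ConfigError, ParseError
CONFIG_SCHEMA_VERSION = 1

#: key -> (type, required, default)
_RUN_KEYS = {
    "schema_version": (int, True, None),
    "kind": (str, True, None),  # run | verify | theory
    # geometry
    "radius_lattice": (float, False, None),
    "length_lattice": (int, False, None),
    "domain_file": (str, False, None),
    # discretization / fluid
    "dx_m": (float, False, None),
    "tau": (float, False, 0.8),
    "rho_kg_per_m3": (float, False, 1000.0),
    "mu_pa_s": (float, False, 4.0e-3),
    # wall model
    "wall_mode": (str, False, "rigid"),  # rigid | elastic
    "f_ratio": (float, False, 0.0),
    "young_modulus_pa": (float, False, None),
    "wall_thickness_m": (float, False, None),
    "poisson_ratio": (float, False, 0.5),
    "p0_pa": (float, False, 0.0),
    "dr_mode": (str, False, "static"),
    "dr_m": (float, False, None),
    "radius_m": (float, False, None),
    # drive
    "drive": (str, False, "pressure"),  # pressure | waveform
    "k_p_pa_per_m": (float, False, None),
    "period_s": (float, False, None),
    "delta_p_pa": (float, False, None),
    "waveform_file": (str, False, None),
    "outlet_pressure_pa": (float, False, 0.0),
    # durations / output
    "warmup_periods": (int, False, 3),
    "measured_periods": (int, False, 1),
    "steps": (int, False, None),
    "output_dir": (str, False, "."),
    "output_fields": (str, False, "velocity,pressure"),
    "output_format": (str, False, "vtk"),
    "seed": (int, False, 0),
    # verification extras
    "alpha": (float, False, 3.0),
    "length_factor": (int, False, 6),
    "rho_wall_kg_per_m3": (float, False, 1000.0),
}


def load_config(path) -> dict:
    """Load and validate a flat YAML run configuration."""
    try:
        with open(path) as fh:
            raw = yaml.safe_load(fh)
    except (OSError, yaml.YAMLError) as exc:
        raise ParseError(f"cannot parse config {path}: {exc}") from exc
    if not isinstance(raw, dict):
        raise ParseError(f"config {path} is not a flat key-value mapping")
    unknown = set(raw) - set(_RUN_KEYS)
    if unknown:
        raise ConfigError(f"unknown config key(s): {sorted(unknown)}")
    cfg = {}
    for key, (typ, required, default) in _RUN_KEYS.items():
        if key in raw and raw[key] is not None:
            try:
                cfg[key] = typ(raw[key])
            except (TypeError, ValueError) as exc:
                raise ConfigError(f"config key {key}={raw[key]!r} is not a {typ.__name__}") from exc
        elif required:
            raise ConfigError(f"missing required config key {key}")
        else:
            cfg[key] = default
    if cfg["schema_version"] != CONFIG_SCHEMA_VERSION:
        raise ConfigError(
            f"config schema version {cfg['schema_version']} unsupported "
            f"(expected {CONFIG_SCHEMA_VERSION})"
        )
    return cfg


def save_config(cfg: dict, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=True)


def read_waveform(path):
    """Read a 2-column waveform CSV (time_s, velocity_m_per_s; header required).

    Returns a callable t -> speed using linear interpolation; times outside
    the table raise at call time (no extrapolation).
    """
    try:
        df = pd.read_csv(path)
    except Exception as exc:
        raise ParseError(f"cannot parse waveform {path}: {exc}") from exc
    cols = [c.strip() for c in df.columns]
    if cols[:2] != ["time_s", "velocity_m_per_s"]:
        raise ParseError(
            f"waveform {path} must have header 'time_s,velocity_m_per_s', got {cols[:2]}"
        )
    t = df["time_s"].to_numpy(dtype=float)
    v = df["velocity_m_per_s"].to_numpy(dtype=float)
    if len(t) < 2 or np.any(np.diff(t) <= 0):
        raise ParseError(f"waveform {path} times must be strictly increasing (>= 2 samples)")

    def u_of_t(time):
        if time < t[0] - 1e-12 or time > t[-1] + 1e-12:
            raise ConfigError(
                f"waveform gap: t={time:.6g}s outside table range [{t[0]:.6g}, {t[-1]:.6g}]"
            )
        return float(np.interp(time, t, v))

    return u_of_t


# --- field output ----------------------------------------------------------

def write_fields(sim, path_prefix, fields=("velocity", "pressure"), fmt="vtk"):
    """Write macroscopic fields of a simulation state.

    ``vtk``: one legacy-VTK structured-points file (ASCII) holding the
    requested fields in physical units (zero outside the fluid).
    ``csv``: one CSV point list (fluid sites only).
    Returns the list of written paths.
    """
    path_prefix = Path(path_prefix)
    written = []
    u = np.nan_to_num(sim.velocity_field(physical=True), nan=0.0)
    p = np.nan_to_num(sim.pressure_field(), nan=0.0)
    rho = np.nan_to_num(sim.density_field(), nan=0.0)
    nx, ny, nz = sim.domain.shape
    dx = sim.spec.dx
    if fmt == "vtk":
        path = path_prefix.with_suffix(".vtk")
        buf = _io.StringIO()
        buf.write("# vtk DataFile Version 3.0\n")
        buf.write(f"vesselflow fields step={sim.step_index}\n")
        buf.write("ASCII\nDATASET STRUCTURED_POINTS\n")
        buf.write(f"DIMENSIONS {nx} {ny} {nz}\n")
        o = sim.domain.origin
        buf.write(f"ORIGIN {o[0] + dx / 2:.9e} {o[1] + dx / 2:.9e} {o[2] + dx / 2:.9e}\n")
        buf.write(f"SPACING {dx:.9e} {dx:.9e} {dx:.9e}\n")
        buf.write(f"POINT_DATA {nx * ny * nz}\n")
        # VTK structured points iterate x fastest
        if "velocity" in fields:
            buf.write("VECTORS velocity_m_per_s double\n")
            flat = u.transpose(2, 1, 0, 3).reshape(-1, 3)
            for vx, vy, vz in flat:
                buf.write(f"{vx:.9e} {vy:.9e} {vz:.9e}\n")
        if "pressure" in fields:
            buf.write("SCALARS pressure_pa double 1\nLOOKUP_TABLE default\n")
            for val in p.transpose(2, 1, 0).ravel():
                buf.write(f"{val:.9e}\n")
        if "density" in fields:
            buf.write("SCALARS density_lattice double 1\nLOOKUP_TABLE default\n")
            for val in rho.transpose(2, 1, 0).ravel():
                buf.write(f"{val:.9e}\n")
        path.write_text(buf.getvalue())
        written.append(path)
    elif fmt == "csv":
        path = path_prefix.with_suffix(".csv")
        mask = sim.domain.fluid_mask
        idx = np.argwhere(mask)
        centers = (idx + 0.5) * dx + sim.domain.origin
        df = pd.DataFrame(
            {
                "x_m": centers[:, 0],
                "y_m": centers[:, 1],
                "z_m": centers[:, 2],
                "ux_m_per_s": u[mask][:, 0],
                "uy_m_per_s": u[mask][:, 1],
                "uz_m_per_s": u[mask][:, 2],
                "pressure_pa": p[mask],
                "density_lattice": rho[mask],
            }
        )
        df.to_csv(path, index=False, float_format="%.12e")
        written.append(path)
    else:
        raise ConfigError(f"unknown output format {fmt!r}")
    return written


# --- state persistence -----------------------------------------------------

_STATE_FORMAT_VERSION = 1


def save_state(sim, path) -> None:
    """Persist populations + step index (HDF5) for later WSS extraction."""
    with h5py.File(path, "w") as f:
        f.attrs["version"] = _STATE_FORMAT_VERSION
        f.attrs["step"] = sim.step_index
        f.attrs["tau"] = sim.spec.tau
        f.attrs["dx"] = sim.spec.dx
        f.attrs["dt"] = sim.spec.dt
        f.attrs["rho_physical"] = sim.spec.rho_physical
        f.attrs["elastic"] = sim.elastic
        f.create_dataset("f", data=sim.f)


def load_state(sim, path) -> None:
    """Restore populations saved by :func:`save_state` into ``sim``.

    The simulation must have been built on the same domain/spec (checked via
    array shape and discretization attributes).
    """
    try:
        with h5py.File(path, "r") as fh:
            if int(fh.attrs.get("version", -1)) != _STATE_FORMAT_VERSION:
                raise ParseError(f"state file version mismatch in {path}")
            f = fh["f"][...]
            if f.shape != sim.f.shape:
                raise ConfigError(
                    f"state shape {f.shape} does not match simulation {sim.f.shape}"
                )
            if abs(float(fh.attrs["tau"]) - sim.spec.tau) > 1e-12:
                raise ConfigError("state tau does not match simulation spec")
            sim.f[...] = f
            sim.step_index = int(fh.attrs["step"])
    except (OSError, KeyError) as exc:
        raise ParseError(f"malformed state file {path}: {exc}") from exc
    # refresh moments
    ids = sim.stream_ids
    fs = sim.f[ids]
    rho = fs.sum(axis=1)
    from .lattice import C

    u = (fs @ C.astype(float)) / rho[:, None]
    sim.rho[ids] = rho
    sim.ux[ids], sim.uy[ids], sim.uz[ids] = u[:, 0], u[:, 1], u[:, 2]
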