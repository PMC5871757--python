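"""Configuration, snapshot serialization and segmented-cell-table ingestion.

Snapshots are diff-able delimited text: a ``#``-prefixed key=value header
block carrying the full parameter set (reproducibility contract), then a CSV
body with one row per cell.  Floats are written with full round-trip
precision, so write -> read reproduces a ClusterState bit-exactly.

Cell tables let the same morphometrics run on segmented experimental
micrographs: one row per cell with center, orientation angle and tip-to-tip
length, in declared units.
"""

from __future__ import annotations

import ast
import io as _stdio
import math
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .engine import SimulationParams
from .geometry import ClusterState, Spherocylinder

__all__ = [
    "load_config",
    "write_snapshot",
    "read_snapshot",
    "write_xyz",
    "load_cell_table",
]

SCHEMA_VERSION = 1

_CONFIG_KEYS = {
    "Gamma", "L_star_0", "D0", "dt_star", "epsilon", "kBT", "N_max",
    "snapshot_counts", "seed", "replicates", "mc_points_per_annulus", "dr",
}


class ConfigError(ValueError):
    """Invalid or unreadable simulation configuration."""


def load_config(path: str | Path, **overrides) -> SimulationParams:
    """Read a YAML/key-value config file into validated SimulationParams.

    Missing keys fall back to the study defaults (L*_0 = 2.6, D0 = 0.1,
    dt* = 1e-4, snapshots at 32..1024, 10 replicates); an empty file yields
    the full default set (Gamma defaults to 1 and should normally be given).
    Unknown keys and out-of-domain values raise :class:`ConfigError`.
    """
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"config file not found: {path}")
    try:
        raw = yaml.safe_load(path.read_text()) or {}
    except yaml.YAMLError as e:
        raise ConfigError(f"cannot parse config {path}: {e}") from e
    if not isinstance(raw, dict):
        raise ConfigError(f"config must be a mapping of keys to values, got {type(raw)}")
    unknown = set(raw) - _CONFIG_KEYS
    if unknown:
        raise ConfigError(f"unknown config keys: {sorted(unknown)}")
    raw.update(overrides)
    raw.setdefault("Gamma", 1.0)
    if "snapshot_counts" in raw:
        raw["snapshot_counts"] = tuple(int(v) for v in raw["snapshot_counts"])
    try:
        return SimulationParams(**raw)
    except (TypeError, ValueError) as e:
        raise ConfigError(f"invalid config {path}: {e}") from e


def _params_header(params: SimulationParams | None) -> dict:
    if params is None:
        return {}
    return {
        "L_star_0": params.L_star_0,
        "Gamma": params.Gamma,
        "D0": params.D0,
        "dt_star": params.dt_star,
        "epsilon": params.epsilon,
        "seed": params.seed,
    }


def write_snapshot(
    state: ClusterState, path: str | Path, params: SimulationParams | None = None
) -> None:
    """Serialize a cluster to the delimited-text snapshot format."""
    path = Path(path)
    header = {
        "schema_version": SCHEMA_VERSION,
        **_params_header(params),
        "time": state.time,
        "division_rounds": state.division_rounds,
        "n_particles": len(state),
    }
    lines = [f"# {k} = {v!r}" for k, v in header.items()]
    rows = [
        {
            "id": p.id,
            "parent_id": -1 if p.parent_id is None else p.parent_id,
            "x": p.center[0],
            "y": p.center[1],
            "theta": p.theta,
            "cyl_length": p.cyl_length,
        }
        for p in state.particles
    ]
    buf = _stdio.StringIO()
    pd.DataFrame(rows, columns=["id", "parent_id", "x", "y", "theta", "cyl_length"]).to_csv(
        buf, index=False, float_format="%.17g"
    )
    path.write_text("\n".join(lines) + "\n" + buf.getvalue())


def _parse_header(lines: list[str]) -> dict:
    meta = {}
    for ln in lines:
        body = ln.lstrip("#").strip()
        if "=" not in body:
            continue
        k, v = body.split("=", 1)
        try:
            meta[k.strip()] = ast.literal_eval(v.strip())
        except (ValueError, SyntaxError):
            meta[k.strip()] = v.strip()
    return meta


def read_snapshot(path: str | Path) -> tuple[ClusterState, dict]:
    """Read a snapshot file back into a ClusterState plus its metadata."""
    path = Path(path)
    text = path.read_text()
    header_lines = [ln for ln in text.splitlines() if ln.startswith("#")]
    meta = _parse_header(header_lines)
    version = meta.get("schema_version")
    if version != SCHEMA_VERSION:
        raise ValueError(
            f"snapshot schema version mismatch: file has {version!r}, "
            f"reader supports {SCHEMA_VERSION}"
        )
    body = "\n".join(ln for ln in text.splitlines() if not ln.startswith("#"))
    # round_trip parsing: the writer emits full-precision floats and the
    # documented contract is a bit-exact write -> read cycle
    df = pd.read_csv(_stdio.StringIO(body), float_precision="round_trip")
    required = {"id", "parent_id", "x", "y", "theta", "cyl_length"}
    if not required.issubset(df.columns):
        raise ValueError(f"snapshot missing columns: {sorted(required - set(df.columns))}")
    n_expected = meta.get("n_particles")
    if n_expected is not None and len(df) != n_expected:
        raise ValueError(
            f"truncated snapshot: header says {n_expected} particles, file has {len(df)}"
        )
    particles = [
        Spherocylinder(
            center=np.array([row.x, row.y]),
            theta=float(row.theta),
            cyl_length=float(row.cyl_length),
            id=int(row.id),
            parent_id=None if row.parent_id < 0 else int(row.parent_id),
        )
        for row in df.itertuples()
    ]
    state = ClusterState(
        particles=particles,
        time=float(meta.get("time", 0.0)),
        division_rounds=int(meta.get("division_rounds", 0)),
    )
    return state, meta


def write_xyz(state: ClusterState, path: str | Path, comment: str = "") -> None:
    """Extended-XYZ export (center, orientation, length) for viewers."""
    path = Path(path)
    lines = [str(len(state))]
    props = 'Properties=species:S:1:pos:R:2:orientation:R:2:cyl_length:R:1'
    lines.append(f'Lattice="1 0 0 0 1 0 0 0 1" {props} time={state.time} {comment}'.strip())
    for p in state.particles:
        e = p.orientation
        lines.append(
            f"C {p.center[0]:.10g} {p.center[1]:.10g} {e[0]:.10g} {e[1]:.10g} {p.cyl_length:.10g}"
        )
    path.write_text("\n".join(lines) + "\n")


def load_cell_table(
    path: str | Path,
    scale: float = 1.0,
    angle_unit: str = "rad",
) -> ClusterState:
    """Turn a segmented-cell table into a ClusterState for morphometrics.

    The CSV must have columns x, y, theta, total_length.  ``scale`` converts
    the table's length unit into cell diameters (sigma), e.g. 1/width_um for
    micrographs in micrometers.  Each row becomes a spherocylinder with
    cylinder length ``total_length*scale - 1`` (clamped at 0, with a warning
    for sub-diameter rows); angles are mapped to [0, pi) since the cells are
    apolar.
    """
    import warnings

    df = pd.read_csv(path)
    required = {"x", "y", "theta", "total_length"}
    if not required.issubset(df.columns):
        raise ValueError(f"cell table missing columns: {sorted(required - set(df.columns))}")
    if len(df) == 0:
        raise ValueError("cell table is empty")
    if angle_unit not in ("rad", "deg"):
        raise ValueError("angle_unit must be 'rad' or 'deg'")
    if scale <= 0:
        raise ValueError("scale must be positive")
    theta = df["theta"].to_numpy(float)
    if angle_unit == "deg":
        theta = np.deg2rad(theta)
    theta = np.mod(theta, np.pi)
    particles = []
    for k, row in enumerate(df.itertuples()):
        total = float(row.total_length) * scale
        cyl = total - 1.0
        if cyl < 0:
            warnings.warn(
                f"row {k}: total length {total:.3g} sigma below one diameter; "
                "clamping cylinder length to 0",
                RuntimeWarning,
                stacklevel=2,
            )
            cyl = 0.0
        particles.append(
            Spherocylinder(
                center=np.array([row.x, row.y]) * scale,
                theta=float(theta[k]),
                cyl_length=cyl,
                id=k,
            )
        )
    n = len(particles)
    rounds = int(math.log2(n)) if n & (n - 1) == 0 else 0
    return ClusterState(particles=particles, time=0.0, division_rounds=rounds)
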