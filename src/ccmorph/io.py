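"""File formats: PLY/OFF meshes, grid archives, feature tables, VTK maps.

Meshes are written as binary little-endian PLY (or ASCII OFF) through
trimesh; grids as NPZ archives; feature tables and manifests as UTF-8 CSV
with a header row; statistical maps additionally as legacy-ASCII VTK
structured grids with point-data scalars for visualization.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import trimesh

from .mesh import SurfaceMesh
from .parameterize import GridSurface
from .morphometry import FeatureField

__all__ = [
    "MeshFormatError",
    "read_mesh",
    "write_mesh",
    "read_grid",
    "write_grid",
    "write_grid_vtk",
    "features_to_frame",
    "write_features",
    "read_features",
]


class MeshFormatError(ValueError):
    """A mesh file could not be parsed."""


def write_mesh(mesh: SurfaceMesh, path) -> Path:
    """Write a surface as binary little-endian PLY or ASCII OFF (by suffix)."""
    path = Path(path)
    tm = mesh.to_trimesh()
    suffix = path.suffix.lower()
    if suffix not in (".ply", ".off"):
        raise MeshFormatError(f"unsupported mesh format {suffix!r}")
    tm.export(path)
    return path


def read_mesh(path, subject_id: str | None = None) -> SurfaceMesh:
    """Read a PLY or OFF surface; malformed files raise :class:`MeshFormatError`."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        tm = trimesh.load(path, process=False, force="mesh")
    except Exception as exc:  # noqa: BLE001 - normalize parser failures
        raise MeshFormatError(f"cannot parse mesh file {path}: {exc}") from exc
    if not isinstance(tm, trimesh.Trimesh) or len(tm.faces) == 0:
        raise MeshFormatError(f"{path} contains no triangle mesh")
    return SurfaceMesh(np.asarray(tm.vertices, dtype=np.float64),
                       np.asarray(tm.faces, dtype=np.int64),
                       subject_id=subject_id or path.stem)


def write_grid(grid: GridSurface, path) -> Path:
    path = Path(path)
    np.savez(path, points=grid.points, subject_id=str(grid.subject_id))
    return path if path.suffix == ".npz" else path.with_suffix(path.suffix + ".npz")


def read_grid(path) -> GridSurface:
    with np.load(path, allow_pickle=False) as data:
        sid = str(data["subject_id"])
        return GridSurface(data["points"], subject_id=None if sid == "None" else sid)


def write_grid_vtk(grid: GridSurface, path, scalars: dict[str, np.ndarray] | None = None) -> Path:
    """Legacy-ASCII VTK structured grid with optional point-data scalar maps.

    The periodic v direction is closed by duplicating the seam column so
    the tube renders without a gap.
    """
    path = Path(path)
    n_u, n_v = grid.dims
    pts = np.concatenate([grid.points, grid.points[:, :1]], axis=1)  # close seam
    lines = [
        "# vtk DataFile Version 3.0",
        f"ccmorph grid {grid.subject_id}",
        "ASCII",
        "DATASET STRUCTURED_GRID",
        f"DIMENSIONS {n_v + 1} {n_u} 1",
        f"POINTS {n_u * (n_v + 1)} float",
    ]
    flat = pts.reshape(-1, 3)
    lines.extend(f"{x:.6f} {y:.6f} {z:.6f}" for x, y, z in flat)
    if scalars:
        lines.append(f"POINT_DATA {n_u * (n_v + 1)}")
        for name, field in scalars.items():
            field = np.asarray(field, dtype=np.float64).reshape(n_u, n_v)
            closed = np.concatenate([field, field[:, :1]], axis=1).ravel()
            lines.append(f"SCALARS {name} float 1")
            lines.append("LOOKUP_TABLE default")
            lines.extend(f"{val:.6g}" for val in closed)
    path.write_text("\n".join(lines) + "\n")
    return path


def features_to_frame(field: FeatureField) -> pd.DataFrame:
    """Tidy per-vertex feature table (u_idx, v_idx, detJ, logS*, MAD)."""
    n_u, n_v = field.dims
    i, j = np.meshgrid(np.arange(n_u), np.arange(n_v), indexing="ij")
    return pd.DataFrame({
        "u_idx": i.ravel(),
        "v_idx": j.ravel(),
        "detJ": field.detj.ravel(),
        "logS11": field.logs3[..., 0].ravel(),
        "logS12": field.logs3[..., 1].ravel(),
        "logS22": field.logs3[..., 2].ravel(),
        "MAD": field.mad.ravel(),
    })


def write_features(field: FeatureField, path) -> Path:
    path = Path(path)
    features_to_frame(field).to_csv(path, index=False)
    return path


def read_features(path, subject_id: str | None = None,
                  log_mad: bool = False) -> FeatureField:
    df = pd.read_csv(path)
    n_u = int(df["u_idx"].max()) + 1
    n_v = int(df["v_idx"].max()) + 1
    if len(df) != n_u * n_v:
        raise ValueError(f"feature table {path} is not a complete grid")
    df = df.sort_values(["u_idx", "v_idx"])
    logs3 = np.stack([df[c].to_numpy().reshape(n_u, n_v)
                      for c in ("logS11", "logS12", "logS22")], axis=-1)
    return FeatureField(
        logs3=logs3,
        detj=df["detJ"].to_numpy().reshape(n_u, n_v),
        mad=df["MAD"].to_numpy().reshape(n_u, n_v),
        subject_id=subject_id,
        log_mad=log_mad,
    )
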