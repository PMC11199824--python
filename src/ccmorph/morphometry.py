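"""Per-vertex morphometric features on the conformal grid.

For each subject in correspondence with a template grid, three families of
features are computed:

* the 2x2 Jacobian ``J`` of the template-to-subject map on each grid
  triangle, with ``det J`` measuring local area expansion (> 1) or
  shrinkage (< 1) relative to the template;
* the deformation (Cauchy-Green) tensor ``S = (J^T J)^(1/2)`` and its
  matrix logarithm, summarized by the 3-vector
  ``(log S_11, log S_12, log S_22)`` — the rotation-invariant multivariate
  tensor-based morphometry (mTBM) feature;
* the medial axial distance (MAD): the distance from each grid vertex to
  the medial axis, where the medial axis is the centroid of each closed
  iso-parametric (constant-u) curve — a thickness measure sensitive to
  change along the surface normal, complementing mTBM's sensitivity to
  tangential shear.

The concatenated 4-vector [log S (3), MAD] is the combined MADMTBM feature.
Jacobians are computed per grid triangle in local orthonormal tangent
frames, ``J = [target edges][source edges]^-1`` with source = template, and
area-weighted averaged onto grid vertices so all features live per vertex.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .mesh import GeometryError
from .parameterize import GridSurface
from .synthetic import MedialCurve

__all__ = [
    "FeatureField",
    "triangle_jacobian",
    "deformation_tensor",
    "medial_axis",
    "mad_field",
    "feature_field",
    "grid_triangles",
    "arclength_fractions",
    "window_rows",
]

_EIG_FLOOR = 1e-12


# --------------------------------------------------------------------------- #
# Jacobians and deformation tensors                                           #
# --------------------------------------------------------------------------- #
def _local_edges(tris: np.ndarray) -> np.ndarray:
    """Edge vectors of triangles in their local orthonormal 2-D frames.

    ``tris`` is (..., 3, 3) vertex positions.  The frame's first axis lies
    along edge v2 - v1, the second in-plane orthogonal to it.  Returns
    (..., 2, 2) matrices whose columns are the coordinates of edges
    v2 - v1 and v3 - v1.
    """
    e1 = tris[..., 1, :] - tris[..., 0, :]
    e2 = tris[..., 2, :] - tris[..., 0, :]
    l1 = np.linalg.norm(e1, axis=-1)
    if np.any(l1 < 1e-300):
        raise GeometryError("degenerate triangle: zero-length edge")
    f1 = e1 / l1[..., None]
    nrm = np.cross(e1, e2)
    area2 = np.linalg.norm(nrm, axis=-1)
    if np.any(area2 < 2e-12):
        raise GeometryError("degenerate triangle: area below 1e-12 mm^2")
    f2 = np.cross(nrm / area2[..., None], f1)
    out = np.empty(tris.shape[:-2] + (2, 2))
    out[..., 0, 0] = l1
    out[..., 1, 0] = 0.0
    out[..., 0, 1] = (e2 * f1).sum(axis=-1)
    out[..., 1, 1] = (e2 * f2).sum(axis=-1)
    return out


def triangle_jacobian(source_tri: np.ndarray, target_tri: np.ndarray) -> np.ndarray:
    """2x2 Jacobian mapping source-triangle edge coordinates to the target's.

    Both triangles are expressed in their own local orthonormal frames, so
    the result is invariant to rigid motions of either triangle:
    identical triangles give the identity, a uniform scaling by ``s``
    gives ``s * I``.
    """
    src = _local_edges(np.asarray(source_tri, dtype=np.float64)[None])
    tgt = _local_edges(np.asarray(target_tri, dtype=np.float64)[None])
    return (tgt[0] @ np.linalg.inv(src[0]))


def _jacobian_batch(src_tris: np.ndarray, tgt_tris: np.ndarray) -> np.ndarray:
    src = _local_edges(src_tris)
    tgt = _local_edges(tgt_tris)
    return tgt @ np.linalg.inv(src)


def deformation_tensor(J: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Deformation tensor ``S = (J^T J)^(1/2)`` and its log 3-vector.

    Computed by symmetric eigendecomposition with an eigenvalue floor of
    1e-12.  Returns ``(S, logS3)`` with ``logS3 = (log S)_{11, 12, 22}``.
    Rotation-invariant: any ``R J`` with ``R`` a rotation gives the same S.
    """
    J = np.asarray(J, dtype=np.float64)
    single = J.ndim == 2
    if single:
        J = J[None]
    if not np.all(np.isfinite(J)):
        raise FloatingPointError("non-finite Jacobian")
    jtj = np.swapaxes(J, -1, -2) @ J
    w, q = np.linalg.eigh(jtj)
    w = np.maximum(w, _EIG_FLOOR)
    s = (q * np.sqrt(w)[..., None, :]) @ np.swapaxes(q, -1, -2)
    logs = (q * (0.5 * np.log(w))[..., None, :]) @ np.swapaxes(q, -1, -2)
    logs3 = np.stack([logs[..., 0, 0], logs[..., 0, 1], logs[..., 1, 1]], axis=-1)
    if single:
        return s[0], logs3[0]
    return s, logs3


# --------------------------------------------------------------------------- #
# medial axis and MAD                                                         #
# --------------------------------------------------------------------------- #
def medial_axis(grid: GridSurface) -> MedialCurve:
    """Medial axis: midpoints of the closed iso-parametric (iso-u) curves.

    Each medial point is the arclength-weighted centroid of the closed
    circumferential polyline at constant u.  Arclength weighting makes the
    midpoint independent of how densely the conformal grid samples each
    part of the curve (conformal maps space the v-lines unevenly around
    curved tubes), so a circular section yields its true centre.
    """
    p = grid.points  # (n_u, n_v, 3)
    seg = np.linalg.norm(np.roll(p, -1, axis=1) - p, axis=2)  # len of edge j -> j+1
    w = 0.5 * (seg + np.roll(seg, 1, axis=1))                 # vertex weight
    wsum = np.maximum(w.sum(axis=1), 1e-300)
    pts = (w[..., None] * p).sum(axis=1) / wsum[:, None]      # (n_u, 3)
    seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    cum = np.concatenate([[0.0], np.cumsum(seg)])
    t = cum / cum[-1] if cum[-1] > 0 else np.linspace(0, 1, len(pts))
    return MedialCurve(points=pts, t=t)


def mad_field(grid: GridSurface, axis: MedialCurve) -> np.ndarray:
    """Medial axial distance: |grid(u_i, v_j) - axis(u_i)| in mm, (n_u, n_v)."""
    n_u = grid.dims[0]
    if len(axis.points) != n_u:
        raise ValueError("medial axis length must equal the grid's n_u")
    return np.linalg.norm(grid.points - axis.points[:, None, :], axis=2)


def arclength_fractions(axis: MedialCurve) -> np.ndarray:
    """Arclength fraction in [0, 1] of each medial-axis point."""
    return axis.t


def window_rows(grid: GridSurface, window: tuple[float, float],
                dilate: int = 0) -> np.ndarray:
    """Grid-row indices whose medial arclength fraction lies in ``window``.

    ``dilate`` widens the row set by that many rows on each side; used to
    compare significance maps against a ground-truth effect window.
    """
    frac = arclength_fractions(medial_axis(grid))
    rows = np.where((frac >= window[0]) & (frac <= window[1]))[0]
    if len(rows) == 0:
        return rows
    lo = max(0, rows.min() - dilate)
    hi = min(len(frac) - 1, rows.max() + dilate)
    return np.arange(lo, hi + 1)


# --------------------------------------------------------------------------- #
# combined feature field                                                      #
# --------------------------------------------------------------------------- #
def grid_triangles(n_u: int, n_v: int) -> np.ndarray:
    """Triangulation of the periodic (u, v) grid; vertex id = i * n_v + j."""
    i, j = np.meshgrid(np.arange(n_u - 1), np.arange(n_v), indexing="ij")
    j2 = (j + 1) % n_v
    a = i * n_v + j
    b = (i + 1) * n_v + j
    c = (i + 1) * n_v + j2
    d = i * n_v + j2
    t1 = np.stack([a, b, c], axis=-1).reshape(-1, 3)
    t2 = np.stack([a, c, d], axis=-1).reshape(-1, 3)
    return np.concatenate([t1, t2], axis=0)


@dataclass
class FeatureField:
    """Per-vertex morphometric features of one subject on the grid.

    ``logs3``: (n_u, n_v, 3) mTBM log-deformation-tensor components;
    ``detj``: (n_u, n_v) area-change determinant; ``mad``: (n_u, n_v) mm.
    """

    logs3: np.ndarray
    detj: np.ndarray
    mad: np.ndarray
    subject_id: str | None = None
    log_mad: bool = False

    @property
    def dims(self) -> tuple[int, int]:
        return self.detj.shape

    def madmtbm(self) -> np.ndarray:
        """The combined 4-vector [logS3, MAD] per vertex, (n_u, n_v, 4)."""
        thick = np.log(self.mad) if self.log_mad else self.mad
        return np.concatenate([self.logs3, thick[..., None]], axis=-1)

    def feature(self, name: str) -> np.ndarray:
        """Feature stack by name: 'madmtbm' (d=4), 'mtbm' (3), 'mad' or 'detj' (1)."""
        if name == "madmtbm":
            return self.madmtbm()
        if name == "mtbm":
            return self.logs3
        if name == "mad":
            thick = np.log(self.mad) if self.log_mad else self.mad
            return thick[..., None]
        if name == "detj":
            return self.detj[..., None]
        raise KeyError(f"unknown feature {name!r}")


def feature_field(subject: GridSurface, template: GridSurface,
                  log_mad: bool = False) -> FeatureField:
    """All morphometric features of ``subject`` relative to ``template``.

    Jacobians are computed per grid triangle (template as source), their
    log-tensors and determinants area-weighted averaged onto grid
    vertices; MAD comes from the subject's own medial axis.  Raises
    :class:`GeometryError` if any triangle correspondence is folded
    (det J <= 0).
    """
    if subject.dims != template.dims:
        raise ValueError("subject and template grids must share dimensions")
    n_u, n_v = subject.dims
    tris = grid_triangles(n_u, n_v)
    src = template.flat()[tris]
    tgt = subject.flat()[tris]
    J = _jacobian_batch(src, tgt)
    detj_tri = np.linalg.det(J)
    if np.any(detj_tri <= 0):
        k = int(np.argmin(detj_tri))
        i, j = divmod(int(tris[k, 0]), n_v)
        raise GeometryError(
            f"non-positive Jacobian determinant ({detj_tri[k]:.3e}) at grid "
            f"cell (u={i}, v={j}); correspondence is folded"
        )
    _, logs3_tri = deformation_tensor(J)

    # area-weighted transfer from triangles to their three vertices
    e1 = src[:, 1] - src[:, 0]
    e2 = src[:, 2] - src[:, 0]
    areas = 0.5 * np.linalg.norm(np.cross(e1, e2), axis=1)
    nv_tot = n_u * n_v
    wsum = np.zeros(nv_tot)
    logs3_v = np.zeros((nv_tot, 3))
    detj_v = np.zeros(nv_tot)
    for corner in range(3):
        idx = tris[:, corner]
        np.add.at(wsum, idx, areas)
        np.add.at(logs3_v, idx, areas[:, None] * logs3_tri)
        np.add.at(detj_v, idx, areas * detj_tri)
    wsum = np.maximum(wsum, 1e-300)
    logs3_v /= wsum[:, None]
    detj_v /= wsum

    axis = medial_axis(subject)
    mad = mad_field(subject, axis)
    return FeatureField(
        logs3=logs3_v.reshape(n_u, n_v, 3),
        detj=detj_v.reshape(n_u, n_v),
        mad=mad,
        subject_id=subject.subject_id,
        log_mad=log_mad,
    )
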