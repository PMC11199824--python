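"""Cylindrical conformal-grid parameterization of tube-like surfaces.

Each subject surface (cylinder topology, two open boundary loops) is mapped
to the unit square: landmark vertices are detected at the two extreme ends,
the tube is sliced open along a shortest path between them (giving a
topological disk), and a constrained harmonic map assigns coordinates
``u`` (0 on the rostral boundary loop, 1 on the caudal one) and ``v``
(0 and 1 on the two copies of the cut seam, periodic circumferentially).
Resampling the surface at a regular (u, v) grid gives cross-subject vertex
correspondence: the conformal grid on which all morphometric features live.

The harmonic coordinates minimize the discrete Dirichlet energy with
cotangent weights; if that map produces fold-overs (flipped parameter
triangles, possible when cotangent weights go negative on poor triangles),
the solver falls back to uniform (Tutte) weights with the full boundary
pinned to the unit-square boundary, which guarantees an injective embedding.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
import scipy.sparse.csgraph as csgraph
from matplotlib.tri import Triangulation, TrapezoidMapTriFinder

from .mesh import SurfaceMesh, TopologyError

logger = logging.getLogger(__name__)

__all__ = [
    "CutSurface",
    "ParamSurface",
    "GridSurface",
    "detect_landmarks",
    "cut_surface",
    "harmonic_map",
    "resample_to_grid",
    "parameterize_mesh",
    "rigid_align",
    "make_template",
]


class SolverError(RuntimeError):
    """Harmonic solve failed or exceeded its residual tolerance."""


# --------------------------------------------------------------------------- #
# landmarks                                                                   #
# --------------------------------------------------------------------------- #
def detect_landmarks(mesh: SurfaceMesh) -> tuple[int, int]:
    """Endpoint landmark vertices, one on each boundary loop.

    The landmarks are the extreme vertices of each loop along the first
    principal axis of the vertex cloud.  The axis sign is fixed so it
    points from the loop containing the smallest vertex index toward the
    other loop, making the (rostral, caudal) order and the returned
    indices deterministic and rigid-motion equivariant.  Ties break to the
    lowest vertex index.
    """
    loops = mesh.boundary_loops()
    if len(loops) != 2:
        raise TopologyError(f"expected 2 boundary loops, found {len(loops)}")
    v = mesh.vertices
    centred = v - v.mean(axis=0)
    cov = centred.T @ centred
    w, vecs = np.linalg.eigh(cov)
    axis = vecs[:, -1]
    ca = v[loops[0]].mean(axis=0)
    cb = v[loops[1]].mean(axis=0)
    if np.dot(axis, cb - ca) < 0:
        axis = -axis
    la = np.sort(loops[0])
    lb = np.sort(loops[1])
    lm_a = int(la[np.argmin(v[la] @ axis)])
    lm_b = int(lb[np.argmax(v[lb] @ axis)])
    return lm_a, lm_b


# --------------------------------------------------------------------------- #
# cutting                                                                     #
# --------------------------------------------------------------------------- #
@dataclass
class CutSurface:
    """A cylinder mesh sliced open to a disk along a seam path.

    ``path`` holds the original vertex ids along the seam (rostral landmark
    first); ``path_dup`` the appended duplicate ids, pairwise corresponding.
    ``parent`` is the uncut mesh (used to solve ``u`` with exactly matched
    values on both seam copies).
    """

    mesh: SurfaceMesh
    parent: SurfaceMesh
    path: np.ndarray
    path_dup: np.ndarray

    def seam_pairs(self) -> np.ndarray:
        return np.column_stack([self.path, self.path_dup])


def _shortest_path(mesh: SurfaceMesh, src: int, dst: int,
                   forbidden: np.ndarray) -> np.ndarray:
    """Shortest edge path src -> dst avoiding ``forbidden`` vertices."""
    edges = mesh.edges_unique()
    keep = ~(np.isin(edges[:, 0], forbidden) | np.isin(edges[:, 1], forbidden))
    edges = edges[keep]
    wts = np.linalg.norm(mesh.vertices[edges[:, 0]] - mesh.vertices[edges[:, 1]], axis=1)
    n = mesh.n_vertices
    g = sp.csr_matrix((wts, (edges[:, 0], edges[:, 1])), shape=(n, n))
    g = g + g.T
    dist, pred = csgraph.dijkstra(g, indices=src, return_predecessors=True)
    if not np.isfinite(dist[dst]):
        raise TopologyError(f"no cut path between landmarks {src} and {dst}")
    path = [dst]
    while path[-1] != src:
        path.append(int(pred[path[-1]]))
    return np.array(path[::-1], dtype=np.int64)


def _directed_edge_face(faces: np.ndarray) -> dict[tuple[int, int], int]:
    """Map directed edge (a, b) -> index of the face whose winding contains it."""
    out: dict[tuple[int, int], int] = {}
    for fi, (a, b, c) in enumerate(faces):
        out[(int(a), int(b))] = fi
        out[(int(b), int(c))] = fi
        out[(int(c), int(a))] = fi
    return out


def cut_surface(mesh: SurfaceMesh, landmarks: tuple[int, int]) -> CutSurface:
    """Slice the cylinder open along the shortest landmark-to-landmark path.

    Every path vertex is duplicated; faces on one consistent side of the
    seam (picked by face winding, so consistent on oriented meshes) are
    rewired to the duplicates.  The result is a topological disk with a
    single boundary loop.
    """
    lm_a, lm_b = landmarks
    loops = mesh.boundary_loops()
    boundary = np.concatenate(loops)
    forbidden = boundary[(boundary != lm_a) & (boundary != lm_b)]
    path = _shortest_path(mesh, lm_a, lm_b, forbidden)

    faces = mesh.faces.copy()
    dedge = _directed_edge_face(faces)
    vert_faces: dict[int, list[int]] = {}
    for fi, f in enumerate(faces):
        for vv in f:
            vert_faces.setdefault(int(vv), []).append(fi)

    path_set = set(int(p) for p in path)
    n_orig = mesh.n_vertices
    new_ids = np.arange(n_orig, n_orig + len(path))
    replace: dict[int, int] = {int(p): int(nid) for p, nid in zip(path, new_ids)}

    # faces to rewire, per path vertex: the fan component (after removing
    # cut edges) that contains the face with the directed path edge
    side_faces: dict[int, set[int]] = {}
    for k, p in enumerate(path):
        p = int(p)
        cut_nbrs = set()
        if k > 0:
            cut_nbrs.add(int(path[k - 1]))
        if k < len(path) - 1:
            cut_nbrs.add(int(path[k + 1]))
        incident = vert_faces[p]
        # adjacency between incident faces via non-cut edges at p
        edge_to_faces: dict[int, list[int]] = {}
        for fi in incident:
            for vv in faces[fi]:
                vv = int(vv)
                if vv != p and vv not in cut_nbrs:
                    edge_to_faces.setdefault(vv, []).append(fi)
        adj: dict[int, set[int]] = {fi: set() for fi in incident}
        for flist in edge_to_faces.values():
            if len(flist) == 2:
                adj[flist[0]].add(flist[1])
                adj[flist[1]].add(flist[0])
        # seed face: contains the directed edge along the path at p
        if k < len(path) - 1:
            seed = dedge[(p, int(path[k + 1]))]
        else:
            seed = dedge[(int(path[k - 1]), p)]
        comp = {seed}
        stack = [seed]
        while stack:
            cur = stack.pop()
            for nxt in adj[cur]:
                if nxt not in comp:
                    comp.add(nxt)
                    stack.append(nxt)
        side_faces[p] = comp

    for p, comp in side_faces.items():
        for fi in comp:
            f = faces[fi]
            faces[fi] = [replace[int(vv)] if int(vv) == p else int(vv) for vv in f]

    new_verts = np.vstack([mesh.vertices, mesh.vertices[path]])
    cut_mesh = SurfaceMesh(new_verts, faces, subject_id=mesh.subject_id)
    chi = cut_mesh.euler_characteristic()
    n_loops = len(cut_mesh.boundary_loops())
    if chi != 1 or n_loops != 1:
        raise TopologyError(
            f"cut surface is not a disk (chi={chi}, boundary loops={n_loops})"
        )
    return CutSurface(mesh=cut_mesh, parent=mesh, path=path, path_dup=new_ids)


# --------------------------------------------------------------------------- #
# harmonic map                                                                #
# --------------------------------------------------------------------------- #
def _cotan_laplacian(vertices: np.ndarray, faces: np.ndarray) -> sp.csr_matrix:
    """Cotangent-weight Laplacian (positive semi-definite convention)."""
    n = len(vertices)
    ii, jj, ww = [], [], []
    for shift in range(3):
        a = faces[:, shift]
        b = faces[:, (shift + 1) % 3]
        c = faces[:, (shift + 2) % 3]
        # cotangent of angle at c, opposite edge (a, b)
        u = vertices[a] - vertices[c]
        v = vertices[b] - vertices[c]
        cross = np.linalg.norm(np.cross(u, v), axis=1)
        cross = np.maximum(cross, 1e-300)
        cot = (u * v).sum(axis=1) / cross
        ii.append(a); jj.append(b); ww.append(0.5 * cot)
        ii.append(b); jj.append(a); ww.append(0.5 * cot)
    ii = np.concatenate(ii)
    jj = np.concatenate(jj)
    ww = np.concatenate(ww)
    w_mat = sp.csr_matrix((ww, (ii, jj)), shape=(n, n))
    deg = np.asarray(w_mat.sum(axis=1)).ravel()
    return sp.diags(deg) - w_mat


def _uniform_laplacian(n: int, edges: np.ndarray) -> sp.csr_matrix:
    w = np.ones(len(edges))
    a = sp.csr_matrix((w, (edges[:, 0], edges[:, 1])), shape=(n, n))
    a = a + a.T
    deg = np.asarray(a.sum(axis=1)).ravel()
    return sp.diags(deg) - a


def _solve_dirichlet(lap: sp.csr_matrix, fixed_idx: np.ndarray,
                     fixed_val: np.ndarray) -> np.ndarray:
    n = lap.shape[0]
    free = np.setdiff1d(np.arange(n), fixed_idx)
    x = np.zeros(n)
    x[fixed_idx] = fixed_val
    if len(free):
        a = lap[free][:, free].tocsc()
        rhs = -lap[free][:, fixed_idx] @ fixed_val
        x[free] = sp.linalg.spsolve(a, rhs)
    return x


@dataclass
class ParamSurface:
    """(u, v) coordinates per cut-mesh vertex, u, v in [0, 1]."""

    cut: CutSurface
    uv: np.ndarray
    method: str = "cotan"
    residual: float = 0.0
    flipped: int = 0

    def signed_areas(self) -> np.ndarray:
        f = self.cut.mesh.faces
        uv = self.uv
        e1 = uv[f[:, 1]] - uv[f[:, 0]]
        e2 = uv[f[:, 2]] - uv[f[:, 0]]
        return 0.5 * (e1[:, 0] * e2[:, 1] - e1[:, 1] * e2[:, 0])


def _count_flips(uv: np.ndarray, faces: np.ndarray) -> int:
    e1 = uv[faces[:, 1]] - uv[faces[:, 0]]
    e2 = uv[faces[:, 2]] - uv[faces[:, 0]]
    area = e1[:, 0] * e2[:, 1] - e1[:, 1] * e2[:, 0]
    sign = np.sign(np.median(area))
    if sign == 0:
        sign = 1.0
    return int(np.sum(area * sign <= 0))


def _interior_residual(lap: sp.csr_matrix, x: np.ndarray,
                       fixed: np.ndarray) -> float:
    free = np.setdiff1d(np.arange(lap.shape[0]), fixed)
    if not len(free):
        return 0.0
    r = np.abs((lap @ x)[free]).max()
    scale = np.abs(lap.diagonal()).mean()
    return float(r / scale)


def _tutte_rectangle(cut: CutSurface) -> np.ndarray:
    """Fallback embedding: full boundary pinned to the unit square, uniform weights.

    The boundary loop of the disk decomposes at the four landmark copies
    into the two end arcs and the two seam copies; each chain is mapped to
    one square side by relative arc length.  Uniform-weight harmonic
    interior coordinates then give an injective (Tutte) embedding.
    """
    mesh = cut.mesh
    loop = mesh.boundary_loops()[0]
    corners = {int(cut.path[0]), int(cut.path[-1]),
               int(cut.path_dup[0]), int(cut.path_dup[-1])}
    # rotate the loop to start at a corner
    start = next(i for i, vv in enumerate(loop) if int(vv) in corners)
    loop = np.roll(loop, -start)
    # split into 4 chains at corners
    chains: list[list[int]] = []
    cur = [int(loop[0])]
    for vv in list(loop[1:]) + [int(loop[0])]:
        cur.append(int(vv))
        if int(vv) in corners:
            chains.append(cur)
            cur = [int(vv)]
    if len(chains) != 4:
        raise SolverError(f"cut boundary decomposes into {len(chains)} chains, expected 4")

    seam0 = set(int(p) for p in cut.path)
    seam1 = set(int(p) for p in cut.path_dup)
    a0, a1 = int(cut.path[0]), int(cut.path[-1])        # seam copy 0 ends
    b0, b1 = int(cut.path_dup[0]), int(cut.path_dup[-1])  # seam copy 1 ends

    uv = np.zeros((mesh.n_vertices, 2))
    fixed = []
    for chain in chains:
        pts = mesh.vertices[chain]
        seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
        s = np.concatenate([[0.0], np.cumsum(seg)])
        s = s / s[-1]
        first, last = int(chain[0]), int(chain[-1])
        body = set(int(x) for x in chain)
        if body <= seam0:            # seam copy 0: v = 0, u along the path
            if first != a0:
                s = 1.0 - s
            coords = np.column_stack([s, np.zeros_like(s)])
        elif body <= seam1:          # seam copy 1: v = 1
            if first != b0:
                s = 1.0 - s
            coords = np.column_stack([s, np.ones_like(s)])
        elif {first, last} == {a0, b0}:  # rostral arc: u = 0, v 0 -> 1
            if first != a0:
                s = 1.0 - s
            coords = np.column_stack([np.zeros_like(s), s])
        elif {first, last} == {a1, b1}:  # caudal arc: u = 1
            if first != a1:
                s = 1.0 - s
            coords = np.column_stack([np.ones_like(s), s])
        else:
            raise SolverError("cut boundary chain matches no square side")
        for k, vv in enumerate(chain):
            uv[int(vv)] = coords[k]
            fixed.append(int(vv))
    fixed = np.unique(np.array(fixed, dtype=np.int64))
    lap = _uniform_laplacian(mesh.n_vertices, mesh.edges_unique())
    u = _solve_dirichlet(lap, fixed, uv[fixed, 0])
    v = _solve_dirichlet(lap, fixed, uv[fixed, 1])
    return np.column_stack([u, v])


def harmonic_map(cut: CutSurface, residual_tol: float = 1e-8) -> ParamSurface:
    """Constrained harmonic (u, v) coordinates on the cut surface.

    ``u`` solves the cotangent-Laplace equation on the *uncut* mesh with
    u = 0 / 1 on the two end loops (so both seam copies carry exactly
    matched values), and is transferred to the cut mesh.  ``v`` solves on
    the cut mesh with v = 0 on the original seam copy and v = 1 on the
    duplicate, natural (zero-Neumann) on the end arcs.  If the result has
    flipped parameter triangles, a uniform-weight Tutte embedding with the
    full boundary pinned to the unit square is used instead.
    """
    parent = cut.parent
    loops = parent.boundary_loops()
    # rostral loop = the one containing the first path vertex
    lm_a = int(cut.path[0])
    if lm_a in set(int(x) for x in loops[0]):
        loop_a, loop_b = loops[0], loops[1]
    else:
        loop_a, loop_b = loops[1], loops[0]

    lap_parent = _cotan_laplacian(parent.vertices, parent.faces)
    fixed_u = np.concatenate([loop_a, loop_b])
    vals_u = np.concatenate([np.zeros(len(loop_a)), np.ones(len(loop_b))])
    u_parent = _solve_dirichlet(lap_parent, fixed_u, vals_u)
    res_u = _interior_residual(lap_parent, u_parent, fixed_u)

    mesh = cut.mesh
    u = np.concatenate([u_parent, u_parent[cut.path]])

    lap_cut = _cotan_laplacian(mesh.vertices, mesh.faces)
    fixed_v = np.concatenate([cut.path, cut.path_dup])
    vals_v = np.concatenate([np.zeros(len(cut.path)), np.ones(len(cut.path_dup))])
    v = _solve_dirichlet(lap_cut, fixed_v, vals_v)
    res_v = _interior_residual(lap_cut, v, fixed_v)
    residual = max(res_u, res_v)
    if not np.isfinite(residual) or residual > residual_tol:
        raise SolverError(f"harmonic solve residual {residual:.2e} above "
                          f"tolerance {residual_tol:.0e}")

    uv = np.column_stack([u, v])
    flips = _count_flips(uv, mesh.faces)
    method = "cotan"
    if flips > 0:
        logger.debug("cotangent map has %d flipped triangles; falling back to Tutte",
                     flips)
        uv = _tutte_rectangle(cut)
        flips = _count_flips(uv, mesh.faces)
        method = "tutte"
        residual = 0.0

    # orientation convention: positive signed parameter areas
    e1 = uv[mesh.faces[:, 1]] - uv[mesh.faces[:, 0]]
    e2 = uv[mesh.faces[:, 2]] - uv[mesh.faces[:, 0]]
    if np.median(e1[:, 0] * e2[:, 1] - e1[:, 1] * e2[:, 0]) < 0:
        uv[:, 1] = 1.0 - uv[:, 1]

    return ParamSurface(cut=cut, uv=uv, method=method, residual=residual,
                        flipped=flips)


# --------------------------------------------------------------------------- #
# grid resampling                                                             #
# --------------------------------------------------------------------------- #
@dataclass
class GridSurface:
    """The surface resampled on a regular conformal (u, v) grid.

    ``points[i, j]`` is the 3-D position (mm) at u = i/(n_u - 1),
    v = j/n_v.  v is periodic: column 0 sits on the seam and there is no
    duplicate closing column.
    """

    points: np.ndarray  # (n_u, n_v, 3)
    subject_id: str | None = None

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=np.float64)
        if self.points.ndim != 3 or self.points.shape[2] != 3:
            raise ValueError("points must be (n_u, n_v, 3)")
        if not np.all(np.isfinite(self.points)):
            raise ValueError("grid contains non-finite coordinates")

    @property
    def dims(self) -> tuple[int, int]:
        return self.points.shape[:2]

    def flat(self) -> np.ndarray:
        return self.points.reshape(-1, 3)

    def transformed(self, rotation=None, translation=None) -> "GridSurface":
        p = self.points.reshape(-1, 3)
        if rotation is not None:
            p = p @ np.asarray(rotation).T
        if translation is not None:
            p = p + np.asarray(translation)
        return GridSurface(p.reshape(self.points.shape), self.subject_id)


def _locate_and_interp(mesh: SurfaceMesh, uv: np.ndarray, finder,
                       uq: np.ndarray, vq: np.ndarray,
                       max_fallback_frac: float) -> np.ndarray:
    """Barycentric interpolation of surface positions at parameter points."""
    idx = finder(uq, vq)
    missing = np.where(idx < 0)[0]
    n_fallback = 0
    if len(missing):
        # retry with a nudge toward the domain centre, then nearest triangle
        for scale in (1e-7, 1e-5):
            still = missing[idx[missing] < 0]
            if not len(still):
                break
            uq2 = uq[still] + scale * (0.5 - uq[still])
            vq2 = vq[still] + scale * (0.5 - vq[still])
            idx[still] = finder(uq2, vq2)
        still = missing[idx[missing] < 0]
        n_fallback = len(still)
        if n_fallback:
            logger.debug("%d grid nodes outside all parameter triangles; "
                         "using nearest triangle", n_fallback)
            from scipy.spatial import cKDTree
            cent = uv[mesh.faces].mean(axis=1)
            _, nearest = cKDTree(cent).query(np.column_stack([uq[still], vq[still]]))
            idx[still] = nearest
    if n_fallback > max_fallback_frac * len(uq):
        raise SolverError(
            f"{n_fallback} of {len(uq)} grid nodes required nearest-triangle "
            "fallback; parameterization unusable"
        )

    f = mesh.faces[idx]
    p0, p1, p2 = uv[f[:, 0]], uv[f[:, 1]], uv[f[:, 2]]
    d = np.column_stack([uq, vq])
    v0 = p1 - p0
    v1 = p2 - p0
    v2 = d - p0
    den = v0[:, 0] * v1[:, 1] - v1[:, 0] * v0[:, 1]
    den = np.where(np.abs(den) < 1e-300, 1e-300, den)
    b1 = (v2[:, 0] * v1[:, 1] - v1[:, 0] * v2[:, 1]) / den
    b2 = (v0[:, 0] * v2[:, 1] - v2[:, 0] * v0[:, 1]) / den
    b1 = np.clip(b1, 0.0, 1.0)
    b2 = np.clip(b2, 0.0, 1.0)
    b0 = np.clip(1.0 - b1 - b2, 0.0, 1.0)
    norm = b0 + b1 + b2
    b0, b1, b2 = b0 / norm, b1 / norm, b2 / norm

    verts = mesh.vertices
    return (b0[:, None] * verts[f[:, 0]]
            + b1[:, None] * verts[f[:, 1]]
            + b2[:, None] * verts[f[:, 2]])


def _arclength_row_coords(mesh: SurfaceMesh, uv: np.ndarray, finder, n_u: int,
                          n_v: int, max_fallback_frac: float) -> np.ndarray:
    """u-coordinates of grid rows at uniform medial-axis arclength.

    The harmonic coordinate compresses or stretches along the tube as the
    conformal modulus varies, so a purely local thickness change would
    shift every subject's iso-u lines globally and break cross-subject
    correspondence.  A pilot sampling at uniform harmonic u measures the
    medial arclength fraction s(u); rows are then placed at u = s^-1 of a
    uniform partition, i.e. at matched positions along the tube.
    """
    n_pilot = max(4 * n_u, 128)
    ui = np.linspace(0.0, 1.0, n_pilot)
    vj = np.arange(n_v) / n_v
    uu, vv = np.meshgrid(ui, vj, indexing="ij")
    eps = 1e-9
    uq = np.clip(uu.ravel(), eps, 1.0 - eps)
    vq = np.clip(vv.ravel(), eps, 1.0 - eps)
    pts = _locate_and_interp(mesh, uv, finder, uq, vq,
                             max_fallback_frac).reshape(n_pilot, n_v, 3)
    # arclength-weighted midpoint of each closed iso-u curve
    seg = np.linalg.norm(np.roll(pts, -1, axis=1) - pts, axis=2)
    w = 0.5 * (seg + np.roll(seg, 1, axis=1))
    mid = (w[..., None] * pts).sum(axis=1) / np.maximum(
        w.sum(axis=1), 1e-300)[:, None]
    s = np.concatenate([[0.0], np.cumsum(np.linalg.norm(np.diff(mid, axis=0),
                                                        axis=1))])
    if s[-1] <= 0:
        return np.linspace(0.0, 1.0, n_u)
    s /= s[-1]
    s = np.maximum.accumulate(s + np.arange(n_pilot) * 1e-15)
    return np.interp(np.linspace(0.0, 1.0, n_u), s, ui)


def _anchor_offsets(ring: np.ndarray, mid: np.ndarray, s: np.ndarray) -> np.ndarray:
    """Circumferential anchor (arclength fraction of v = 0) per grid row.

    The anchor is the point of each iso-u ring in the in-plane direction
    from the medial axis toward the arch apex (the direction from the
    axis-endpoint chord to the mid-axis point), a rigid-motion-equivariant
    convention that does not depend on where the cut seam happens to run.
    Nearly straight tubes (no apex direction) keep the seam anchor.
    """
    n_u, nf, _ = ring.shape
    chord = mid[-1] - mid[0]
    cn = np.linalg.norm(chord)
    apex = mid[n_u // 2] - 0.5 * (mid[0] + mid[-1])
    if cn > 0:
        apex = apex - (apex @ chord) * chord / cn**2
    if np.linalg.norm(apex) < 1e-3 * max(cn, 1.0):
        return np.zeros(n_u)
    up = apex / np.linalg.norm(apex)

    tan = np.zeros_like(mid)
    tan[0] = mid[1] - mid[0]
    tan[-1] = mid[-1] - mid[-2]
    tan[1:-1] = mid[2:] - mid[:-2]
    tan /= np.maximum(np.linalg.norm(tan, axis=1, keepdims=True), 1e-300)

    s0 = np.zeros(n_u)
    for i in range(n_u):
        d = up - (up @ tan[i]) * tan[i]
        dn = np.linalg.norm(d)
        if dn < 1e-9:
            continue
        d /= dn
        e = np.cross(tan[i], d)
        q = ring[i] - mid[i]
        ang = np.arctan2(q @ e, q @ d)
        k = int(np.argmin(np.abs(ang)))
        total = max(s[i, -1], 1e-300)
        # refine: linear zero crossing on the adjacent segment that brackets 0
        a = None
        for cand in (k, (k - 1) % nf):
            a1, a2 = ang[cand], ang[(cand + 1) % nf]
            if a1 == 0.0 or (a1 < 0) != (a2 < 0):
                a = cand
                break
        if a is None:
            s0[i] = s[i, k] / total
            continue
        a1, a2 = ang[a], ang[(a + 1) % nf]
        frac = 0.0 if a1 == a2 else a1 / (a1 - a2)
        seg_len = s[i, a + 1] - s[i, a]
        s0[i] = np.mod((s[i, a] + frac * seg_len) / total, 1.0)
    return s0


def resample_to_grid(param: ParamSurface, dims: tuple[int, int],
                     max_fallback_frac: float = 0.01,
                     row_spacing: str = "arclength") -> GridSurface:
    """Sample the surface at the conformal (u, v) grid by barycentric lookup.

    Grid nodes: n_u rows from u = 0 to u = 1 inclusive, v_j = j/n_v
    excluding v = 1 (the seam at v = 0 and v = 1 is the same circle).
    With ``row_spacing='arclength'`` (default) the rows are placed at
    uniform medial-axis arclength fractions, so corresponding rows of
    different subjects sit at matched positions along the tube;
    ``'harmonic'`` uses uniform harmonic u instead.  Nodes that fall in
    numerical gaps between parameter triangles use a nearest-triangle
    fallback; more than ``max_fallback_frac`` of them is an error.
    """
    n_u, n_v = dims
    mesh = param.cut.mesh
    uv = param.uv
    tri = Triangulation(uv[:, 0], uv[:, 1], mesh.faces)
    finder = TrapezoidMapTriFinder(tri)

    eps = 1e-9
    if row_spacing == "arclength":
        ui = _arclength_row_coords(mesh, uv, finder, n_u, n_v, max_fallback_frac)
        # second pilot: uniform circumferential arclength within each row,
        # anchored at an intrinsic direction rather than the cut seam (the
        # shortest-path seam route jitters with shape noise, which would
        # rotate the whole v labeling from subject to subject)
        over = 8
        nf = over * n_v
        vf = np.arange(nf) / nf
        uu, vv = np.meshgrid(ui, vf, indexing="ij")
        ring = _locate_and_interp(
            mesh, uv, finder,
            np.clip(uu.ravel(), eps, 1.0 - eps),
            np.clip(vv.ravel(), eps, 1.0 - eps),
            max_fallback_frac,
        ).reshape(n_u, nf, 3)
        seg = np.linalg.norm(np.roll(ring, -1, axis=1) - ring, axis=2)
        s = np.concatenate([np.zeros((n_u, 1)), np.cumsum(seg, axis=1)], axis=1)
        w = 0.5 * (seg + np.roll(seg, 1, axis=1))
        mid = (w[..., None] * ring).sum(axis=1) / np.maximum(
            w.sum(axis=1), 1e-300)[:, None]
        s0 = _anchor_offsets(ring, mid, s)
        vj = np.empty((n_u, n_v))
        vgrid = np.concatenate([vf, [1.0]])
        step = np.arange(n_v) / n_v
        for i in range(n_u):
            total = max(s[i, -1], 1e-300)
            si = np.maximum.accumulate(s[i] / total + np.arange(nf + 1) * 1e-15)
            targets = np.mod(s0[i] + step, 1.0)
            vj[i] = np.interp(targets, si, vgrid)
        uu = np.repeat(ui, n_v)
        vv = vj.ravel()
    elif row_spacing == "harmonic":
        ui = np.linspace(0.0, 1.0, n_u)
        uu, vv = np.meshgrid(ui, np.arange(n_v) / n_v, indexing="ij")
        uu, vv = uu.ravel(), vv.ravel()
    else:
        raise ValueError(f"unknown row_spacing {row_spacing!r}")
    # nudge off the exact domain boundary where point location is ambiguous
    uq = np.clip(uu, eps, 1.0 - eps)
    vq = np.clip(vv, eps, 1.0 - eps)
    pts = _locate_and_interp(mesh, uv, finder, uq, vq, max_fallback_frac)
    return GridSurface(pts.reshape(n_u, n_v, 3), subject_id=mesh.subject_id)


def parameterize_mesh(mesh: SurfaceMesh, grid_dims: tuple[int, int]) -> GridSurface:
    """Full parameterization of one subject: landmarks -> cut -> harmonic -> grid."""
    mesh.validate_cylinder()
    landmarks = detect_landmarks(mesh)
    cut = cut_surface(mesh, landmarks)
    param = harmonic_map(cut)
    return resample_to_grid(param, grid_dims)


# --------------------------------------------------------------------------- #
# template construction                                                       #
# --------------------------------------------------------------------------- #
def rigid_align(source: np.ndarray, target: np.ndarray) -> np.ndarray:
    """Rigidly align point set ``source`` to ``target`` (Kabsch, no scaling)."""
    sc = source.mean(axis=0)
    tc = target.mean(axis=0)
    h = (source - sc).T @ (target - tc)
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    r = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    return (source - sc) @ r.T + tc


def make_template(grids: list[GridSurface], n_iter: int = 3) -> GridSurface:
    """Vertex-wise mean grid surface after generalized rigid alignment.

    Grids (already in correspondence through the shared conformal grid)
    are rigidly aligned to the evolving mean; no scaling, so genuine size
    differences survive in the template-relative Jacobians.
    """
    dims = grids[0].dims
    if any(g.dims != dims for g in grids):
        raise ValueError("all grids must share the same dimensions")
    pts = [g.flat() for g in grids]
    mean = pts[0]
    for _ in range(n_iter):
        aligned = [rigid_align(p, mean) for p in pts]
        mean = np.mean(aligned, axis=0)
    n_u, n_v = dims
    return GridSurface(mean.reshape(n_u, n_v, 3), subject_id="template")
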