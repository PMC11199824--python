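"""Triangle surface meshes with cylinder topology.

The corpus callosum is modeled as a surface topologically equivalent to a
cylinder: a single connected, orientable triangle mesh with exactly two open
boundary loops (the rostral and caudal ends).  This module provides the mesh
container used throughout the package plus the topology queries (boundary
loops, Euler characteristic) the parameterization stage relies on.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import trimesh


class TopologyError(ValueError):
    """Raised when a mesh does not have the expected (cylinder) topology."""


class GeometryError(ValueError):
    """Raised for degenerate or self-intersecting geometry."""


@dataclass
class SurfaceMesh:
    """A triangulated surface of one subject.

    Parameters
    ----------
    vertices : (V, 3) float array, millimetres.
    faces : (F, 3) int array of oriented vertex-index triples.
    subject_id : optional label carried through the pipeline.
    """

    vertices: np.ndarray
    faces: np.ndarray
    subject_id: str | None = None
    _edge_cache: dict = field(default_factory=dict, repr=False, compare=False)

    def __post_init__(self) -> None:
        self.vertices = np.ascontiguousarray(self.vertices, dtype=np.float64)
        self.faces = np.ascontiguousarray(self.faces, dtype=np.int64)
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 3:
            raise ValueError("vertices must be (V, 3)")
        if self.faces.ndim != 2 or self.faces.shape[1] != 3:
            raise ValueError("faces must be (F, 3)")
        if self.faces.size and self.faces.max() >= len(self.vertices):
            raise ValueError("face index out of range")

    # ------------------------------------------------------------------ #
    # topology                                                           #
    # ------------------------------------------------------------------ #
    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def n_faces(self) -> int:
        return len(self.faces)

    def edges_unique(self) -> np.ndarray:
        """Sorted unique undirected edges, shape (E, 2)."""
        if "unique" not in self._edge_cache:
            e = np.sort(self.faces[:, [0, 1, 1, 2, 2, 0]].reshape(-1, 2), axis=1)
            self._edge_cache["unique"], self._edge_cache["counts"] = np.unique(
                e, axis=0, return_counts=True
            )
        return self._edge_cache["unique"]

    def boundary_edges(self) -> np.ndarray:
        """Undirected edges incident to exactly one face."""
        uniq = self.edges_unique()
        return uniq[self._edge_cache["counts"] == 1]

    def euler_characteristic(self) -> int:
        return self.n_vertices - len(self.edges_unique()) + self.n_faces

    def boundary_loops(self) -> list[np.ndarray]:
        """Closed boundary loops as ordered vertex-index arrays.

        Loops are returned sorted by their smallest vertex index so the
        ordering is reproducible across runs.
        """
        be = self.boundary_edges()
        if len(be) == 0:
            return []
        adj: dict[int, list[int]] = {}
        for a, b in be:
            adj.setdefault(int(a), []).append(int(b))
            adj.setdefault(int(b), []).append(int(a))
        for v, nbrs in adj.items():
            if len(nbrs) != 2:
                raise TopologyError(
                    f"boundary vertex {v} has {len(nbrs)} boundary edges; "
                    "mesh is not manifold along its boundary"
                )
        loops = []
        seen: set[int] = set()
        for start in sorted(adj):
            if start in seen:
                continue
            loop = [start]
            seen.add(start)
            prev, cur = start, adj[start][0]
            while cur != start:
                loop.append(cur)
                seen.add(cur)
                nxt = adj[cur][0] if adj[cur][0] != prev else adj[cur][1]
                prev, cur = cur, nxt
            loops.append(np.array(loop, dtype=np.int64))
        loops.sort(key=lambda lp: int(lp.min()))
        return loops

    def validate_cylinder(self) -> None:
        """Check connectedness, two boundary loops and Euler characteristic 0."""
        loops = self.boundary_loops()
        if len(loops) != 2:
            raise TopologyError(
                f"expected 2 boundary loops (cylinder topology), found {len(loops)}"
            )
        chi = self.euler_characteristic()
        if chi != 0:
            raise TopologyError(f"Euler characteristic {chi} != 0 (not a cylinder)")

    # ------------------------------------------------------------------ #
    # geometry                                                           #
    # ------------------------------------------------------------------ #
    def face_areas(self) -> np.ndarray:
        v = self.vertices
        f = self.faces
        cr = np.cross(v[f[:, 1]] - v[f[:, 0]], v[f[:, 2]] - v[f[:, 0]])
        return 0.5 * np.linalg.norm(cr, axis=1)

    def transformed(self, rotation: np.ndarray | None = None,
                    translation: np.ndarray | None = None) -> "SurfaceMesh":
        """Return a rigidly moved copy (same connectivity)."""
        v = self.vertices
        if rotation is not None:
            v = v @ np.asarray(rotation).T
        if translation is not None:
            v = v + np.asarray(translation)
        return SurfaceMesh(v, self.faces.copy(), subject_id=self.subject_id)

    def to_trimesh(self) -> trimesh.Trimesh:
        return trimesh.Trimesh(vertices=self.vertices, faces=self.faces,
                               process=False)
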