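"""Synthetic cortical surface substrate.

A shared symmetric triangular mesh stands in for a cross-hemispheric
registration template: every per-vertex map (left or right hemisphere) lives
on the same vertex set, so vertex-wise left/right comparison is direct.  The
mesh is an icosphere rescaled to a configurable hemispheric surface area so
that cluster sizes are meaningful in mm².
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import trimesh
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components, dijkstra


class MeshError(ValueError):
    """Invalid mesh construction parameters or inconsistent mesh state."""


@dataclass(frozen=True)
class SurfaceMesh:
    """Triangular mesh with per-vertex areas.

    Attributes
    ----------
    vertex_coords : (V, 3) float array, mm
    triangles : (T, 3) int array, vertex indices
    vertex_area : (V,) float array, mm²; one third of the summed area of the
        triangles incident to each vertex, so vertex areas partition the
        total surface area exactly.
    """

    vertex_coords: np.ndarray
    triangles: np.ndarray
    vertex_area: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        coords = np.ascontiguousarray(self.vertex_coords, dtype=float)
        tris = np.ascontiguousarray(self.triangles, dtype=np.int64)
        if tris.ndim != 2 or tris.shape[1] != 3:
            raise MeshError("triangles must be a (T, 3) integer array")
        if tris.min() < 0 or tris.max() >= len(coords):
            raise MeshError("triangle indices out of range")
        object.__setattr__(self, "vertex_coords", coords)
        object.__setattr__(self, "triangles", tris)
        object.__setattr__(self, "vertex_area", _vertex_areas(coords, tris))
        if np.any(self.vertex_area <= 0):
            raise MeshError("every vertex must carry positive area")

    @property
    def n_vertices(self) -> int:
        return len(self.vertex_coords)

    @property
    def total_area(self) -> float:
        return float(self.vertex_area.sum())

    def triangle_areas(self) -> np.ndarray:
        return _triangle_areas(self.vertex_coords, self.triangles)

    def edges(self) -> np.ndarray:
        """Unique undirected edges as a (E, 2) array, i < j."""
        t = self.triangles
        e = np.vstack([t[:, [0, 1]], t[:, [1, 2]], t[:, [2, 0]]])
        e.sort(axis=1)
        return np.unique(e, axis=0)

    def adjacency(self) -> coo_matrix:
        """Sparse symmetric vertex adjacency (edge-connected)."""
        e = self.edges()
        i = np.concatenate([e[:, 0], e[:, 1]])
        j = np.concatenate([e[:, 1], e[:, 0]])
        return coo_matrix(
            (np.ones(len(i)), (i, j)), shape=(self.n_vertices, self.n_vertices)
        )

    def edge_length_graph(self) -> coo_matrix:
        """Adjacency weighted by Euclidean edge length (mm), for geodesics."""
        e = self.edges()
        w = np.linalg.norm(
            self.vertex_coords[e[:, 0]] - self.vertex_coords[e[:, 1]], axis=1
        )
        i = np.concatenate([e[:, 0], e[:, 1]])
        j = np.concatenate([e[:, 1], e[:, 0]])
        return coo_matrix(
            (np.concatenate([w, w]), (i, j)),
            shape=(self.n_vertices, self.n_vertices),
        )

    def is_connected(self) -> bool:
        n, _ = connected_components(self.adjacency(), directed=False)
        return n == 1

    def geodesic_from(self, sources: np.ndarray) -> np.ndarray:
        """Edge-graph shortest-path distance (mm) from each source vertex.

        Returns an (S, V) matrix.  A graph geodesic is an upper bound on the
        exact polyhedral geodesic; on fine meshes the discrepancy is small.
        """
        return dijkstra(
            self.edge_length_graph().tocsr(), directed=False, indices=sources
        )


def _triangle_areas(coords: np.ndarray, tris: np.ndarray) -> np.ndarray:
    a = coords[tris[:, 1]] - coords[tris[:, 0]]
    b = coords[tris[:, 2]] - coords[tris[:, 0]]
    return 0.5 * np.linalg.norm(np.cross(a, b), axis=1)


def _vertex_areas(coords: np.ndarray, tris: np.ndarray) -> np.ndarray:
    tri_area = _triangle_areas(coords, tris)
    va = np.zeros(len(coords))
    np.add.at(va, tris.ravel(), np.repeat(tri_area / 3.0, 3))
    return va


def build_mesh(subdivision_level: int = 4, total_area: float = 9.0e4) -> SurfaceMesh:
    """Build an icosphere mesh rescaled to a target total surface area.

    Parameters
    ----------
    subdivision_level : icosahedron subdivision depth; vertex count is
        ``10 * 4**level + 2`` (level 4 → 2562 vertices).
    total_area : target summed triangle area in mm².  The default, 9×10⁴ mm²,
        is roughly one human cortical hemisphere.
    """
    if subdivision_level < 1:
        raise MeshError("subdivision_level must be >= 1")
    if not np.isfinite(total_area) or total_area <= 0:
        raise MeshError("total_area must be positive")
    ico = trimesh.creation.icosphere(subdivisions=subdivision_level, radius=1.0)
    coords = np.asarray(ico.vertices, dtype=float)
    tris = np.asarray(ico.faces, dtype=np.int64)
    raw = _triangle_areas(coords, tris).sum()
    coords = coords * np.sqrt(total_area / raw)
    return SurfaceMesh(coords, tris)


def write_ply(mesh: SurfaceMesh, path) -> None:
    """Write the mesh as ASCII PLY."""
    tm = trimesh.Trimesh(
        vertices=mesh.vertex_coords, faces=mesh.triangles, process=False
    )
    with open(path, "wb") as fh:
        fh.write(trimesh.exchange.ply.export_ply(tm, encoding="ascii"))


def read_ply(path) -> SurfaceMesh:
    tm = trimesh.load(path, file_type="ply", process=False)
    return SurfaceMesh(np.asarray(tm.vertices), np.asarray(tm.faces))
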