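"""Triangulated surface meshes used as cortical-surface stand-ins.

The average cortical surface is emulated by an icosphere; small rectangular
patches (seed/target regions for tractography) are open triangulated grids.
Both are represented by :class:`SurfaceMesh`, which carries the vertex
adjacency structure needed for surface smoothing, cluster extraction and
graph-geodesic distances.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
from scipy.sparse.csgraph import dijkstra

__all__ = ["SurfaceMesh", "make_surface_mesh", "make_planar_patch"]

MAX_SUBDIVISIONS = 6


@dataclass
class SurfaceMesh:
    """A triangulated surface with symmetric vertex adjacency.

    Parameters
    ----------
    vertices : (V, 3) float array
        Vertex coordinates in millimetres.
    faces : (F, 3) int array
        Triangles as vertex-index triples.
    """

    vertices: np.ndarray
    faces: np.ndarray
    neighbor_lists: list[np.ndarray] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=float)
        self.faces = np.asarray(self.faces, dtype=np.intp)
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 3:
            raise ValueError("vertices must be (V, 3)")
        if self.faces.ndim != 2 or self.faces.shape[1] != 3:
            raise ValueError("faces must be (F, 3)")
        if np.any((self.faces[:, [0, 1, 2]] == self.faces[:, [1, 2, 0]])):
            raise ValueError("degenerate face (repeated vertex index)")
        self._build_adjacency()

    def _build_adjacency(self) -> None:
        f = self.faces
        edges = np.concatenate([f[:, [0, 1]], f[:, [1, 2]], f[:, [2, 0]]])
        i = np.concatenate([edges[:, 0], edges[:, 1]])
        j = np.concatenate([edges[:, 1], edges[:, 0]])
        data = np.ones(i.size, dtype=np.int8)
        a = sp.coo_matrix((data, (i, j)), shape=(self.n_vertices, self.n_vertices))
        a = (a.tocsr() > 0).astype(np.int8)
        self._adjacency = a
        self.neighbor_lists = [a.indices[a.indptr[k]: a.indptr[k + 1]] for k in range(self.n_vertices)]

    # -- basic properties -------------------------------------------------
    @property
    def n_vertices(self) -> int:
        return int(self.vertices.shape[0])

    @property
    def n_faces(self) -> int:
        return int(self.faces.shape[0])

    @property
    def n_edges(self) -> int:
        return int(self._adjacency.nnz // 2)

    @property
    def adjacency(self) -> sp.csr_matrix:
        """Symmetric binary vertex adjacency (CSR)."""
        return self._adjacency

    def euler_characteristic(self) -> int:
        return self.n_vertices - self.n_edges + self.n_faces

    # -- geometry ---------------------------------------------------------
    def edge_length_graph(self) -> sp.csr_matrix:
        """Adjacency weighted by Euclidean edge lengths (mm)."""
        a = self._adjacency.tocoo()
        w = np.linalg.norm(self.vertices[a.row] - self.vertices[a.col], axis=1)
        return sp.csr_matrix((w, (a.row, a.col)), shape=a.shape)

    def geodesic_distances(self, sources: np.ndarray | list[int]) -> np.ndarray:
        """Graph-geodesic distances (mm) from ``sources`` to every vertex.

        Shortest paths along mesh edges approximate true geodesics; on the
        icosphere stand-in the approximation error is a few percent, adequate
        for smoothing-kernel calibration.
        """
        d = dijkstra(self.edge_length_graph(), indices=np.atleast_1d(sources))
        return d if np.ndim(sources) else d[0]

    def vertex_areas(self) -> np.ndarray:
        """Barycentric vertex areas (mm^2): one third of incident face areas."""
        v = self.vertices
        f = self.faces
        cross = np.cross(v[f[:, 1]] - v[f[:, 0]], v[f[:, 2]] - v[f[:, 0]])
        fa = 0.5 * np.linalg.norm(cross, axis=1)
        areas = np.zeros(self.n_vertices)
        for k in range(3):
            np.add.at(areas, f[:, k], fa / 3.0)
        return areas

    def vertex_normals(self) -> np.ndarray:
        """Area-weighted vertex normals (unit length)."""
        v = self.vertices
        f = self.faces
        fn = np.cross(v[f[:, 1]] - v[f[:, 0]], v[f[:, 2]] - v[f[:, 0]])
        n = np.zeros_like(v)
        for k in range(3):
            np.add.at(n, f[:, k], fn)
        norm = np.linalg.norm(n, axis=1, keepdims=True)
        norm[norm == 0] = 1.0
        return n / norm


def make_surface_mesh(subdivisions: int = 2, radius_mm: float = 50.0) -> SurfaceMesh:
    """Icosphere stand-in for an average cortical hemisphere surface.

    Vertex count is ``10 * 4**subdivisions + 2``; radius defaults to 50 mm
    (the scale of a human hemisphere).
    """
    import trimesh

    if subdivisions < 0:
        raise ValueError("subdivisions must be non-negative")
    if subdivisions > MAX_SUBDIVISIONS:
        raise ResourceWarning(
            f"subdivisions={subdivisions} exceeds the supported maximum "
            f"{MAX_SUBDIVISIONS} (41k vertices)"
        )
    ico = trimesh.creation.icosphere(subdivisions=subdivisions, radius=radius_mm)
    return SurfaceMesh(np.asarray(ico.vertices), np.asarray(ico.faces))


def make_planar_patch(
    n_u: int,
    n_v: int,
    spacing_mm: float = 1.0,
    origin: np.ndarray | tuple = (0.0, 0.0, 0.0),
    axis_u: np.ndarray | tuple = (0.0, 1.0, 0.0),
    axis_v: np.ndarray | tuple = (0.0, 0.0, 1.0),
) -> SurfaceMesh:
    """Open rectangular surface patch (``n_u x n_v`` grid, triangulated).

    Used for the seed/target patches of the tractography phantoms; the grid
    graph supports the same smoothing machinery as the closed icosphere.
    """
    if n_u < 2 or n_v < 2:
        raise ValueError("patch needs at least 2 vertices per side")
    origin = np.asarray(origin, float)
    eu = np.asarray(axis_u, float) * spacing_mm
    ev = np.asarray(axis_v, float) * spacing_mm
    uu, vv = np.meshgrid(np.arange(n_u), np.arange(n_v), indexing="ij")
    verts = origin + uu[..., None] * eu + vv[..., None] * ev
    verts = verts.reshape(-1, 3)

    idx = np.arange(n_u * n_v).reshape(n_u, n_v)
    a, b = idx[:-1, :-1].ravel(), idx[1:, :-1].ravel()
    c, d = idx[:-1, 1:].ravel(), idx[1:, 1:].ravel()
    faces = np.concatenate([np.stack([a, b, d], 1), np.stack([a, d, c], 1)])
    return SurfaceMesh(verts, faces)
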