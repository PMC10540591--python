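"""Triangulated cortical surface meshes and their graph structure.

The gray--white interface is represented as a closed triangulated mesh in
world millimetre coordinates.  All manifold operations downstream (smoothing
along the cortical sheet, geodesic patch construction) run on the vertex
adjacency graph weighted by Euclidean edge length, so the mesh itself only
needs vertices, faces, and a way to build that graph.

A deterministic icosphere generator is included as the synthetic stand-in
for a real FreeSurfer-style surface: it produces ``10 * 4**k + 2`` vertices
at subdivision level ``k`` with reproducible vertex ordering.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp

__all__ = [
    "CorticalMesh",
    "make_synthetic_mesh",
    "vertex_adjacency",
]


@dataclass(frozen=True)
class CorticalMesh:
    """A triangulated surface in world mm coordinates.

    Parameters
    ----------
    vertices : (V, 3) float array
        Vertex coordinates in millimetres (world space).
    faces : (F, 3) int array
        Triangle vertex indices.
    """

    vertices: np.ndarray
    faces: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.vertices, dtype=np.float64)
        f = np.asarray(self.faces, dtype=np.int64)
        if v.ndim != 2 or v.shape[1] != 3:
            raise ValueError("vertices must be (V, 3)")
        if f.ndim != 2 or f.shape[1] != 3:
            raise ValueError("faces must be (F, 3)")
        if f.size and (f.min() < 0 or f.max() >= len(v)):
            raise ValueError("face indices out of range")
        object.__setattr__(self, "vertices", v)
        object.__setattr__(self, "faces", f)

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def n_faces(self) -> int:
        return len(self.faces)

    @property
    def n_edges(self) -> int:
        """Number of undirected edges."""
        return vertex_adjacency(self).nnz // 2

    def euler_characteristic(self) -> int:
        return self.n_vertices - self.n_edges + self.n_faces


def vertex_adjacency(mesh: CorticalMesh) -> sp.csr_matrix:
    """Undirected vertex adjacency with Euclidean edge lengths (mm).

    Returns a symmetric sparse CSR matrix whose entry (i, j) is the length
    of edge i--j.  For a closed triangular mesh the number of undirected
    edges equals ``3 F / 2``.

    Raises
    ------
    ValueError
        If the mesh contains duplicate (non-manifold) faces or a
        zero-length edge.
    """
    f = mesh.faces
    canon = np.sort(f, axis=1)
    if len(np.unique(canon, axis=0)) != len(canon):
        raise ValueError("mesh has duplicate faces (non-manifold)")

    i = np.concatenate([f[:, 0], f[:, 1], f[:, 2]])
    j = np.concatenate([f[:, 1], f[:, 2], f[:, 0]])
    # symmetrise and deduplicate edges
    ij = np.unique(np.sort(np.stack([i, j], axis=1), axis=1), axis=0)
    d = np.linalg.norm(mesh.vertices[ij[:, 0]] - mesh.vertices[ij[:, 1]], axis=1)
    if np.any(d == 0.0):
        raise ValueError("mesh has zero-length edges")
    rows = np.concatenate([ij[:, 0], ij[:, 1]])
    cols = np.concatenate([ij[:, 1], ij[:, 0]])
    w = np.concatenate([d, d])
    n = mesh.n_vertices
    return sp.csr_matrix((w, (rows, cols)), shape=(n, n))


def _icosahedron() -> tuple[np.ndarray, np.ndarray]:
    """Unit icosahedron with a fixed, documented vertex order."""
    phi = (1.0 + np.sqrt(5.0)) / 2.0
    verts = np.array(
        [
            [-1, phi, 0], [1, phi, 0], [-1, -phi, 0], [1, -phi, 0],
            [0, -1, phi], [0, 1, phi], [0, -1, -phi], [0, 1, -phi],
            [phi, 0, -1], [phi, 0, 1], [-phi, 0, -1], [-phi, 0, 1],
        ],
        dtype=np.float64,
    )
    verts /= np.linalg.norm(verts[0])
    faces = np.array(
        [
            [0, 11, 5], [0, 5, 1], [0, 1, 7], [0, 7, 10], [0, 10, 11],
            [1, 5, 9], [5, 11, 4], [11, 10, 2], [10, 7, 6], [7, 1, 8],
            [3, 9, 4], [3, 4, 2], [3, 2, 6], [3, 6, 8], [3, 8, 9],
            [4, 9, 5], [2, 4, 11], [6, 2, 10], [8, 6, 7], [9, 8, 1],
        ],
        dtype=np.int64,
    )
    return verts, faces


def make_synthetic_mesh(subdivision_level: int = 3, radius_mm: float = 30.0) -> CorticalMesh:
    """Closed icosphere mesh as a synthetic gray--white surface.

    Starts from a unit icosahedron and applies ``subdivision_level`` rounds
    of midpoint (Loop-style 1-to-4) subdivision, projecting every vertex
    back to the sphere of radius ``radius_mm``.  Vertex ordering is
    deterministic: original vertices first, then edge midpoints in the
    order edges are first encountered while scanning faces.

    Parameters
    ----------
    subdivision_level : int
        ``k >= 0``; the result has ``10 * 4**k + 2`` vertices and
        ``20 * 4**k`` faces.
    radius_mm : float
        Sphere radius in millimetres; must be positive.
    """
    if subdivision_level < 0:
        raise ValueError("subdivision_level must be >= 0")
    if radius_mm <= 0:
        raise ValueError("radius_mm must be positive")

    verts, faces = _icosahedron()
    for _ in range(subdivision_level):
        verts, faces = _subdivide(verts, faces)
    verts = verts / np.linalg.norm(verts, axis=1, keepdims=True) * radius_mm
    return CorticalMesh(vertices=verts, faces=faces)


def _subdivide(verts: np.ndarray, faces: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    midpoint: dict[tuple[int, int], int] = {}
    new_verts = [verts]
    next_id = len(verts)

    def mid(a: int, b: int) -> int:
        nonlocal next_id
        key = (a, b) if a < b else (b, a)
        if key not in midpoint:
            m = (verts[a] + verts[b]) / 2.0
            m /= np.linalg.norm(m)
            new_verts.append(m[None, :])
            midpoint[key] = next_id
            next_id += 1
        return midpoint[key]

    new_faces = np.empty((4 * len(faces), 3), dtype=np.int64)
    for fi, (a, b, c) in enumerate(faces):
        ab, bc, ca = mid(a, b), mid(b, c), mid(c, a)
        new_faces[4 * fi: 4 * fi + 4] = [
            [a, ab, ca], [b, bc, ab], [c, ca, bc], [ab, bc, ca],
        ]
    return np.vstack(new_verts), new_faces
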