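"""Triangle surface meshes for regions of interest.

A :class:`SurfaceMesh` carries vertex coordinates, a triangulation, and a
canonical per-vertex axis coordinate in [0, 1] describing where each vertex
sits along the dominant anatomical axis of the region (e.g. the
dorsomedial-to-ventrolateral axis of the precentral gyrus). Synthetic meshes
are rectangular grid strips; real meshes can be ingested from the plain-text
format written by :func:`write_mesh`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import sparse
from scipy.sparse.csgraph import connected_components


@dataclass
class SurfaceMesh:
    """A triangulated surface with a canonical gradient axis.

    Parameters
    ----------
    vertices : (V, 3) float array
        Vertex coordinates, arbitrary units.
    triangles : (F, 3) int array
        Vertex-index triples.
    axis_coordinate : (V,) float array
        Canonical position of each vertex along the region's dominant
        axis, spanning [0, 1].
    """

    vertices: np.ndarray
    triangles: np.ndarray
    axis_coordinate: np.ndarray
    _adjacency: sparse.csr_matrix | None = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=float)
        self.triangles = np.asarray(self.triangles, dtype=np.int64)
        self.axis_coordinate = np.asarray(self.axis_coordinate, dtype=float)
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 3:
            raise ValueError("vertices must be an (V, 3) array")
        if self.triangles.ndim != 2 or self.triangles.shape[1] != 3:
            raise ValueError("triangles must be an (F, 3) array")
        v = self.n_vertices
        if self.axis_coordinate.shape != (v,):
            raise ValueError("axis_coordinate must have one entry per vertex")
        if self.triangles.size and (self.triangles.min() < 0 or self.triangles.max() >= v):
            raise ValueError("triangle indices out of range")

    @property
    def n_vertices(self) -> int:
        return self.vertices.shape[0]

    def adjacency(self) -> sparse.csr_matrix:
        """Boolean vertex adjacency from shared triangle edges (cached)."""
        if self._adjacency is None:
            v = self.n_vertices
            tri = self.triangles
            rows = np.concatenate([tri[:, 0], tri[:, 1], tri[:, 2]])
            cols = np.concatenate([tri[:, 1], tri[:, 2], tri[:, 0]])
            data = np.ones(rows.size, dtype=bool)
            a = sparse.coo_matrix((data, (rows, cols)), shape=(v, v))
            a = ((a + a.T) > 0).tocsr()
            a.setdiag(False)
            a.eliminate_zeros()
            self._adjacency = a
        return self._adjacency

    def edges(self) -> np.ndarray:
        """Unique undirected edges as an (E, 2) array with u < v."""
        a = sparse.triu(self.adjacency(), k=1).tocoo()
        return np.column_stack([a.row, a.col])

    def is_connected(self) -> bool:
        n_comp, _ = connected_components(self.adjacency(), directed=False)
        return n_comp == 1


def make_mesh(n_axis: int, n_width: int) -> SurfaceMesh:
    """Build a rectangular grid-strip mesh with a known gradient axis.

    Vertices form an ``n_axis`` x ``n_width`` grid; each grid quad is split
    into two triangles.  ``axis_coordinate`` of a vertex in grid column ``i``
    is ``i / (n_axis - 1)``, so the mesh carries its own ground-truth
    gradient.  A single-row strip (``n_width == 1``) is triangulated with
    degenerate collinear triangles so that vertex adjacency stays connected.

    Raises
    ------
    ValueError
        If ``n_axis < 2``, ``n_width < 1`` or fewer than 3 vertices total.
    """
    if n_axis < 2:
        raise ValueError(f"n_axis must be >= 2 to span a gradient axis, got {n_axis}")
    if n_width < 1:
        raise ValueError(f"n_width must be >= 1, got {n_width}")
    if n_axis * n_width < 3:
        raise ValueError("mesh needs at least 3 vertices to form a triangle")

    ii, ww = np.meshgrid(np.arange(n_axis), np.arange(n_width), indexing="ij")
    verts = np.column_stack(
        [ii.ravel() / (n_axis - 1), ww.ravel().astype(float), np.zeros(n_axis * n_width)]
    )
    axis = verts[:, 0].copy()

    def vid(i: int, w: int) -> int:
        return i * n_width + w

    tris: list[tuple[int, int, int]] = []
    if n_width == 1:
        for i in range(n_axis - 2):
            tris.append((vid(i, 0), vid(i + 1, 0), vid(i + 2, 0)))
    else:
        for i in range(n_axis - 1):
            for w in range(n_width - 1):
                a, b = vid(i, w), vid(i + 1, w)
                c, d = vid(i, w + 1), vid(i + 1, w + 1)
                tris.append((a, b, c))
                tris.append((b, d, c))
    return SurfaceMesh(verts, np.asarray(tris, dtype=np.int64), axis)


_MAGIC = "#connectopath-mesh v1"


def write_mesh(mesh: SurfaceMesh, path: str | Path) -> None:
    """Write a mesh in the package's plain-text triangle format.

    Format: a magic comment line; a count line ``V F``; V lines of
    ``x y z axis_coordinate``; F lines of ``i j k`` triangle indices.
    """
    path = Path(path)
    with path.open("w") as fh:
        fh.write(_MAGIC + "\n")
        fh.write(f"{mesh.n_vertices} {mesh.triangles.shape[0]}\n")
        for (x, y, z), a in zip(mesh.vertices, mesh.axis_coordinate):
            fh.write(f"{x:.10g} {y:.10g} {z:.10g} {a:.10g}\n")
        for i, j, k in mesh.triangles:
            fh.write(f"{i} {j} {k}\n")


def read_mesh(path: str | Path) -> SurfaceMesh:
    """Read a mesh written by :func:`write_mesh`."""
    path = Path(path)
    with path.open() as fh:
        magic = fh.readline().strip()
        if magic != _MAGIC:
            raise ValueError(f"{path} is not a connectopath mesh file")
        nv, nf = (int(tok) for tok in fh.readline().split())
        verts = np.empty((nv, 3))
        axis = np.empty(nv)
        for r in range(nv):
            x, y, z, a = (float(tok) for tok in fh.readline().split())
            verts[r] = (x, y, z)
            axis[r] = a
        tris = np.empty((nf, 3), dtype=np.int64)
        for r in range(nf):
            tris[r] = [int(tok) for tok in fh.readline().split()]
    return SurfaceMesh(verts, tris, axis)
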