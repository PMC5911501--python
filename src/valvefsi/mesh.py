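"""Simplicial mesh container, per-cell geometry and the shape-quality measure.

The mesh is a flat numpy container: vertex coordinates, cell connectivity
(positively oriented simplices), an integer region tag per cell and named
facet sets (inlet, outlet, wall, interface, closure).  All solver modules
operate on this one structure; file formats live in :mod:`valvefsi.meshio_`.

The cell quality

    Q(K) = ||F||_F^2 / (d * det(F)^(2/d)),

with ``F`` the deformation gradient between the physical cell ``K`` and a
scaled equilateral reference simplex, equals 1 exactly for equilateral cells
and grows without bound as a cell degenerates.  ``Q`` is invariant under
rotation and uniform scaling of the cell, and under the choice of reference
scale; the implementation uses the unit-measure equilateral simplex.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import DegenerateCellError, MeshFormatError

# Region tag convention: 1 = fluid, 2.. = solid subdomains (leaflets).
REGION_FLUID = 1
REGION_LEAFLET_1 = 2
REGION_LEAFLET_2 = 3
REGION_LEAFLET_3 = 4

#: canonical facet-set names
FACET_NAMES = ("inlet", "outlet", "wall", "interface", "closure")


@dataclass
class TaggedMesh:
    """Simplicial mesh with per-cell region tags and named facet sets.

    Parameters
    ----------
    vertices : (nv, dim) float array
        Vertex coordinates (SI meters internally).
    cells : (nc, dim+1) int array
        Simplex connectivity, positively oriented.
    region_tags : (nc,) int array
        ``REGION_FLUID`` for fluid cells, >= 2 for solid (leaflet) cells.
    facet_tags : dict[str, (nf, dim) int array]
        Facets as vertex-index tuples, keyed by role name.
    """

    vertices: np.ndarray
    cells: np.ndarray
    region_tags: np.ndarray
    facet_tags: dict = field(default_factory=dict)
    metadata: dict = field(default_factory=dict)

    # -- basic properties -------------------------------------------------
    @property
    def dim(self) -> int:
        return self.vertices.shape[1]

    @property
    def num_vertices(self) -> int:
        return self.vertices.shape[0]

    @property
    def num_cells(self) -> int:
        return self.cells.shape[0]

    def copy(self) -> "TaggedMesh":
        return TaggedMesh(
            self.vertices.copy(),
            self.cells.copy(),
            self.region_tags.copy(),
            {k: v.copy() for k, v in self.facet_tags.items()},
            dict(self.metadata),
        )

    # -- derived connectivity --------------------------------------------
    def facet_to_cells(self) -> dict:
        """Map each facet (sorted vertex tuple) to the list of incident cells."""
        d = self.dim
        out: dict = {}
        cells = self.cells
        for ci in range(cells.shape[0]):
            cell = cells[ci]
            for k in range(d + 1):
                fac = tuple(sorted(np.delete(cell, k)))
                out.setdefault(fac, []).append(ci)
        return out

    def boundary_facets(self) -> np.ndarray:
        """All facets incident to exactly one cell, as an (nf, dim) array."""
        f2c = self.facet_to_cells()
        bnd = [f for f, cs in f2c.items() if len(cs) == 1]
        return np.array(sorted(bnd), dtype=np.int64).reshape(-1, self.dim)

    def tagged_vertices(self, name: str) -> np.ndarray:
        """Sorted unique vertex indices touched by the named facet set."""
        facs = self.facet_tags.get(name)
        if facs is None or len(facs) == 0:
            return np.array([], dtype=np.int64)
        return np.unique(np.asarray(facs))

    def solid_cells(self) -> np.ndarray:
        return np.flatnonzero(self.region_tags != REGION_FLUID)

    def fluid_cells(self) -> np.ndarray:
        return np.flatnonzero(self.region_tags == REGION_FLUID)

    def validate(self) -> None:
        """Raise MeshFormatError on inconsistent connectivity or tags."""
        nv = self.num_vertices
        if self.cells.min(initial=0) < 0 or self.cells.max(initial=-1) >= nv:
            raise MeshFormatError("cell connectivity references unknown vertices")
        if self.region_tags.shape[0] != self.num_cells:
            raise MeshFormatError("region_tags length does not match cell count")
        if np.any(cell_volumes(self.vertices, self.cells) <= 0):
            raise MeshFormatError("mesh contains non-positive-volume cells")
        f2c = self.facet_to_cells()
        for name, facs in self.facet_tags.items():
            for f in np.asarray(facs).reshape(-1, self.dim):
                key = tuple(sorted(f))
                if key not in f2c:
                    raise MeshFormatError(
                        f"tagged facet {key!r} in set {name!r} is not a face of any cell"
                    )


# ---------------------------------------------------------------------------
# per-cell geometry
# ---------------------------------------------------------------------------

def edge_matrices(vertices: np.ndarray, cells: np.ndarray) -> np.ndarray:
    """(nc, dim, dim) arrays of cell edge vectors p_i - p_0 as columns."""
    p = vertices[cells]  # (nc, d+1, d)
    return np.swapaxes(p[:, 1:, :] - p[:, :1, :], 1, 2)


def cell_volumes(vertices: np.ndarray, cells: np.ndarray) -> np.ndarray:
    """Signed simplex measures (positive for correctly oriented cells)."""
    E = edge_matrices(vertices, cells)
    d = vertices.shape[1]
    from math import factorial

    return np.linalg.det(E) / factorial(d)


def orient_cells(vertices: np.ndarray, cells: np.ndarray) -> np.ndarray:
    """Return connectivity with every simplex positively oriented."""
    cells = np.array(cells, dtype=np.int64, copy=True)
    vol = cell_volumes(vertices, cells)
    flip = vol < 0
    cells[flip, 0], cells[flip, 1] = cells[flip, 1], cells[flip, 0].copy()
    return cells


def cell_diameters(mesh: TaggedMesh) -> np.ndarray:
    """Per-cell diameter: the maximal edge length of each simplex."""
    p = mesh.vertices[mesh.cells]  # (nc, d+1, d)
    n = p.shape[1]
    dmax = np.zeros(p.shape[0])
    for i in range(n):
        for j in range(i + 1, n):
            dmax = np.maximum(dmax, np.linalg.norm(p[:, i] - p[:, j], axis=1))
    return dmax


def min_diameter(mesh: TaggedMesh) -> float:
    return float(cell_diameters(mesh).min())


# ---------------------------------------------------------------------------
# quality measure
# ---------------------------------------------------------------------------

def reference_simplex(dim: int) -> np.ndarray:
    """Vertices of the unit-measure equilateral simplex in ``dim`` dimensions."""
    if dim == 2:
        a = (4.0 / np.sqrt(3.0)) ** 0.5  # side length giving area 1
        return np.array([[0.0, 0.0], [a, 0.0], [a / 2.0, a * np.sqrt(3.0) / 2.0]])
    if dim == 3:
        a = (6.0 * np.sqrt(2.0)) ** (1.0 / 3.0)  # edge giving volume 1
        return np.array(
            [
                [0.0, 0.0, 0.0],
                [a, 0.0, 0.0],
                [a / 2.0, a * np.sqrt(3.0) / 2.0, 0.0],
                [a / 2.0, a * np.sqrt(3.0) / 6.0, a * np.sqrt(2.0 / 3.0)],
            ]
        )
    raise ValueError(f"unsupported dimension {dim}")


def _reference_edge_inverse(dim: int) -> np.ndarray:
    ref = reference_simplex(dim)
    V = (ref[1:] - ref[0]).T
    return np.linalg.inv(V)


_REF_INV = {2: _reference_edge_inverse(2), 3: _reference_edge_inverse(3)}


def deformation_gradients(vertices: np.ndarray, cells: np.ndarray) -> np.ndarray:
    """F = E @ Vref^-1 per cell, mapping the equilateral reference onto the cell."""
    d = vertices.shape[1]
    return edge_matrices(vertices, cells) @ _REF_INV[d]


def cell_quality(cell_coords: np.ndarray, dim: int | None = None) -> float:
    """Shape quality Q of one simplex; 1 for equilateral, raises if degenerate."""
    cell_coords = np.asarray(cell_coords, dtype=float)
    d = cell_coords.shape[1] if dim is None else dim
    F = (cell_coords[1:] - cell_coords[0]).T @ _REF_INV[d]
    detF = np.linalg.det(F)
    # relative degeneracy floor: a numerically collinear/coplanar simplex can
    # yield a tiny positive determinant through round-off
    scale = (np.sum(F * F) / d) ** (d / 2.0)
    if detF <= 1e-12 * scale:
        raise DegenerateCellError(
            f"degenerate or inverted simplex (det F = {detF:.3e})"
        )
    return float(np.sum(F * F) / (d * detF ** (2.0 / d)))


def quality_all(vertices: np.ndarray, cells: np.ndarray) -> np.ndarray:
    """Vectorized Q over all cells; inverted cells get Q = +inf."""
    d = vertices.shape[1]
    F = deformation_gradients(vertices, cells)
    detF = np.linalg.det(F)
    num = np.einsum("kij,kij->k", F, F)
    out = np.full(cells.shape[0], np.inf)
    ok = detF > 0
    out[ok] = num[ok] / (d * detF[ok] ** (2.0 / d))
    return out


@dataclass
class QualityReport:
    """Summary of per-cell shape quality for a mesh snapshot."""

    Q_per_cell: np.ndarray
    Q_max: float
    Q_mean: float


def mesh_quality(mesh: TaggedMesh) -> QualityReport:
    q = quality_all(mesh.vertices, mesh.cells)
    return QualityReport(q, float(q.max()), float(q.mean()))
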