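"""Derived valve-dynamics quantities and series output.

* geometric orifice area (GOA): the area of the closure surface not
  occluded by the axis-aligned projection of the leaflet surfaces; zero
  while the valve is closed.
* leaflet rotation angle alpha about a hinge axis and its rate omega.
* lambda2 vortex criterion (middle eigenvalue of S^2 + Omega^2, 3D only).
* von Mises stress of the composite stress field.
* VTU/PVD + CSV trajectory writers.
"""

from __future__ import annotations

import os
import warnings
from dataclasses import dataclass, field

import numpy as np

from .continuum import MaterialConstants, composite_stress, fluid_stress, von_mises
from .errors import ConfigurationError, ValveFsiError
from .mesh import TaggedMesh, cell_volumes
from .meshio_ import write_pvd, write_vtu
from .smoothing import p1_gradients


@dataclass
class TimeSeries:
    """Named, aligned time-series columns (t strictly increasing)."""

    t: list = field(default_factory=list)
    columns: dict = field(default_factory=dict)

    def append(self, t: float, **values):
        if self.t and t <= self.t[-1]:
            raise ValueError("time series times must be strictly increasing")
        self.t.append(t)
        for k, v in values.items():
            self.columns.setdefault(k, [np.nan] * (len(self.t) - 1)).append(v)
        for k in self.columns:
            if len(self.columns[k]) < len(self.t):
                self.columns[k].append(np.nan)

    def as_arrays(self):
        return np.asarray(self.t), {k: np.asarray(v) for k, v in self.columns.items()}

    def to_csv(self, path: str):
        t, cols = self.as_arrays()
        names = ["t"] + sorted(cols)
        data = np.column_stack([t] + [cols[k] for k in sorted(cols)])
        np.savetxt(path, data, delimiter=",", header=",".join(names), comments="")


# ---------------------------------------------------------------------------
# geometric orifice area
# ---------------------------------------------------------------------------

def _facet_measures(mesh, facets):
    coords = mesh.vertices[facets]
    if mesh.dim == 2:
        return np.linalg.norm(coords[:, 1] - coords[:, 0], axis=1)
    return 0.5 * np.linalg.norm(
        np.cross(coords[:, 1] - coords[:, 0], coords[:, 2] - coords[:, 0]), axis=1
    )


def _barycentric_samples(n_per_edge=4):
    """Deterministic interior barycentric sample points of a simplex facet."""
    pts = []
    n = n_per_edge
    for i in range(n):
        for j in range(n - i):
            k = n - 1 - i - j
            pts.append(((i + 1 / 3), (j + 1 / 3), (k + 1 / 3)))
    pts = np.array(pts)
    return pts / pts.sum(axis=1, keepdims=True)


def geometric_orifice_area(
    mesh: TaggedMesh,
    theta: np.ndarray,
    closure_tag: str = "closure",
    leaflet_tags=(2, 3, 4),
    samples_per_facet: int = 10,
) -> float:
    """Orifice area open to flow, by projection along the valve axis.

    Sample points on the closure surface count as occluded when their
    projection along the axis hits any leaflet surface facet.  Cells under
    the closure surface that have been phase-switched to solid occlude
    their facets entirely, so a closed valve reports exactly zero.
    """
    closure = mesh.facet_tags.get(closure_tag)
    if closure is None or len(closure) == 0:
        raise ConfigurationError("mesh has no tagged closure surface")
    closure = np.asarray(closure).reshape(-1, mesh.dim)
    areas = _facet_measures(mesh, closure)

    # closed check: any adjacent cell switched to solid blocks its facet
    f2c = mesh.facet_to_cells()
    open_facet = np.array([
        all(theta[c] > 0.5 for c in f2c[tuple(sorted(f))]) for f in closure
    ])
    if not open_facet.any():
        return 0.0

    axis = {"x": 0, "y": 1, "z": 2}[mesh.metadata.get("axis", "z" if mesh.dim == 3 else "x")]
    other = [a for a in range(mesh.dim) if a != axis]

    # leaflet surface = boundary facets of solid leaflet cells (projected)
    leaf_cells = np.flatnonzero(np.isin(mesh.region_tags, leaflet_tags))
    if len(leaf_cells) == 0:
        return float(areas[open_facet].sum())
    leaf_pts = mesh.vertices[np.unique(mesh.cells[leaf_cells])]

    if mesh.dim == 2:
        # project each leaflet onto the closure line: union of occluded
        # transverse intervals, one per leaflet region
        intervals = []
        for tag in np.unique(mesh.region_tags[leaf_cells]):
            pts = mesh.vertices[np.unique(mesh.cells[mesh.region_tags == tag])]
            intervals.append((pts[:, other[0]].min(), pts[:, other[0]].max()))
        total = 0.0
        n = max(samples_per_facet, 4)
        w = np.linspace(0.5 / n, 1 - 0.5 / n, n)
        for f, a, ok in zip(closure, areas, open_facet):
            if not ok:
                continue
            p0, p1 = mesh.vertices[f]
            samp = p0[other[0]] + w * (p1[other[0]] - p0[other[0]])
            occluded = np.zeros(n, dtype=bool)
            for lo, hi in intervals:
                occluded |= (samp >= lo) & (samp <= hi)
            total += a * (1.0 - occluded.mean())
        return float(total)

    # 3D: point-in-triangle of projected leaflet surface triangles
    leaf_facets = _leaflet_surface_triangles(mesh, leaf_cells)
    tri2d = mesh.vertices[leaf_facets][:, :, other]  # (nf, 3, 2)
    bary = _barycentric_samples(max(2, int(np.sqrt(samples_per_facet))))
    total = 0.0
    for f, a, ok in zip(closure, areas, open_facet):
        if not ok:
            continue
        pts = bary @ mesh.vertices[f][:, other]  # (ns, 2)
        occluded = _points_in_any_triangle(pts, tri2d)
        total += a * (1.0 - occluded.mean())
    return float(total)


def _leaflet_surface_triangles(mesh, leaf_cells):
    leaf_set = set(leaf_cells.tolist())
    f2c = mesh.facet_to_cells()
    out = []
    for f, cs in f2c.items():
        ns = sum(1 for c in cs if c in leaf_set)
        if ns >= 1 and (len(cs) == 1 or ns < len(cs)):
            out.append(f)
    return np.array(out, dtype=np.int64).reshape(-1, mesh.dim)


def _points_in_any_triangle(pts, tris):
    """Boolean per point: inside any of the 2D triangles (inclusive)."""
    res = np.zeros(len(pts), dtype=bool)
    for tri in tris:
        a, b, c = tri
        v0, v1 = b - a, c - a
        den = v0[0] * v1[1] - v0[1] * v1[0]
        if abs(den) < 1e-30:
            continue
        ap = pts - a
        u = (ap[:, 0] * v1[1] - ap[:, 1] * v1[0]) / den
        v = (v0[0] * ap[:, 1] - v0[1] * ap[:, 0]) / den
        res |= (u >= -1e-12) & (v >= -1e-12) & (u + v <= 1 + 1e-12)
    return res


# ---------------------------------------------------------------------------
# rotation angle
# ---------------------------------------------------------------------------

def rotation_angle(
    leaflet_coords: np.ndarray,
    hinge_a: np.ndarray,
    hinge_b: np.ndarray,
    closed_normal: np.ndarray,
) -> float:
    """Dihedral angle (degrees) of the leaflet best-fit plane about the hinge.

    ``closed_normal`` is the normal of the leaflet's closed reference plane.
    The angle is measured between the two planes about the hinge axis.
    """
    pts = np.asarray(leaflet_coords, dtype=float)
    if len(pts) < 3:
        raise ValveFsiError("need at least 3 leaflet vertices")
    X = pts - pts.mean(axis=0)
    _, svals, Vt = np.linalg.svd(X, full_matrices=False)
    if svals[1] < 1e-12 * max(svals[0], 1e-300):
        raise ValveFsiError("collinear leaflet vertices: no plane fit")
    n = Vt[-1]
    axis = np.asarray(hinge_b, dtype=float) - np.asarray(hinge_a, dtype=float)
    na = np.linalg.norm(axis)
    if na < 1e-300:
        raise ConfigurationError("degenerate hinge axis")
    axis = axis / na
    # project both normals onto the plane orthogonal to the hinge axis
    n_perp = n - (n @ axis) * axis
    c_perp = closed_normal - (closed_normal @ axis) * axis
    nn, nc = np.linalg.norm(n_perp), np.linalg.norm(c_perp)
    if nn < 1e-300 or nc < 1e-300:
        return 0.0
    cosang = np.clip(abs(n_perp @ c_perp) / (nn * nc), -1.0, 1.0)
    return float(np.degrees(np.arccos(cosang)))


def angular_velocity(t: np.ndarray, alpha: np.ndarray) -> np.ndarray:
    """Centered finite-difference rate of a stored angle series (deg/s)."""
    return np.gradient(np.asarray(alpha, dtype=float), np.asarray(t, dtype=float))


# ---------------------------------------------------------------------------
# lambda2 and von Mises fields
# ---------------------------------------------------------------------------

def lambda2_field(U: np.ndarray, mesh: TaggedMesh) -> np.ndarray:
    """Per-vertex lambda2: middle eigenvalue of S^2 + Omega^2 (3D only).

    Vortex cores are regions with lambda2 below a user-chosen negative
    threshold; the threshold is applied at visualization time, not here.
    """
    if mesh.dim != 3:
        raise ValveFsiError("lambda2 is defined for 3D velocity fields only")
    G, vol = p1_gradients(mesh.vertices, mesh.cells)
    g = np.einsum("kjd,kje->kde", U[mesh.cells], G)
    S = 0.5 * (g + np.swapaxes(g, 1, 2))
    W = 0.5 * (g - np.swapaxes(g, 1, 2))
    A = S @ S + W @ W
    lam = np.linalg.eigvalsh(A)  # ascending
    lam2_cell = lam[:, 1]
    num = np.zeros(mesh.num_vertices)
    den = np.zeros(mesh.num_vertices)
    np.add.at(num, mesh.cells.ravel(), np.repeat(lam2_cell * vol, mesh.dim + 1))
    np.add.at(den, mesh.cells.ravel(), np.repeat(vol, mesh.dim + 1))
    return num / np.maximum(den, 1e-300)


def von_mises_field(
    state,
    theta: np.ndarray,
    mesh: TaggedMesh,
    materials: MaterialConstants,
    log_scale: bool = False,
) -> np.ndarray:
    """Per-cell von Mises stress of the composite stress tau = tau_D - p I."""
    G, _ = p1_gradients(mesh.vertices, mesh.cells)
    g = np.einsum("kjd,kje->kde", state.U[mesh.cells], G)
    tau_f = fluid_stress(g, materials.mu_f)
    p_cell = state.P[mesh.cells].mean(axis=1)
    tau, tau_D = composite_stress(theta, tau_f, state.tau_s, p_cell)
    if mesh.dim == 2:
        # planar flow of an incompressible medium: the out-of-plane normal
        # stress is -p, so the pressure must embed isotropically in 3D
        tau3 = np.zeros((tau.shape[0], 3, 3))
        tau3[:, :2, :2] = tau_D
        tau3 -= p_cell[:, None, None] * np.eye(3)
        tau = tau3
    tv = von_mises(tau)
    if log_scale:
        return np.log10(np.maximum(tv, 1e-300))
    return tv


# ---------------------------------------------------------------------------
# output
# ---------------------------------------------------------------------------

def write_outputs(trajectory, outdir: str, series: TimeSeries | None = None,
                  basename: str = "step") -> list:
    """Write VTU snapshots + PVD index (+ CSV series) for a trajectory.

    ``trajectory`` is a sequence of (mesh, state, theta) triples.  Returns
    the list of files written; an empty trajectory writes nothing and warns.
    """
    if len(trajectory) == 0:
        warnings.warn("empty trajectory: no output written", stacklevel=2)
        return []
    os.makedirs(outdir, exist_ok=True)
    written = []
    entries = []
    for i, (mesh, state, theta) in enumerate(trajectory):
        fname = f"{basename}_{i:05d}.vtu"
        cell_data = {"theta": theta, "region": mesh.region_tags.astype(float)}
        write_vtu(mesh, os.path.join(outdir, fname),
                  point_data={"U": state.U, "P": state.P},
                  cell_data=cell_data)
        written.append(fname)
        entries.append((state.t, fname))
    pvd = os.path.join(outdir, f"{basename}.pvd")
    write_pvd(pvd, entries)
    written.append(pvd)
    if series is not None and len(series.t):
        csv = os.path.join(outdir, "timeseries.csv")
        series.to_csv(csv)
        written.append(csv)
    return written
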