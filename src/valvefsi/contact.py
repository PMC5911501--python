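"""Valve contact: collision detection, phase-switch closure, hinge locking.

Closure of a valve is modeled inside the unified continuum by switching
fluid cells to solid: when the minimal distance between two leaflet
surfaces (or a leaflet and the facing wall) drops below a threshold, the
cells directly attached under the pre-embedded closure surface flip their
phase from fluid to solid in a single step — whole-orifice closure at once,
acceptable because the closing moment of a healthy valve is very short.
The contact is released, and the switched cells returned to fluid, at the
start of the next systole.

Distances are available from an exact geometric computation (min
point-to-facet distance, the reference oracle) or from a vanishing-
viscosity finite-element Eikonal solve, which agrees with the geometric
distance to within twice the local mesh size.

The mechanical-valve hinge mechanism is modeled by angle thresholds: a
leaflet exceeding the opening (closing) barrier is locked by zero-velocity
constraints, released from fully open when the mean pressure above the
valve exceeds the mean pressure below, and from fully closed when a new
heart cycle starts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .errors import ConfigurationError
from .mesh import TaggedMesh
from .smoothing import p1_gradients


@dataclass
class ContactState:
    d_min: float = np.inf
    closed: bool = False
    threshold: float = 0.0
    closed_cells: np.ndarray = field(
        default_factory=lambda: np.array([], dtype=np.int64)
    )


@dataclass
class HingeState:
    """Per-leaflet hinge bookkeeping for a bileaflet mechanical valve."""

    alpha: np.ndarray = field(default_factory=lambda: np.zeros(2))
    omega: np.ndarray = field(default_factory=lambda: np.zeros(2))
    locked_open: np.ndarray = field(default_factory=lambda: np.zeros(2, dtype=bool))
    locked_closed: np.ndarray = field(default_factory=lambda: np.zeros(2, dtype=bool))
    alpha_max: float = 45.0
    alpha_closed: float = 0.0


# ---------------------------------------------------------------------------
# distances
# ---------------------------------------------------------------------------

def _point_segment_distance(pts, seg_a, seg_b):
    """Min distance of each point to one segment (vectorized over points)."""
    ab = seg_b - seg_a
    denom = float(ab @ ab)
    t = np.clip(((pts - seg_a) @ ab) / max(denom, 1e-300), 0.0, 1.0)
    proj = seg_a + t[:, None] * ab
    return np.linalg.norm(pts - proj, axis=1)


def _point_triangle_distance(pts, tri):
    """Min distance of each point to one triangle in 3D (vectorized)."""
    a, b, c = tri
    ab, ac = b - a, c - a
    n = np.cross(ab, ac)
    nn = float(n @ n)
    if nn < 1e-300:  # degenerate triangle: fall back to its edges
        return np.minimum(
            _point_segment_distance(pts, a, b), _point_segment_distance(pts, a, c)
        )
    ap = pts - a
    # barycentric coordinates of the in-plane projection
    d00, d01, d11 = ab @ ab, ab @ ac, ac @ ac
    d20, d21 = ap @ ab, ap @ ac
    den = d00 * d11 - d01 * d01
    v = (d11 * d20 - d01 * d21) / den
    w = (d00 * d21 - d01 * d20) / den
    inside = (v >= 0) & (w >= 0) & (v + w <= 1)
    dist = np.empty(len(pts))
    dist[inside] = np.abs(ap[inside] @ n) / np.sqrt(nn)
    out = ~inside
    if out.any():
        po = pts[out]
        d = np.minimum(
            _point_segment_distance(po, a, b),
            np.minimum(
                _point_segment_distance(po, a, c),
                _point_segment_distance(po, b, c),
            ),
        )
        dist[out] = d
    return dist


def _points_to_facets(points, vertices, facets, dim):
    if len(points) == 0 or len(facets) == 0:
        return np.inf
    best = np.full(len(points), np.inf)
    for f in facets:
        coords = vertices[f]
        if dim == 2:
            d = _point_segment_distance(points, coords[0], coords[1])
        else:
            d = _point_triangle_distance(points, coords)
        best = np.minimum(best, d)
    return float(best.min())


def surface_facets(mesh: TaggedMesh, leaflet_tag: int) -> np.ndarray:
    """Interface facets bounding the leaflet with the given region tag."""
    tag_cells = set(np.flatnonzero(mesh.region_tags == leaflet_tag))
    f2c = mesh.facet_to_cells()
    out = []
    for f in mesh.facet_tags.get("interface", []):
        cs = f2c[tuple(sorted(f))]
        if any(c in tag_cells for c in cs):
            out.append(tuple(f))
    return np.array(out, dtype=np.int64).reshape(-1, mesh.dim)


def surface_distance(
    mesh: TaggedMesh,
    facets_a: np.ndarray,
    facets_b: np.ndarray,
    method: str = "geometric",
) -> float:
    """Minimal distance between two facet surfaces of the same mesh."""
    if len(facets_a) == 0 or len(facets_b) == 0:
        raise ConfigurationError("empty surface in distance computation")
    if method == "geometric":
        pa = mesh.vertices[np.unique(facets_a)]
        pb = mesh.vertices[np.unique(facets_b)]
        d1 = _points_to_facets(pa, mesh.vertices, facets_b, mesh.dim)
        d2 = _points_to_facets(pb, mesh.vertices, facets_a, mesh.dim)
        return min(d1, d2)
    if method == "eikonal":
        phi = eikonal_distance(mesh, np.unique(facets_a))
        return float(phi[np.unique(facets_b)].min())
    raise ConfigurationError(f"unknown distance method {method!r}")


def leaflet_distance(
    mesh: TaggedMesh,
    theta: np.ndarray,
    leaflet_tag_i: int,
    leaflet_tag_j: int,
    method: str = "geometric",
) -> float:
    """Distance d_ij between the surfaces of two tagged leaflets."""
    del theta  # surfaces are defined by the region tags
    fa = surface_facets(mesh, leaflet_tag_i)
    fb = surface_facets(mesh, leaflet_tag_j)
    shared = set(map(tuple, np.sort(fa, axis=1))) & set(
        map(tuple, np.sort(fb, axis=1))
    )
    if shared or len(
        set(np.unique(fa)) & set(np.unique(fb))
    ):
        return 0.0
    return surface_distance(mesh, fa, fb, method)


def minimal_leaflet_distance(
    mesh: TaggedMesh, theta: np.ndarray, tags=(2, 3, 4), method="geometric"
) -> float:
    """d_min = min over leaflet pairs, as used for native-valve closure."""
    present = [t for t in tags if np.any(mesh.region_tags == t)]
    best = np.inf
    for ii in range(len(present)):
        for jj in range(ii + 1, len(present)):
            best = min(
                best,
                leaflet_distance(mesh, theta, present[ii], present[jj], method),
            )
    return best


# ---------------------------------------------------------------------------
# Eikonal distance field
# ---------------------------------------------------------------------------

def eikonal_distance(
    mesh: TaggedMesh,
    source_vertices: np.ndarray,
    n_sweeps: int = 3,
    eps_factor: float = 1.0,
) -> np.ndarray:
    """FEM vanishing-viscosity solve of |grad(phi)| = 1 with phi = 0 on sources.

    A shortest-edge-path (Dijkstra) field initializes the transport
    direction; a few fixed-point sweeps of the stabilized linear problem

        (eps h grad(phi), grad(v)) + ((w . grad) phi, v) = (1, v),
        w = grad(phi_prev)/|grad(phi_prev)|,

    then relax the graph metric toward the Euclidean distance.
    """
    from scipy.sparse.csgraph import dijkstra

    nv, d = mesh.vertices.shape
    cells = mesh.cells
    # edge graph for the initial guess
    edges = set()
    for k in range(d + 1):
        for l in range(k + 1, d + 1):
            for e in zip(cells[:, k], cells[:, l]):
                edges.add((min(e), max(e)))
    ei = np.array(list(edges))
    w = np.linalg.norm(mesh.vertices[ei[:, 0]] - mesh.vertices[ei[:, 1]], axis=1)
    Gr = sp.csr_matrix(
        (np.r_[w, w], (np.r_[ei[:, 0], ei[:, 1]], np.r_[ei[:, 1], ei[:, 0]])),
        shape=(nv, nv),
    )
    phi = dijkstra(Gr, indices=source_vertices, min_only=True)
    phi[~np.isfinite(phi)] = phi[np.isfinite(phi)].max()

    G, vol = p1_gradients(mesh.vertices, cells)
    h = vol ** (1.0 / d)
    n1 = d + 1
    src = np.zeros(nv, dtype=bool)
    src[source_vertices] = True
    free = np.flatnonzero(~src)

    for _ in range(n_sweeps):
        gphi = np.einsum("kj,kjd->kd", phi[cells], G)
        norm = np.maximum(np.linalg.norm(gphi, axis=1), 1e-12)
        wdir = gphi / norm[:, None]
        adv = np.einsum("kd,kjd->kj", wdir, G)
        diff = (eps_factor * h * vol)[:, None, None] * np.einsum(
            "kid,kjd->kij", G, G
        )
        convec = (vol / n1)[:, None, None] * np.ones((1, n1, 1)) * adv[:, None, :]
        local = diff + convec
        rows = np.repeat(cells, n1, axis=1).ravel()
        colsm = np.tile(cells, (1, n1)).ravel()
        A = sp.csr_matrix((local.ravel(), (rows, colsm)), shape=(nv, nv))
        b = np.zeros(nv)
        np.add.at(b, cells.ravel(), np.repeat(vol / n1, n1))
        Aff = A[free][:, free]
        bf = b[free] - A[free][:, np.flatnonzero(src)] @ phi[src]
        phi_new = phi.copy()
        phi_new[free] = spla.spsolve(Aff.tocsc(), np.asarray(bf).ravel())
        phi = np.maximum(phi_new, 0.0)
        phi[src] = 0.0
    return phi


# ---------------------------------------------------------------------------
# phase switching
# ---------------------------------------------------------------------------

def closure_under_cells(mesh: TaggedMesh, axis_dim: int | None = None) -> np.ndarray:
    """Cells directly attached under the closure surface (upstream side)."""
    closure = mesh.facet_tags.get("closure")
    if closure is None or len(closure) == 0:
        raise ConfigurationError("mesh has no tagged closure surface")
    if axis_dim is None:
        axis_dim = {"x": 0, "y": 1, "z": 2}[mesh.metadata.get("axis", "z")]
    f2c = mesh.facet_to_cells()
    centroids = mesh.vertices[mesh.cells].mean(axis=1)
    under = []
    for f in closure:
        cs = f2c[tuple(sorted(f))]
        if len(cs) == 1:
            under.append(cs[0])
        else:
            a, b = cs
            under.append(a if centroids[a, axis_dim] < centroids[b, axis_dim] else b)
    return np.unique(under)


def check_and_close(
    mesh: TaggedMesh,
    theta: np.ndarray,
    contact_state: ContactState,
    d_min: float,
) -> tuple[np.ndarray, ContactState]:
    """Switch the orifice to solid when d_min falls below the threshold.

    Idempotent while closed; conserves the cell count (only the phase array
    changes).  Returns the (possibly new) phase array and contact state.
    """
    cs = ContactState(
        d_min=d_min, closed=contact_state.closed,
        threshold=contact_state.threshold,
        closed_cells=contact_state.closed_cells,
    )
    if cs.closed or d_min >= cs.threshold:
        return theta, cs
    under = closure_under_cells(mesh)
    switch = under[theta[under] > 0.5]
    theta = theta.copy()
    theta[switch] = 0.0
    cs.closed = True
    cs.closed_cells = switch
    return theta, cs


def release_contact(
    theta: np.ndarray,
    contact_state: ContactState,
    tau_s: np.ndarray | None = None,
) -> tuple[np.ndarray, ContactState]:
    """Revert switched cells to fluid at the systole-start event."""
    if not contact_state.closed:
        return theta, contact_state
    theta = theta.copy()
    theta[contact_state.closed_cells] = 1.0
    if tau_s is not None and len(contact_state.closed_cells):
        tau_s[contact_state.closed_cells] = 0.0
    return theta, ContactState(
        d_min=contact_state.d_min, closed=False,
        threshold=contact_state.threshold,
    )


# ---------------------------------------------------------------------------
# hinge mechanism and probe pressures
# ---------------------------------------------------------------------------

def mean_pressure(mesh: TaggedMesh, P: np.ndarray, probe_facets: np.ndarray) -> float:
    """Area-weighted mean of the P1 pressure over a facet surface."""
    probe_facets = np.asarray(probe_facets).reshape(-1, mesh.dim)
    if len(probe_facets) == 0:
        raise ConfigurationError("empty pressure probe surface")
    total_a, total = 0.0, 0.0
    for f in probe_facets:
        coords = mesh.vertices[f]
        if mesh.dim == 2:
            a = np.linalg.norm(coords[1] - coords[0])
        else:
            a = 0.5 * np.linalg.norm(
                np.cross(coords[1] - coords[0], coords[2] - coords[0])
            )
        total_a += a
        total += a * P[f].mean()  # exact for a linear field on a simplex facet
    return total / total_a


def update_hinge(
    hinge: HingeState,
    alphas: np.ndarray,
    omegas: np.ndarray,
    p_above: float,
    p_below: float,
    new_cycle: bool,
) -> HingeState:
    """Advance the hinge lock/release logic for both leaflets.

    Release rules run before lock checks so a leaflet cannot oscillate
    within one step: fully open leaflets release when the downstream mean
    pressure exceeds the upstream one; fully closed leaflets release when a
    new heart cycle starts.  A leaflet beyond a barrier is locked and its
    reported angle clamped to the barrier value.
    """
    new = HingeState(
        alpha=np.asarray(alphas, dtype=float).copy(),
        omega=np.asarray(omegas, dtype=float).copy(),
        locked_open=hinge.locked_open.copy(),
        locked_closed=hinge.locked_closed.copy(),
        alpha_max=hinge.alpha_max,
        alpha_closed=hinge.alpha_closed,
    )
    for i in range(len(new.alpha)):
        released = False
        if new.locked_open[i] and p_above > p_below:
            new.locked_open[i] = False
            released = True
        if new.locked_closed[i] and new_cycle:
            new.locked_closed[i] = False
            released = True
        if released:
            continue  # a freshly released leaflet may move before re-locking
        if not new.locked_open[i] and new.alpha[i] >= new.alpha_max:
            new.locked_open[i] = True
        if not new.locked_closed[i] and new.alpha[i] <= new.alpha_closed:
            new.locked_closed[i] = True
        if new.locked_open[i]:
            new.alpha[i] = new.alpha_max
            new.omega[i] = 0.0
        elif new.locked_closed[i]:
            new.alpha[i] = new.alpha_closed
            new.omega[i] = 0.0
    return new
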