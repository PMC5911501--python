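"""Parametric valve geometry generators.

Three fully programmatic generators produce tagged simplicial meshes:

* :func:`generate_aortic_root` — idealized trileaflet aortic root: a
  truncated cone from the annulus radius ``R_A`` (z = 0) to the sinotubular
  radius ``R_S`` (z = h_l) with a fixed axisymmetric sinus-of-Valsalva
  bulge, three thin leaflet shells in the fully open position lining the
  sinus wall, an attached ascending-aorta cylinder, and an interior closure
  surface spanning the orifice at the free-edge plane z = h_l.
* :func:`generate_bmhv` — a bileaflet mechanical valve reduced to two
  semicircular-disc leaflets hinged inside an idealized straight aorta.
* :func:`generate_2d_valve_channel` — a desk-scale 2D channel with one or
  two flexible leaflet strips and a closure line across the gap.

All user-facing lengths are millimeters (the paper-style parameter scale);
generated meshes are in SI meters.  Meshes are structured (cylindrical
extrusions of a triangulated disk, split into tetrahedra with a globally
consistent diagonal rule), so the threefold symmetry of the root and the
grid-convergence behaviour of the channel hold exactly by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import GeometryError
from .mesh import REGION_FLUID, TaggedMesh, cell_volumes, orient_cells

MM = 1e-3  # millimeters -> meters


# ---------------------------------------------------------------------------
# parameter records
# ---------------------------------------------------------------------------

@dataclass
class RootParams:
    """Parameters of the idealized aortic root (all lengths in mm).

    ``beta`` is the rotational opening angle (degrees) of the cutting plane
    that carves the leaflet attachment out of the truncated cone: within
    ``beta/2`` of each leaflet midline the attachment sits on the annulus
    plane (the leaflet belly), rising to the commissure height ``h_c`` at
    the sector edges.
    """

    R_A: float = 20.0          # inner annulus radius
    R_S: float = 22.0          # inner sinotubular radius
    h_l: float = 20.0          # leaflet height (open position)
    h_c: float = 6.0           # commissure height
    t_l: float = 1.0           # leaflet thickness
    beta: float = 60.0         # cutting-plane opening angle (deg)
    aorta_length: float = 30.0
    mesh_size: float = 4.0

    def __post_init__(self):
        lengths = (self.R_A, self.R_S, self.h_l, self.h_c, self.t_l,
                   self.aorta_length, self.mesh_size)
        if min(lengths) <= 0:
            raise GeometryError("all root lengths must be positive")
        if self.t_l >= self.h_l:
            raise GeometryError("leaflet thickness must be below leaflet height")
        if self.h_c >= self.h_l:
            raise GeometryError(
                "commissure height above leaflet height: cutting plane misses the cone"
            )
        if not 0.0 < self.beta < 120.0:
            raise GeometryError("opening angle beta must lie in (0, 120) degrees")
        if self.t_l >= min(self.R_A, self.R_S) / 2:
            raise GeometryError("leaflet thickness incompatible with root radius")


@dataclass
class BmhvParams:
    """Parameters of the simplified bileaflet mechanical valve (mm / deg)."""

    aorta_radius: float = 11.0
    leaflet_chord: float = 8.0        # radial extent hinge line -> leaflet tip
    leaflet_thickness: float = 1.0
    hinge_offset: float = 2.0         # |x| of the two hinge axes
    alpha_open_max: float = 45.0
    alpha_closed: float = 0.0
    initial_angle: float = 0.0
    aorta_length: float = 60.0
    mesh_size: float = 2.5
    hinge_points: list = field(default_factory=list)  # filled by the generator

    def __post_init__(self):
        if min(self.aorta_radius, self.leaflet_chord, self.leaflet_thickness,
               self.aorta_length, self.mesh_size) <= 0:
            raise GeometryError("all BMHV lengths must be positive")
        if not self.alpha_closed <= self.initial_angle <= self.alpha_open_max:
            raise GeometryError("initial angle outside the admissible hinge range")
        if self.hinge_offset + self.leaflet_chord >= self.aorta_radius:
            raise GeometryError("leaflet would overlap the aorta wall")


# ---------------------------------------------------------------------------
# structured building blocks
# ---------------------------------------------------------------------------

def _disk_triangulation(nr: int, nphi: int):
    """Unit-pattern triangulated disk: center vertex + nr rings of nphi vertices.

    Returns (unit_xy, ring_index, triangles).  Ring radii are assigned later
    per extrusion level, so ``unit_xy`` holds unit direction vectors.
    """
    phis = 2.0 * np.pi * np.arange(nphi) / nphi
    unit = [np.array([0.0, 0.0])]
    ring = [0]
    for j in range(1, nr + 1):
        for p in phis:
            unit.append(np.array([np.cos(p), np.sin(p)]))
            ring.append(j)
    unit = np.array(unit)
    ring = np.array(ring)

    def rid(j, i):  # vertex index of ring j (1-based), azimuthal slot i
        return 1 + (j - 1) * nphi + (i % nphi)

    tris = []
    for i in range(nphi):
        tris.append((0, rid(1, i), rid(1, i + 1)))
    for j in range(1, nr):
        for i in range(nphi):
            a, b = rid(j, i), rid(j, i + 1)
            c, d = rid(j + 1, i), rid(j + 1, i + 1)
            tris.append((a, c, d))
            tris.append((a, d, b))
    return unit, ring, np.array(tris, dtype=np.int64)


# the six orientation-preserving relabelings of a prism (bottom 012, top 345)
_PRISM_ROTS = (
    (0, 1, 2, 3, 4, 5), (1, 2, 0, 4, 5, 3), (2, 0, 1, 5, 3, 4),
    (3, 5, 4, 0, 2, 1), (4, 3, 5, 1, 0, 2), (5, 4, 3, 2, 1, 0),
)


def _split_prism(gids):
    """Split one prism into 3 tets with globally consistent quad diagonals.

    Diagonals are chosen through the smallest global vertex id of each quad
    face, so neighbouring prisms always agree on shared faces.
    """
    best = min(range(6), key=lambda i: gids[i])
    rot = next(r for r in _PRISM_ROTS if r[0] == best)
    g = [gids[r] for r in rot]
    if min(g[1], g[5]) < min(g[2], g[4]):
        tets = ((0, 1, 2, 5), (0, 1, 5, 4), (0, 4, 5, 3))
    else:
        tets = ((0, 1, 2, 4), (0, 4, 2, 5), (0, 4, 5, 3))
    return [tuple(g[i] for i in tet) for tet in tets]


def _extrude_disk(unit, ring, tris, ring_radii_per_level, z_levels):
    """Extrude a disk triangulation along z into a tet mesh.

    ``ring_radii_per_level[k][j]`` is the radius of ring j (1-based; ring 0
    is the axis) at level k.  Returns vertices, tets and, per tet, the
    (level_interval, disk_triangle) it came from.
    """
    nlev = len(z_levels)
    npattern = len(unit)
    verts = np.empty((nlev * npattern, 3))
    for k, z in enumerate(z_levels):
        radii = ring_radii_per_level[k]
        r = np.array([0.0] + list(radii))[ring]
        verts[k * npattern:(k + 1) * npattern, 0] = unit[:, 0] * r
        verts[k * npattern:(k + 1) * npattern, 1] = unit[:, 1] * r
        verts[k * npattern:(k + 1) * npattern, 2] = z

    tets, origin = [], []
    for k in range(nlev - 1):
        lo, hi = k * npattern, (k + 1) * npattern
        for ti, tri in enumerate(tris):
            prism = [lo + tri[0], lo + tri[1], lo + tri[2],
                     hi + tri[0], hi + tri[1], hi + tri[2]]
            for tet in _split_prism(prism):
                tets.append(tet)
                origin.append((k, ti))
    return verts, np.array(tets, dtype=np.int64), origin


def _interface_facets(mesh: TaggedMesh) -> np.ndarray:
    """Facets shared by one fluid and one solid cell."""
    f2c = mesh.facet_to_cells()
    out = []
    for fac, cs in f2c.items():
        if len(cs) == 2:
            a, b = mesh.region_tags[cs[0]], mesh.region_tags[cs[1]]
            if (a == REGION_FLUID) != (b == REGION_FLUID):
                out.append(fac)
    return np.array(sorted(out), dtype=np.int64).reshape(-1, mesh.dim)


def _boundary_split(mesh, classify):
    """Partition boundary facets by a classify(facet_vertex_coords) -> name."""
    tags: dict = {}
    for fac in mesh.boundary_facets():
        name = classify(mesh.vertices[fac])
        tags.setdefault(name, []).append(tuple(fac))
    return {k: np.array(v, dtype=np.int64) for k, v in tags.items()}


# ---------------------------------------------------------------------------
# aortic root
# ---------------------------------------------------------------------------

#: fixed sinus-of-Valsalva bulge amplitude, as a fraction of R_S
SINUS_BULGE_FRACTION = 0.25


def _attachment_height(phi_local_deg, p: RootParams):
    """Leaflet attachment height a(phi) within one 120-degree sector.

    The cutting plane P_c is realized as a smooth attachment curve on the
    cone: flat on the annulus over the belly (|phi| <= beta/2), then rising
    quadratically to the commissure height h_c at the sector edge (60 deg).
    """
    x = np.abs(np.asarray(phi_local_deg, dtype=float))
    half = p.beta / 2.0
    rise = np.clip((x - half) / (60.0 - half), 0.0, 1.0)
    return p.h_c * rise**2


def generate_aortic_root(params: RootParams | None = None) -> TaggedMesh:
    """Generate the idealized trileaflet aortic root as a tagged tet mesh.

    The annulus plane is z = 0 and the axis is z.  Leaflets (region tags
    2, 3, 4) are one-cell-thick shells of thickness ``t_l`` lining the sinus
    wall between the attachment curve and the free edge at z = h_l; the
    closure surface is the interior facet layer spanning the orifice at
    z = h_l.  Rim radii at the annulus and the sinotubular junction equal
    ``R_A`` and ``R_S`` exactly (the sinus bulge vanishes at both planes).
    """
    p = params or RootParams()
    ms = p.mesh_size

    # azimuthal count: multiple of 6 so the three 120-degree sectors are
    # congruent and each has a mirror line through its midline
    nphi = max(12, 6 * int(np.ceil(2 * np.pi * p.R_S / ms / 6.0)))
    nr_inner = max(2, int(round((min(p.R_A, p.R_S) - p.t_l) / ms)))

    def seg(z0, z1):
        n = max(1, int(round((z1 - z0) / ms)))
        return np.linspace(z0, z1, n + 1)

    z_levels = np.unique(np.concatenate([
        seg(0.0, p.h_c), seg(p.h_c, p.h_l),
        seg(p.h_l, p.h_l + p.aorta_length),
    ]))
    lev_free = int(np.argmin(np.abs(z_levels - p.h_l)))

    def wall_radius(z):
        cone = p.R_A + (p.R_S - p.R_A) * np.clip(z / p.h_l, 0.0, 1.0)
        bulge = SINUS_BULGE_FRACTION * p.R_S * np.sin(
            np.pi * np.clip(z / p.h_l, 0.0, 1.0)
        )
        return cone + bulge

    unit, ring, tris = _disk_triangulation(nr_inner + 1, nphi)
    radii_per_level = []
    for z in z_levels:
        rw = wall_radius(z)
        inner = [(j / nr_inner) * (rw - p.t_l) for j in range(1, nr_inner + 1)]
        radii_per_level.append(inner + [rw])

    verts, tets, origin = _extrude_disk(unit, ring, tris, radii_per_level, z_levels)

    # per disk triangle: is it in the outer (wall-shell) band, and its angle
    tri_ring_max = ring[tris].max(axis=1)
    outer_band = tri_ring_max == nr_inner + 1
    tri_mid = unit[tris].mean(axis=1)
    tri_phi = np.degrees(np.arctan2(tri_mid[:, 1], tri_mid[:, 0]))  # [-180,180)

    region = np.full(len(tets), REGION_FLUID, dtype=np.int64)
    zc = np.array([0.5 * (z_levels[k] + z_levels[k + 1]) for k, _ in origin])
    tri_of = np.array([ti for _, ti in origin])
    lev_of = np.array([k for k, _ in origin])

    phi = tri_phi[tri_of]
    sector = np.floor(((phi + 60.0) % 360.0) / 120.0).astype(int)  # 0,1,2
    phi_local = ((phi + 60.0) % 120.0) - 60.0
    attach = _attachment_height(phi_local, p)
    is_leaf = (
        outer_band[tri_of]
        & (zc >= attach)
        & (zc <= p.h_l)
    )
    region[is_leaf] = 2 + sector[is_leaf]

    # closure surface: interior orifice facets at z = h_l (disk triangles of
    # the inner region at the free-edge level, shared by the prisms below
    # and above; the prism split preserves these horizontal triangles)
    npattern = len(unit)
    closure = []
    for ti, tri in enumerate(tris):
        if not outer_band[ti]:
            closure.append(tuple(lev_free * npattern + v for v in tri))
    closure = np.array(closure, dtype=np.int64)

    verts = verts * MM
    tets = orient_cells(verts, tets)
    mesh = TaggedMesh(verts, tets, region)

    z_top = (p.h_l + p.aorta_length) * MM
    tol = 1e-9

    def classify(coords):
        z = coords[:, 2]
        if np.all(np.abs(z) < tol):
            return "inlet"
        if np.all(np.abs(z - z_top) < tol):
            return "outlet"
        return "wall"

    mesh.facet_tags = _boundary_split(mesh, classify)
    mesh.facet_tags["closure"] = closure
    mesh.facet_tags["interface"] = _interface_facets(mesh)
    mesh.metadata = {
        "kind": "aortic_root",
        "params": p,
        "free_edge_z": p.h_l * MM,
        "axis": "z",
    }
    if np.any(cell_volumes(verts, tets) <= 0):
        raise GeometryError("root generation produced a degenerate cell")
    return mesh


# ---------------------------------------------------------------------------
# bileaflet mechanical valve
# ---------------------------------------------------------------------------

def _rotation_about_axis(axis_point, axis_dir, angle_rad):
    """Rigid rotation matrix/offset about an arbitrary 3D axis."""
    k = axis_dir / np.linalg.norm(axis_dir)
    K = np.array([[0, -k[2], k[1]], [k[2], 0, -k[0]], [-k[1], k[0], 0]])
    R = np.eye(3) + np.sin(angle_rad) * K + (1 - np.cos(angle_rad)) * (K @ K)
    return R, axis_point - R @ axis_point


def generate_bmhv(params: BmhvParams | None = None) -> TaggedMesh:
    """Generate the simplified BMHV-in-aorta mesh.

    Two semicircular-disc leaflets (region tags 2 and 3) sit in the valve
    plane of a straight tube; each rotates about the hinge axis defined by
    two fixed edge points at x = +-hinge_offset.  The leaflets are tilted to
    ``initial_angle`` by an exact rigid rotation of the leaflet vertices
    (with an axially tapered blend into the neighbouring fluid mesh), so the
    angle recomputed from the generated coordinates equals the input.  The
    geometry keeps a central gap so the leaflets can never touch each other.
    """
    p = params or BmhvParams()
    ms = p.mesh_size
    R, L = p.aorta_radius, p.aorta_length
    z_v = L / 3.0

    nphi = max(12, 4 * int(np.ceil(2 * np.pi * R / ms / 4.0)))
    nr = max(3, int(round(R / ms)))

    def seg(z0, z1, step):
        n = max(1, int(round((z1 - z0) / step)))
        return np.linspace(z0, z1, n + 1)

    # leaflet slab is one thin level pair [z_v, z_v + t]; taper region above
    taper = min(L - z_v - 2 * ms, 2.0 * p.leaflet_chord)
    z_levels = np.unique(np.concatenate([
        seg(0.0, z_v, ms),
        [z_v, z_v + p.leaflet_thickness],
        seg(z_v + p.leaflet_thickness, z_v + p.leaflet_thickness + taper, ms),
        seg(z_v + p.leaflet_thickness + taper, L, ms),
    ]))

    unit, ring, tris = _disk_triangulation(nr, nphi)
    radii = [[(j / nr) * R for j in range(1, nr + 1)]] * len(z_levels)
    verts, tets, origin = _extrude_disk(unit, ring, tris, radii, z_levels)

    k_slab = int(np.argmin(np.abs(z_levels - z_v)))
    # triangle centroids in the disk cross-section
    rad0 = np.array([0.0] + radii[0])[ring]
    disk_xy = unit * rad0[:, None]
    tri_cent = disk_xy[tris].mean(axis=1)

    region = np.full(len(tets), REGION_FLUID, dtype=np.int64)
    lev_of = np.array([k for k, _ in origin])
    tri_of = np.array([ti for _, ti in origin])
    in_slab = lev_of == k_slab
    cx = tri_cent[tri_of, 0]
    right = in_slab & (cx >= p.hinge_offset)
    left = in_slab & (cx <= -p.hinge_offset)
    region[right] = 2
    region[left] = 3

    # hinge edge points (on the tube wall, in the valve plane)
    y_h = np.sqrt(max(R**2 - p.hinge_offset**2, 0.0))
    hinges = {
        2: (np.array([p.hinge_offset, -y_h, z_v]), np.array([p.hinge_offset, y_h, z_v])),
        3: (np.array([-p.hinge_offset, -y_h, z_v]), np.array([-p.hinge_offset, y_h, z_v])),
    }

    # tilt leaflets: exact rigid rotation of the leaflet-cell vertices about
    # the hinge axis (free edge swings downstream, +z), with an axially
    # tapered blend of the same motion for fluid vertices above the slab so
    # the tube mesh stays valid up to the 45-degree limit
    alpha = np.radians(p.initial_angle)
    if alpha != 0.0:
        zt0 = z_levels[k_slab + 1]
        for tag, side_sign in ((2, +1.0), (3, -1.0)):
            a_pt, b_pt = hinges[tag]
            axis_dir = b_pt - a_pt  # +y for both hinges
            # about +y, a positive angle moves +x toward -z; choose the sign
            # so the leaflet tip (at side_sign * x > 0) moves downstream
            Rm, toff = _rotation_about_axis(a_pt, axis_dir, -side_sign * alpha)
            leaf_vs = np.unique(tets[region == tag])
            w = np.zeros(len(verts))
            above = verts[:, 2] > zt0 + 1e-12
            same_side = side_sign * verts[:, 0] > p.hinge_offset
            w[above & same_side] = np.clip(
                1.0 - (verts[above & same_side, 2] - zt0) / taper, 0.0, 1.0
            )
            is_leaf_v = np.zeros(len(verts), dtype=bool)
            is_leaf_v[leaf_vs] = True
            w[is_leaf_v] = 1.0
            moving = w > 0.0
            disp = verts[moving] @ Rm.T + toff - verts[moving]
            # blended fluid vertices only slide axially (keeps wall vertices
            # on the tube surface); leaflet vertices move rigidly
            disp[~is_leaf_v[moving], :2] = 0.0
            verts[moving] += w[moving, None] * disp

    # closure / measurement surface: first planar cross-section above the
    # taper (used for orifice-area projection; BMHV closure is hinge-locked)
    k_meas = int(np.searchsorted(z_levels, z_v + p.leaflet_thickness + taper))
    npattern = len(unit)
    closure = np.array(
        [tuple(k_meas * npattern + v for v in tri) for tri in tris],
        dtype=np.int64,
    )

    verts = verts * MM
    tets = orient_cells(verts, tets)
    if np.any(cell_volumes(verts, tets) <= 0):
        raise GeometryError("BMHV generation produced a degenerate cell")
    mesh = TaggedMesh(verts, tets, region)

    tol = 1e-9

    def classify(coords):
        z = coords[:, 2]
        if np.all(np.abs(z) < tol):
            return "inlet"
        if np.all(np.abs(z - L * MM) < tol):
            return "outlet"
        return "wall"

    mesh.facet_tags = _boundary_split(mesh, classify)
    mesh.facet_tags["closure"] = closure
    mesh.facet_tags["interface"] = _interface_facets(mesh)
    p.hinge_points = [
        (tuple(hinges[2][0] * MM), tuple(hinges[2][1] * MM)),
        (tuple(hinges[3][0] * MM), tuple(hinges[3][1] * MM)),
    ]
    mesh.metadata = {
        "kind": "bmhv",
        "params": p,
        "hinge_points": p.hinge_points,
        "alpha_open_max": p.alpha_open_max,
        "alpha_closed": p.alpha_closed,
        "initial_angle": p.initial_angle,
        "valve_plane_z": z_v * MM,
        "axis": "z",
    }
    return mesh


# ---------------------------------------------------------------------------
# 2D channel fixture
# ---------------------------------------------------------------------------

def generate_2d_valve_channel(
    channel_length: float,
    channel_height: float,
    leaflet_length: float,
    leaflet_thickness: float,
    mesh_size: float,
    leaflet_x: float | None = None,
    num_leaflets: int = 1,
) -> TaggedMesh:
    """Desk-scale 2D analog: a channel with flexible leaflet strip(s).

    All lengths in mm; the mesh is in meters.  The leaflet is a vertical
    strip of solid cells attached to the bottom wall (and, for
    ``num_leaflets=2``, a mirrored strip on the top wall); the closure line
    is the column of interior vertical edges continuing the leaflet's
    upstream face across the gap.
    """
    Lc, H = channel_length, channel_height
    lh, t = leaflet_length, leaflet_thickness
    if t <= 0 or lh <= 0 or mesh_size <= 0:
        raise GeometryError("leaflet and mesh dimensions must be positive")
    if lh >= H:
        raise GeometryError("leaflet length must be below the channel height")
    if num_leaflets == 2 and 2 * lh >= H:
        raise GeometryError("two leaflets of this length would overlap")
    x_l = Lc / 3.0 if leaflet_x is None else leaflet_x
    if x_l <= 0 or x_l + t >= Lc:
        raise GeometryError("leaflet does not fit inside the channel")

    def grid(lo, hi, forced):
        # uniform fill between forced grid lines so leaflet faces and the
        # tip height are exact mesh lines
        marks = sorted({lo, hi} | {f for f in forced if lo < f < hi})
        pts = []
        for a, b in zip(marks[:-1], marks[1:]):
            n = max(1, int(round((b - a) / mesh_size)))
            pts.extend(np.linspace(a, b, n + 1)[:-1])
        pts.append(hi)
        return np.array(pts)

    xs = grid(0.0, Lc, (x_l, x_l + t))
    ys = grid(0.0, H, (lh,) if num_leaflets == 1 else (lh, H - lh))

    nx, ny = len(xs), len(ys)
    X, Y = np.meshgrid(xs, ys, indexing="ij")
    verts = np.column_stack([X.ravel(), Y.ravel()]) * MM

    def vid(i, j):
        return i * ny + j

    cells, region = [], []
    for i in range(nx - 1):
        for j in range(ny - 1):
            xm = 0.5 * (xs[i] + xs[i + 1])
            ym = 0.5 * (ys[j] + ys[j + 1])
            solid = x_l <= xm <= x_l + t and (
                ym <= lh or (num_leaflets == 2 and ym >= H - lh)
            )
            if solid:
                tag = 2 if ym <= lh else 3
            else:
                tag = REGION_FLUID
            a, b = vid(i, j), vid(i + 1, j)
            c, d = vid(i + 1, j + 1), vid(i, j + 1)
            cells.append((a, b, c))
            region.append(tag)
            cells.append((a, c, d))
            region.append(tag)

    cells = orient_cells(verts, np.array(cells, dtype=np.int64))
    mesh = TaggedMesh(verts, cells, np.array(region, dtype=np.int64))

    tol = 1e-12
    Lm, Hm = Lc * MM, H * MM

    def classify(coords):
        x, y = coords[:, 0], coords[:, 1]
        if np.all(np.abs(x) < tol):
            return "inlet"
        if np.all(np.abs(x - Lm) < tol):
            return "outlet"
        return "wall"

    mesh.facet_tags = _boundary_split(mesh, classify)

    # closure line: the full column of interior vertical edges at x = x_l —
    # the 2D surface covering the entire valve opening (edges alongside the
    # leaflet are its upstream face and count as occluded while solid)
    i_l = int(np.argmin(np.abs(xs - x_l)))
    closure = []
    for j in range(ny - 1):
        closure.append((vid(i_l, j), vid(i_l, j + 1)))
    mesh.facet_tags["closure"] = np.array(closure, dtype=np.int64)
    mesh.facet_tags["interface"] = _interface_facets(mesh)
    mesh.metadata = {
        "kind": "channel2d",
        "leaflet_x": x_l * MM,
        "leaflet_tip_y": lh * MM,
        "leaflet_thickness": t * MM,
        "channel": (Lm, Hm),
        "axis": "x",
        "num_leaflets": num_leaflets,
    }
    return mesh
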