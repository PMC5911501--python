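"""Mesh and field file I/O: Gmsh ``.msh`` v4.1 ASCII, XDMF+HDF5, VTU/PVD.

Only the simplicial subset used by this package is supported (triangles in
2D, tetrahedra in 3D, plus their facets).  Region tags and named facet sets
map onto Gmsh physical groups; the ASCII writer/reader pair round-trips
coordinates, connectivity and tags bit-exactly.
"""

from __future__ import annotations

import os
import xml.etree.ElementTree as ET

import numpy as np

from .errors import MeshFormatError
from .mesh import TaggedMesh, orient_cells

# Gmsh element type ids for the supported simplices
_GMSH_LINE = 1
_GMSH_TRI = 2
_GMSH_TET = 4

_CELL_TYPE = {2: _GMSH_TRI, 3: _GMSH_TET}
_FACET_TYPE = {2: _GMSH_LINE, 3: _GMSH_TRI}
_TYPE_NNODES = {_GMSH_LINE: 2, _GMSH_TRI: 3, _GMSH_TET: 4}


def _fmt(x: float) -> str:
    return format(x, ".17g")


# ---------------------------------------------------------------------------
# Gmsh 4.1 ASCII
# ---------------------------------------------------------------------------

def write_msh(mesh: TaggedMesh, path: str) -> None:
    """Write a TaggedMesh as Gmsh 4.1 ASCII with physical groups for tags."""
    dim = mesh.dim
    # physical groups: regions at dim, facet sets at dim-1
    region_ids = sorted(set(int(t) for t in mesh.region_tags))
    facet_names = [n for n in mesh.facet_tags if len(mesh.facet_tags[n])]
    phys = []  # (dim, tag, name)
    for r in region_ids:
        phys.append((dim, r, f"region_{r}"))
    for i, name in enumerate(facet_names):
        phys.append((dim - 1, 1000 + i, name))

    lines = ["$MeshFormat", "4.1 0 8", "$EndMeshFormat"]
    lines.append("$PhysicalNames")
    lines.append(str(len(phys)))
    for d, tag, name in phys:
        lines.append(f'{d} {tag} "{name}"')
    lines.append("$EndPhysicalNames")

    # one discrete entity per physical group; entity tag == physical tag
    npt = [0, 0, 0, 0]
    for d, _, _ in phys:
        npt[d] += 1
    # a point entity to own the nodes block
    lines.append("$Entities")
    lines.append(f"{npt[0] + 1} {npt[1]} {npt[2]} {npt[3]}")
    lines.append("1 0 0 0 0")  # point entity 1, no physical tag
    for d in (1, 2, 3):
        for pd, tag, _ in phys:
            if pd == d:
                lines.append(f"{tag} 0 0 0 0 0 0 1 {tag} 0")
    lines.append("$EndEntities")

    nv = mesh.num_vertices
    lines.append("$Nodes")
    lines.append(f"1 {nv} 1 {nv}")
    lines.append(f"0 1 0 {nv}")
    for i in range(nv):
        lines.append(str(i + 1))
    for i in range(nv):
        x = mesh.vertices[i]
        coords = [x[k] if k < dim else 0.0 for k in range(3)]
        lines.append(" ".join(_fmt(c) for c in coords))
    lines.append("$EndNodes")

    # element blocks: consecutive runs of equal region tag (preserves cell
    # order so that write->read round-trips connectivity bit-exactly)
    blocks = []
    rt = np.asarray(mesh.region_tags)
    run_starts = np.flatnonzero(np.r_[True, rt[1:] != rt[:-1]])
    run_ends = np.r_[run_starts[1:], len(rt)] if len(rt) else np.array([], dtype=int)
    for s, e in zip(run_starts, run_ends):
        blocks.append((dim, int(rt[s]), _CELL_TYPE[dim], mesh.cells[s:e]))
    for i, name in enumerate(facet_names):
        facs = np.asarray(mesh.facet_tags[name], dtype=np.int64).reshape(-1, dim)
        blocks.append((dim - 1, 1000 + i, _FACET_TYPE[dim], facs))

    nelem = sum(len(b[3]) for b in blocks)
    lines.append("$Elements")
    lines.append(f"{len(blocks)} {nelem} 1 {nelem}")
    tag = 1
    for d, etag, etype, conn in blocks:
        lines.append(f"{d} {etag} {etype} {len(conn)}")
        for row in conn:
            lines.append(str(tag) + " " + " ".join(str(v + 1) for v in row))
            tag += 1
    lines.append("$EndElements")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def read_msh(path: str) -> TaggedMesh:
    """Read the simplicial subset of Gmsh 4.1 ASCII back into a TaggedMesh."""
    with open(path) as fh:
        text = fh.read()
    sections = {}
    pos = 0
    while True:
        start = text.find("$", pos)
        if start < 0:
            break
        eol = text.index("\n", start)
        name = text[start + 1 : eol].strip()
        end = text.index(f"$End{name}", eol)
        sections[name] = text[eol + 1 : end].strip().splitlines()
        pos = end + len(name) + 4

    if "MeshFormat" not in sections:
        raise MeshFormatError(f"{path}: not a Gmsh mesh file")
    version = sections["MeshFormat"][0].split()
    if not version[0].startswith("4"):
        raise MeshFormatError(f"{path}: unsupported msh version {version[0]}")
    if version[1] != "0":
        raise MeshFormatError(f"{path}: binary msh is not supported")

    phys_names = {}  # (dim, tag) -> name
    if "PhysicalNames" in sections:
        rows = sections["PhysicalNames"]
        for line in rows[1 : 1 + int(rows[0])]:
            parts = line.split(None, 2)
            phys_names[(int(parts[0]), int(parts[1]))] = parts[2].strip().strip('"')

    # entity -> physical tag
    ent_phys = {}
    if "Entities" in sections:
        rows = sections["Entities"]
        counts = list(map(int, rows[0].split()))
        i = 1
        for d, n in enumerate(counts):
            for _ in range(n):
                parts = rows[i].split()
                i += 1
                tag = int(parts[0])
                if d == 0:
                    nphys = int(parts[4]) if len(parts) > 4 else 0
                    ptags = [int(p) for p in parts[5 : 5 + nphys]]
                else:
                    nphys = int(parts[7])
                    ptags = [int(p) for p in parts[8 : 8 + nphys]]
                if ptags:
                    ent_phys[(d, tag)] = ptags[0]

    # nodes
    rows = sections["Nodes"]
    header = rows[0].split()
    nblocks, nnodes = int(header[0]), int(header[1])
    coords = np.zeros((nnodes, 3))
    tag_to_index = {}
    i = 1
    count = 0
    for _ in range(nblocks):
        bh = rows[i].split()
        i += 1
        nb = int(bh[3])
        tags = [int(rows[i + k]) for k in range(nb)]
        i += nb
        for k in range(nb):
            coords[count + k] = [float(v) for v in rows[i + k].split()[:3]]
            tag_to_index[tags[k]] = count + k
        i += nb
        count += nb

    # elements
    rows = sections["Elements"]
    nblocks = int(rows[0].split()[0])
    i = 1
    by_type: dict = {}
    for _ in range(nblocks):
        bh = rows[i].split()
        i += 1
        edim, etag, etype, nb = int(bh[0]), int(bh[1]), int(bh[2]), int(bh[3])
        if etype not in _TYPE_NNODES:
            raise MeshFormatError(
                f"{path}: unsupported element type {etype} (only simplices)"
            )
        nn = _TYPE_NNODES[etype]
        conn = np.empty((nb, nn), dtype=np.int64)
        for k in range(nb):
            parts = rows[i + k].split()
            conn[k] = [tag_to_index[int(p)] for p in parts[1 : 1 + nn]]
        i += nb
        phys = ent_phys.get((edim, etag), etag)
        by_type.setdefault(etype, []).append((phys, conn))

    if _GMSH_TET in by_type:
        dim = 3
    elif _GMSH_TRI in by_type:
        dim = 2
    else:
        raise MeshFormatError(f"{path}: no supported cells found")

    vertices = coords[:, :dim].copy()
    cell_type = _CELL_TYPE[dim]
    facet_type = _FACET_TYPE[dim]

    cell_blocks = by_type.get(cell_type, [])
    cells = np.vstack([c for _, c in cell_blocks])
    region_tags = np.concatenate(
        [np.full(len(c), p, dtype=np.int64) for p, c in cell_blocks]
    )
    facet_tags = {}
    for p, conn in by_type.get(facet_type, []) if dim > 1 else []:
        name = phys_names.get((dim - 1, p), f"facets_{p}")
        facet_tags.setdefault(name, []).append(conn)
    facet_tags = {k: np.vstack(v) for k, v in facet_tags.items()}

    return TaggedMesh(vertices, cells, region_tags, facet_tags)


# ---------------------------------------------------------------------------
# XDMF + HDF5
# ---------------------------------------------------------------------------

def write_xdmf(mesh: TaggedMesh, path: str, fields: dict | None = None) -> None:
    """Write mesh (and optional named arrays) as XDMF XML + an HDF5 sidecar."""
    import h5py

    h5path = os.path.splitext(path)[0] + ".h5"
    with h5py.File(h5path, "w") as h5:
        h5.create_dataset("vertices", data=mesh.vertices)
        h5.create_dataset("cells", data=mesh.cells)
        h5.create_dataset("region_tags", data=mesh.region_tags)
        for name, facs in mesh.facet_tags.items():
            h5.create_dataset(f"facets/{name}", data=np.asarray(facs))
        for name, arr in (fields or {}).items():
            h5.create_dataset(f"fields/{name}", data=np.asarray(arr))

    topo = "Tetrahedron" if mesh.dim == 3 else "Triangle"
    h5name = os.path.basename(h5path)
    root = ET.Element("Xdmf", Version="3.0")
    dom = ET.SubElement(root, "Domain")
    grid = ET.SubElement(dom, "Grid", Name="mesh", GridType="Uniform")
    t = ET.SubElement(
        grid, "Topology", TopologyType=topo,
        NumberOfElements=str(mesh.num_cells),
    )
    di = ET.SubElement(
        t, "DataItem", Dimensions=f"{mesh.num_cells} {mesh.dim + 1}",
        NumberType="Int", Format="HDF",
    )
    di.text = f"{h5name}:/cells"
    g = ET.SubElement(grid, "Geometry", GeometryType="XYZ" if mesh.dim == 3 else "XY")
    di = ET.SubElement(
        g, "DataItem", Dimensions=f"{mesh.num_vertices} {mesh.dim}", Format="HDF"
    )
    di.text = f"{h5name}:/vertices"
    ET.ElementTree(root).write(path, xml_declaration=True)


def write_field_series(path: str, mesh: TaggedMesh, times, field_series) -> None:
    """Write a time series of named vertex/cell fields (XDMF temporal + HDF5).

    ``field_series`` is a sequence of dicts (one per time) mapping field
    names to arrays.  The mesh connectivity is stored once; readers get the
    arrays back bit-exactly via :func:`read_field_series`.
    """
    import h5py

    h5path = os.path.splitext(path)[0] + ".h5"
    with h5py.File(h5path, "w") as h5:
        h5.create_dataset("vertices", data=mesh.vertices)
        h5.create_dataset("cells", data=mesh.cells)
        h5.create_dataset("region_tags", data=mesh.region_tags)
        h5.create_dataset("times", data=np.asarray(times, dtype=float))
        for i, fields in enumerate(field_series):
            for name, arr in fields.items():
                h5.create_dataset(f"series/{i:05d}/{name}", data=np.asarray(arr))

    topo = "Tetrahedron" if mesh.dim == 3 else "Triangle"
    h5name = os.path.basename(h5path)
    root = ET.Element("Xdmf", Version="3.0")
    dom = ET.SubElement(root, "Domain")
    coll = ET.SubElement(dom, "Grid", Name="series", GridType="Collection",
                         CollectionType="Temporal")
    for i, t in enumerate(times):
        grid = ET.SubElement(coll, "Grid", Name=f"step{i}", GridType="Uniform")
        ET.SubElement(grid, "Time", Value=_fmt(float(t)))
        topo_el = ET.SubElement(grid, "Topology", TopologyType=topo,
                                NumberOfElements=str(mesh.num_cells))
        di = ET.SubElement(topo_el, "DataItem",
                           Dimensions=f"{mesh.num_cells} {mesh.dim + 1}",
                           NumberType="Int", Format="HDF")
        di.text = f"{h5name}:/cells"
        geo = ET.SubElement(grid, "Geometry",
                            GeometryType="XYZ" if mesh.dim == 3 else "XY")
        di = ET.SubElement(geo, "DataItem",
                           Dimensions=f"{mesh.num_vertices} {mesh.dim}",
                           Format="HDF")
        di.text = f"{h5name}:/vertices"
        for name in field_series[i]:
            arr = np.asarray(field_series[i][name])
            center = "Node" if arr.shape[0] == mesh.num_vertices else "Cell"
            att = ET.SubElement(grid, "Attribute", Name=name, Center=center)
            dims = " ".join(str(s) for s in arr.shape)
            di = ET.SubElement(att, "DataItem", Dimensions=dims, Format="HDF")
            di.text = f"{h5name}:/series/{i:05d}/{name}"
    ET.ElementTree(root).write(path, xml_declaration=True)


def read_field_series(path: str):
    """Read back (mesh, times, field_series) written by write_field_series."""
    import h5py

    h5path = os.path.splitext(path)[0] + ".h5"
    if not os.path.exists(h5path):
        raise MeshFormatError(f"missing HDF5 sidecar for {path}")
    with h5py.File(h5path, "r") as h5:
        mesh = TaggedMesh(h5["vertices"][...], h5["cells"][...],
                          h5["region_tags"][...], {})
        times = h5["times"][...]
        series = []
        if "series" in h5:
            for key in sorted(h5["series"]):
                series.append({n: h5[f"series/{key}/{n}"][...]
                               for n in h5[f"series/{key}"]})
    return mesh, times, series


def read_xdmf(path: str) -> tuple:
    """Read back a mesh (+fields dict) written by :func:`write_xdmf`."""
    import h5py

    h5path = os.path.splitext(path)[0] + ".h5"
    if not os.path.exists(h5path):
        raise MeshFormatError(f"missing HDF5 sidecar for {path}")
    with h5py.File(h5path, "r") as h5:
        vertices = h5["vertices"][...]
        cells = h5["cells"][...]
        region_tags = h5["region_tags"][...]
        facet_tags = {}
        if "facets" in h5:
            for name in h5["facets"]:
                facet_tags[name] = h5[f"facets/{name}"][...]
        fields = {}
        if "fields" in h5:
            for name in h5["fields"]:
                fields[name] = h5[f"fields/{name}"][...]
    return TaggedMesh(vertices, cells, region_tags, facet_tags), fields


# ---------------------------------------------------------------------------
# VTU / PVD (ASCII XML)
# ---------------------------------------------------------------------------

_VTK_TYPE = {2: 5, 3: 10}  # triangle, tetra


def write_vtu(
    mesh: TaggedMesh,
    path: str,
    point_data: dict | None = None,
    cell_data: dict | None = None,
) -> None:
    """Write an ASCII VTU snapshot readable by ParaView/VisIt."""
    dim = mesh.dim
    nv, nc = mesh.num_vertices, mesh.num_cells

    def data_array(parent, name, arr, ncomp):
        da = ET.SubElement(
            parent, "DataArray", type="Float64", Name=name,
            NumberOfComponents=str(ncomp), format="ascii",
        )
        da.text = " ".join(_fmt(v) for v in np.asarray(arr, dtype=float).ravel())
        return da

    root = ET.Element("VTKFile", type="UnstructuredGrid", version="0.1")
    ug = ET.SubElement(root, "UnstructuredGrid")
    piece = ET.SubElement(ug, "Piece", NumberOfPoints=str(nv), NumberOfCells=str(nc))

    pts = ET.SubElement(piece, "Points")
    coords3 = np.zeros((nv, 3))
    coords3[:, :dim] = mesh.vertices
    data_array(pts, "Points", coords3, 3)

    cells_el = ET.SubElement(piece, "Cells")
    conn = ET.SubElement(
        cells_el, "DataArray", type="Int64", Name="connectivity", format="ascii"
    )
    conn.text = " ".join(str(v) for v in mesh.cells.ravel())
    offs = ET.SubElement(
        cells_el, "DataArray", type="Int64", Name="offsets", format="ascii"
    )
    offs.text = " ".join(str((i + 1) * (dim + 1)) for i in range(nc))
    types = ET.SubElement(
        cells_el, "DataArray", type="UInt8", Name="types", format="ascii"
    )
    types.text = " ".join(str(_VTK_TYPE[dim]) for _ in range(nc))

    pd = ET.SubElement(piece, "PointData")
    for name, arr in (point_data or {}).items():
        arr = np.asarray(arr, dtype=float)
        if arr.ndim == 2:  # pad vectors to 3 components for VTK
            a3 = np.zeros((nv, 3))
            a3[:, : arr.shape[1]] = arr
            data_array(pd, name, a3, 3)
        else:
            data_array(pd, name, arr, 1)
    cd = ET.SubElement(piece, "CellData")
    for name, arr in (cell_data or {}).items():
        data_array(cd, name, np.asarray(arr, dtype=float), 1)

    ET.ElementTree(root).write(path, xml_declaration=True)


def write_pvd(path: str, entries: list) -> None:
    """Write a PVD collection; ``entries`` is a list of (time, vtu_filename)."""
    root = ET.Element("VTKFile", type="Collection", version="0.1")
    coll = ET.SubElement(root, "Collection")
    for t, fname in entries:
        ET.SubElement(coll, "DataSet", timestep=_fmt(t), part="0", file=fname)
    ET.ElementTree(root).write(path, xml_declaration=True)


# ---------------------------------------------------------------------------
# dispatch
# ---------------------------------------------------------------------------

def read_mesh(path: str, fmt: str | None = None) -> TaggedMesh:
    """Read a mesh file; format inferred from the extension unless given."""
    if not os.path.exists(path):
        raise MeshFormatError(f"mesh file not found: {path}")
    fmt = fmt or os.path.splitext(path)[1].lstrip(".")
    if fmt == "msh":
        m = read_msh(path)
    elif fmt == "xdmf":
        m, _ = read_xdmf(path)
    else:
        raise MeshFormatError(f"unsupported mesh format: {fmt!r}")
    m.cells = orient_cells(m.vertices, m.cells)
    return m


def write_mesh(mesh: TaggedMesh, path: str, fmt: str | None = None) -> None:
    fmt = fmt or os.path.splitext(path)[1].lstrip(".")
    if fmt == "msh":
        write_msh(mesh, path)
    elif fmt == "xdmf":
        write_xdmf(mesh, path)
    elif fmt == "vtu":
        write_vtu(mesh, path)
    else:
        raise MeshFormatError(f"unsupported mesh format: {fmt!r}")
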