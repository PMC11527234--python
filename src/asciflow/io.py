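"""Mesh and field output in standard exchange formats.

Writes ASCII VTK XML unstructured grids (.vtu), a matching ParaView
collection (.pvd) for time series, and a minimal Gmsh v2.2 ASCII reader and
writer (.msh) so user-supplied meshes with physical groups can enter the
pipeline.  Patch labels travel as an integer facet field plus a name table.
"""

from __future__ import annotations

import os
from xml.sax.saxutils import escape

import numpy as np

from .geometry import Mesh

_VTK_CELL = {(2, 3): 5, (3, 4): 10, (2, 2): 3, (3, 3): 5}  # (dim, nverts)


def _pad3(points: np.ndarray) -> np.ndarray:
    if points.shape[1] == 3:
        return points
    return np.hstack([points, np.zeros((len(points), 1))])


def _arr(a: np.ndarray) -> str:
    return "\n".join(" ".join(repr(float(x)) for x in row)
                     for row in np.atleast_2d(a))


def write_vtu(path: str, mesh: Mesh, point_data: dict | None = None,
              cell_data: dict | None = None,
              use_boundary: bool = False) -> None:
    """Write the mesh (or its boundary when ``use_boundary``) as ASCII VTU.

    ``point_data`` maps names to (n_nodes,) or (n_nodes, dim) arrays; vector
    fields are padded to 3 components.  When writing the boundary, a
    ``patch_id`` cell array and a name table comment are included
    automatically.
    """
    if use_boundary:
        cells = mesh.boundary_facets
        names = sorted(set(mesh.facet_patches.tolist()))
        ids = {n: i for i, n in enumerate(names)}
        cdata = dict(cell_data or {})
        cdata["patch_id"] = np.array([ids[p] for p in mesh.facet_patches])
        comment = "patches: " + ", ".join(f"{i}={n}"
                                          for n, i in ids.items())
    else:
        cells = mesh.cells
        cdata = dict(cell_data or {})
        comment = ""
    ctype = _VTK_CELL[(mesh.dim, cells.shape[1])]
    pts = _pad3(mesh.points)
    n_pts, n_cells = len(pts), len(cells)
    with open(path, "w") as f:
        f.write('<?xml version="1.0"?>\n')
        if comment:
            f.write(f"<!-- {escape(comment)} -->\n")
        f.write('<VTKFile type="UnstructuredGrid" version="0.1" '
                'byte_order="LittleEndian">\n<UnstructuredGrid>\n')
        f.write(f'<Piece NumberOfPoints="{n_pts}" '
                f'NumberOfCells="{n_cells}">\n')
        f.write('<Points>\n<DataArray type="Float64" '
                'NumberOfComponents="3" format="ascii">\n')
        f.write(_arr(pts))
        f.write("\n</DataArray>\n</Points>\n<Cells>\n")
        f.write('<DataArray type="Int64" Name="connectivity" '
                'format="ascii">\n')
        f.write("\n".join(" ".join(str(v) for v in c) for c in cells))
        f.write('\n</DataArray>\n<DataArray type="Int64" Name="offsets" '
                'format="ascii">\n')
        f.write(" ".join(str((i + 1) * cells.shape[1])
                         for i in range(n_cells)))
        f.write('\n</DataArray>\n<DataArray type="UInt8" Name="types" '
                'format="ascii">\n')
        f.write(" ".join(str(ctype) for _ in range(n_cells)))
        f.write("\n</DataArray>\n</Cells>\n")
        f.write("<PointData>\n")
        for name, arr in (point_data or {}).items():
            arr = np.asarray(arr, float)
            if arr.ndim == 1:
                f.write(f'<DataArray type="Float64" Name="{name}" '
                        'format="ascii">\n')
                f.write(" ".join(repr(float(x)) for x in arr))
            else:
                f.write(f'<DataArray type="Float64" Name="{name}" '
                        'NumberOfComponents="3" format="ascii">\n')
                f.write(_arr(_pad3(arr)))
            f.write("\n</DataArray>\n")
        f.write("</PointData>\n<CellData>\n")
        for name, arr in cdata.items():
            f.write(f'<DataArray type="Float64" Name="{name}" '
                    'format="ascii">\n')
            f.write(" ".join(repr(float(x)) for x in np.asarray(arr).ravel()))
            f.write("\n</DataArray>\n")
        f.write("</CellData>\n</Piece>\n</UnstructuredGrid>\n</VTKFile>\n")


def write_pvd(path: str, entries: list[tuple[float, str]]) -> None:
    """ParaView collection file: entries are (time, vtu filename)."""
    with open(path, "w") as f:
        f.write('<?xml version="1.0"?>\n<VTKFile type="Collection" '
                'version="0.1">\n<Collection>\n')
        for t, fn in entries:
            f.write(f'<DataSet timestep="{float(t)!r}" '
                    f'file="{escape(fn)}"/>\n')
        f.write("</Collection>\n</VTKFile>\n")


# ---------------------------------------------------------------------------
# Gmsh v2.2 ASCII
# ---------------------------------------------------------------------------

_MSH_ELEM = {1: 2, 2: 3, 4: 4}          # gmsh type -> nverts (line, tri, tet)
_MSH_TYPE_OF = {2: {2: 1, 3: 2}, 3: {3: 2, 4: 4}}


def write_msh(path: str, mesh: Mesh) -> None:
    """Minimal Gmsh v2.2 writer; patches become physical groups of facets."""
    names = sorted(set(mesh.facet_patches.tolist()))
    pid = {n: i + 1 for i, n in enumerate(names)}
    vol_tag = len(names) + 1
    with open(path, "w") as f:
        f.write("$MeshFormat\n2.2 0 8\n$EndMeshFormat\n")
        f.write("$PhysicalNames\n%d\n" % (len(names) + 1))
        fdim = mesh.dim - 1
        for n in names:
            f.write(f'{fdim} {pid[n]} "{n}"\n')
        f.write(f'{mesh.dim} {vol_tag} "volume"\n$EndPhysicalNames\n')
        f.write("$Nodes\n%d\n" % mesh.n_nodes)
        pts = _pad3(mesh.points)
        for i, p in enumerate(pts, 1):
            f.write(f"{i} {float(p[0])!r} {float(p[1])!r} {float(p[2])!r}\n")
        f.write("$EndNodes\n$Elements\n%d\n"
                % (len(mesh.boundary_facets) + mesh.n_cells))
        eid = 1
        ftype = _MSH_TYPE_OF[mesh.dim][mesh.boundary_facets.shape[1]]
        for facet, patch in zip(mesh.boundary_facets, mesh.facet_patches):
            verts = " ".join(str(v + 1) for v in facet)
            f.write(f"{eid} {ftype} 2 {pid[patch]} {pid[patch]} {verts}\n")
            eid += 1
        ctype = _MSH_TYPE_OF[mesh.dim][mesh.cells.shape[1]]
        for cell in mesh.cells:
            verts = " ".join(str(v + 1) for v in cell)
            f.write(f"{eid} {ctype} 2 {vol_tag} {vol_tag} {verts}\n")
            eid += 1
        f.write("$EndElements\n")


def read_msh(path: str) -> Mesh:
    """Read a Gmsh v2.2 ASCII mesh with physical-group facet labels."""
    with open(path) as f:
        lines = f.read().splitlines()
    i = 0
    names: dict[int, str] = {}
    nodes: list[list[float]] = []
    elems: list[tuple[int, int, list[int]]] = []
    while i < len(lines):
        line = lines[i].strip()
        if line == "$PhysicalNames":
            n = int(lines[i + 1])
            for j in range(n):
                parts = lines[i + 2 + j].split()
                names[int(parts[1])] = parts[2].strip('"')
            i += n + 2
        elif line == "$Nodes":
            n = int(lines[i + 1])
            for j in range(n):
                parts = lines[i + 2 + j].split()
                nodes.append([float(x) for x in parts[1:4]])
            i += n + 2
        elif line == "$Elements":
            n = int(lines[i + 1])
            for j in range(n):
                parts = [int(x) for x in lines[i + 2 + j].split()]
                etype, ntags = parts[1], parts[2]
                tag = parts[3] if ntags else 0
                verts = [v - 1 for v in parts[3 + ntags:]]
                elems.append((etype, tag, verts))
            i += n + 2
        else:
            i += 1
    points = np.array(nodes)
    tets = [v for t, _, v in elems if t == 4]
    tris = [(tag, v) for t, tag, v in elems if t == 2]
    lin = [(tag, v) for t, tag, v in elems if t == 1]
    if tets:
        dim = 3
        cells = np.array(tets)
        facets = np.array([v for _, v in tris])
        tags = [tag for tag, _ in tris]
    elif tris and lin:
        dim = 2
        cells = np.array([v for _, v in tris])
        facets = np.array([v for _, v in lin])
        tags = [tag for tag, _ in lin]
    else:
        raise ValueError("mesh must contain volume cells and labelled facets")
    if points.shape[1] == 3 and dim == 2:
        points = points[:, :2]
    patches = np.array([names.get(t, f"patch_{t}") for t in tags])
    from .geometry import _orient_cells, _orient_boundary_outward
    cells = _orient_cells(points, cells)
    facets = _orient_boundary_outward(points, cells, facets)
    mesh = Mesh(points, cells, facets, patches, dim)
    mesh.validate()
    return mesh


def export_history(out_dir: str, mesh: Mesh, history, stride: int = 1,
                   prefix: str = "flow") -> str:
    """Write a flow history as a VTU series + PVD collection; returns PVD path."""
    os.makedirs(out_dir, exist_ok=True)
    entries = []
    nv = mesh.n_nodes
    for k, state in enumerate(history.states[::stride]):
        fn = f"{prefix}_{k:04d}.vtu"
        disp = state.mesh_displacement
        moved = mesh.displaced(disp)
        write_vtu(os.path.join(out_dir, fn), moved, point_data={
            "velocity_m_s": state.velocity[:nv],
            "pressure_pa_p1": state.pressure[:nv],
            "mesh_displacement_m": disp,
        })
        entries.append((state.time, fn))
    pvd = os.path.join(out_dir, f"{prefix}.pvd")
    write_pvd(pvd, entries)
    return pvd
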