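"""Mesh and field exchange in standard text formats.

Writes VTK XML unstructured grids (.vtu, ascii) with nodal velocity and
pressure, a PVD collection index for time series, and reads Gmsh v2.2 ascii
meshes.  Coordinates and connectivity round-trip exactly through the
writer/reader pair (full repr precision).
"""

from __future__ import annotations

import os
import xml.etree.ElementTree as ET

import numpy as np

from .assembly import State
from .mesh import Mesh

__all__ = ["write_vtu", "read_vtu", "write_fields", "write_pvd", "read_gmsh"]

_VTK_CELL = {2: 5, 3: 10}  # triangle, tetrahedron


def _fmt(arr: np.ndarray) -> str:
    return "\n".join(" ".join(repr(float(v)) for v in row)
                     for row in np.atleast_2d(arr))


def write_vtu(mesh: Mesh, path, point_data: dict | None = None) -> None:
    """Write the mesh and optional nodal fields as ascii XML .vtu."""
    point_data = point_data or {}
    nn, ne = mesh.n_nodes, mesh.n_el
    xyz = np.zeros((nn, 3))
    xyz[:, :mesh.dim] = mesh.nodes
    lines = [
        '<?xml version="1.0"?>',
        '<VTKFile type="UnstructuredGrid" version="0.1" '
        'byte_order="LittleEndian">',
        "<UnstructuredGrid>",
        f'<Piece NumberOfPoints="{nn}" NumberOfCells="{ne}">',
        "<Points>",
        '<DataArray type="Float64" NumberOfComponents="3" format="ascii">',
        _fmt(xyz),
        "</DataArray>", "</Points>", "<Cells>",
        '<DataArray type="Int64" Name="connectivity" format="ascii">',
        "\n".join(" ".join(str(i) for i in el) for el in mesh.elements),
        "</DataArray>",
        '<DataArray type="Int64" Name="offsets" format="ascii">',
        " ".join(str((mesh.dim + 1) * (i + 1)) for i in range(ne)),
        "</DataArray>",
        '<DataArray type="UInt8" Name="types" format="ascii">',
        " ".join(str(_VTK_CELL[mesh.dim]) for _ in range(ne)),
        "</DataArray>", "</Cells>", "<PointData>",
    ]
    for name, arr in point_data.items():
        arr = np.asarray(arr, dtype=np.float64)
        ncomp = 1 if arr.ndim == 1 else arr.shape[1]
        if ncomp == 2:  # pad 2D vectors for VTK
            arr = np.column_stack([arr, np.zeros(arr.shape[0])])
            ncomp = 3
        lines += [
            f'<DataArray type="Float64" Name="{name}" '
            f'NumberOfComponents="{ncomp}" format="ascii">',
            _fmt(arr), "</DataArray>"]
    lines += ["</PointData>", "</Piece>", "</UnstructuredGrid>", "</VTKFile>"]
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def read_vtu(path):
    """Read a .vtu written by :func:`write_vtu`.

    Returns (points (n,3), connectivity (ne, k), {name: array}).
    """
    root = ET.parse(path).getroot()
    piece = root.find(".//Piece")
    nn = int(piece.get("NumberOfPoints"))
    ne = int(piece.get("NumberOfCells"))
    pts = np.fromstring(piece.find("./Points/DataArray").text.replace(
        "\n", " "), sep=" ").reshape(nn, 3)
    cells = {d.get("Name"): d for d in piece.findall("./Cells/DataArray")}
    conn = np.fromstring(cells["connectivity"].text.replace("\n", " "),
                         dtype=np.int64, sep=" ")
    offsets = np.fromstring(cells["offsets"].text.replace("\n", " "),
                            dtype=np.int64, sep=" ")
    k = int(offsets[0])
    conn = conn.reshape(ne, k)
    fields = {}
    for d in piece.findall("./PointData/DataArray"):
        arr = np.fromstring(d.text.replace("\n", " "), sep=" ")
        ncomp = int(d.get("NumberOfComponents", "1"))
        fields[d.get("Name")] = arr.reshape(nn, ncomp) if ncomp > 1 else arr
    return pts, conn, fields


def write_fields(mesh: Mesh, state: State, path) -> None:
    """Write mesh plus nodal velocity/pressure of a State to .vtu."""
    if state.u.shape != (mesh.n_nodes, mesh.dim) \
            or state.p.shape != (mesh.n_nodes,):
        raise ValueError("state arrays do not match the mesh")
    write_vtu(mesh, path, {"velocity": state.u, "pressure": state.p})


def write_pvd(entries: list[tuple[float, str]], path) -> None:
    """Write a ParaView collection index of (time, vtu file) pairs."""
    lines = ['<?xml version="1.0"?>',
             '<VTKFile type="Collection" version="0.1">', "<Collection>"]
    for t, fname in entries:
        lines.append(f'<DataSet timestep="{t!r}" file="{os.path.basename(fname)}"/>')
    lines += ["</Collection>", "</VTKFile>"]
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def read_gmsh(path) -> tuple[np.ndarray, np.ndarray, int]:
    """Read nodes and highest-dimensional simplex elements from a Gmsh v2.2
    ascii file.  Returns (nodes (n, dim), elements, dim); node indices are
    converted to 0-based."""
    with open(path) as fh:
        lines = [ln.strip() for ln in fh]
    def section(name):
        i = lines.index(f"${name}")
        j = lines.index(f"$End{name}")
        return lines[i + 1:j]
    nodes_sec = section("Nodes")
    n = int(nodes_sec[0])
    coords = np.array([[float(v) for v in ln.split()[1:4]]
                       for ln in nodes_sec[1:n + 1]])
    elems_sec = section("Elements")
    ne = int(elems_sec[0])
    tris, tets = [], []
    for ln in elems_sec[1:ne + 1]:
        parts = [int(v) for v in ln.split()]
        etype, ntags = parts[1], parts[2]
        conn = [v - 1 for v in parts[3 + ntags:]]
        if etype == 2:
            tris.append(conn)
        elif etype == 4:
            tets.append(conn)
    if tets:
        return coords, np.array(tets, dtype=np.int64), 3
    if tris:
        return coords[:, :2], np.array(tris, dtype=np.int64), 2
    raise ValueError("no triangle or tetrahedron elements found")
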