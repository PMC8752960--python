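"""Mesh and table I/O.

Meshes travel as ASCII VTU unstructured grids (tetrahedra plus labelled
boundary triangles in one piece, with "fibre" and "label" cell arrays) or as
the CARP-style .pts/.elem/.lon text triple (0-based node indices).  Tables
are tidy CSV, manifests JSON.
"""

from __future__ import annotations

import json
import xml.etree.ElementTree as ET
from pathlib import Path

import numpy as np
import pandas as pd

from .anatomy import VentricularMesh

__all__ = [
    "write_vtu",
    "read_vtu",
    "write_carp",
    "read_carp",
    "write_coordinates_csv",
    "write_response_csv",
    "write_manifest",
]

VTK_TETRA = 10
VTK_TRIANGLE = 5


def _fmt(a: np.ndarray) -> str:
    return "\n".join(
        " ".join(repr(float(x)) if isinstance(x, (float, np.floating)) else str(int(x)) for x in row)
        for row in np.atleast_2d(a)
    )


def write_vtu(
    mesh: VentricularMesh, path, point_data: dict | None = None, cell_data: dict | None = None
) -> None:
    """Write the mesh (tets + boundary tris) as an ASCII VTU file.

    Cell arrays cover tetrahedra first, then boundary triangles: "label"
    holds the element region for tets and the surface label for triangles;
    "fibre" holds per-tet fibres (zero for triangles).  Extra per-node /
    per-tet arrays go in ``point_data`` / ``cell_data``.
    """
    path = Path(path)
    n_pts = mesh.n_nodes
    n_tet = mesh.n_elements
    n_tri = len(mesh.surface_triangles)
    conn = np.concatenate(
        [mesh.tetrahedra.ravel(), mesh.surface_triangles.ravel()]
    )
    offsets = np.concatenate(
        [4 * (np.arange(n_tet) + 1), 4 * n_tet + 3 * (np.arange(n_tri) + 1)]
    )
    types = np.concatenate(
        [np.full(n_tet, VTK_TETRA), np.full(n_tri, VTK_TRIANGLE)]
    )
    label = np.concatenate([mesh.element_region, mesh.surface_labels])
    fibre = np.concatenate([mesh.element_fibre, np.zeros((n_tri, 3))])

    lines = [
        '<?xml version="1.0"?>',
        '<VTKFile type="UnstructuredGrid" version="0.1" byte_order="LittleEndian">',
        "<UnstructuredGrid>",
        f'<Piece NumberOfPoints="{n_pts}" NumberOfCells="{n_tet + n_tri}">',
        "<Points>",
        '<DataArray type="Float64" NumberOfComponents="3" format="ascii">',
        _fmt(mesh.node_coordinates),
        "</DataArray>",
        "</Points>",
        "<Cells>",
        '<DataArray type="Int64" Name="connectivity" format="ascii">',
        " ".join(map(str, conn.tolist())),
        "</DataArray>",
        '<DataArray type="Int64" Name="offsets" format="ascii">',
        " ".join(map(str, offsets.tolist())),
        "</DataArray>",
        '<DataArray type="UInt8" Name="types" format="ascii">',
        " ".join(map(str, types.tolist())),
        "</DataArray>",
        "</Cells>",
    ]
    lines.append("<CellData>")
    lines.append('<DataArray type="Int64" Name="label" format="ascii">')
    lines.append(" ".join(map(str, label.astype(int).tolist())))
    lines.append("</DataArray>")
    lines.append('<DataArray type="Float64" Name="fibre" NumberOfComponents="3" format="ascii">')
    lines.append(_fmt(fibre))
    lines.append("</DataArray>")
    for name, arr in (cell_data or {}).items():
        arr = np.asarray(arr, dtype=float)
        full = np.concatenate([arr, np.full(n_tri, np.nan)])
        lines.append(f'<DataArray type="Float64" Name="{name}" format="ascii">')
        lines.append(" ".join(repr(float(x)) for x in full.tolist()))
        lines.append("</DataArray>")
    lines.append("</CellData>")
    if point_data:
        lines.append("<PointData>")
        for name, arr in point_data.items():
            arr = np.asarray(arr, dtype=float)
            lines.append(f'<DataArray type="Float64" Name="{name}" format="ascii">')
            lines.append(" ".join(repr(float(x)) for x in arr.tolist()))
            lines.append("</DataArray>")
        lines.append("</PointData>")
    lines += ["</Piece>", "</UnstructuredGrid>", "</VTKFile>"]
    path.write_text("\n".join(lines))


def read_vtu(path) -> tuple[VentricularMesh, dict, dict]:
    """Read an ASCII VTU written by :func:`write_vtu` (or compatible).

    Returns (mesh, point_data, cell_data); cell_data arrays are restricted
    to the tetrahedra.  Only ascii-format DataArrays are supported.
    """
    root = ET.parse(str(path)).getroot()
    piece = root.find(".//Piece")

    def parse(da):
        if da.get("format", "ascii") != "ascii":
            raise ValueError("only ascii VTU DataArrays are supported")
        vals = np.fromstring(da.text.replace("\n", " "), sep=" ")
        nc = int(da.get("NumberOfComponents", 1))
        return vals.reshape(-1, nc) if nc > 1 else vals

    points = parse(piece.find("Points/DataArray"))
    arrays = {da.get("Name"): da for da in piece.findall("Cells/DataArray")}
    conn = parse(arrays["connectivity"]).astype(np.int64)
    offsets = parse(arrays["offsets"]).astype(np.int64)
    types = parse(arrays["types"]).astype(np.int64)

    cells = np.split(conn, offsets[:-1])
    tets = np.array([c for c, t in zip(cells, types) if t == VTK_TETRA], dtype=np.int64)
    tris = np.array([c for c, t in zip(cells, types) if t == VTK_TRIANGLE], dtype=np.int64)
    if tris.size == 0:
        tris = tris.reshape(0, 3)

    point_data = {}
    pd_el = piece.find("PointData")
    if pd_el is not None:
        for da in pd_el.findall("DataArray"):
            point_data[da.get("Name")] = parse(da)
    cell_data = {}
    cd_el = piece.find("CellData")
    if cd_el is not None:
        for da in cd_el.findall("DataArray"):
            cell_data[da.get("Name")] = parse(da)

    n_tet = len(tets)
    label = cell_data.pop("label", np.zeros(n_tet + len(tris)))
    fibre = cell_data.pop("fibre", None)
    if fibre is None:
        fibre = np.tile([1.0, 0.0, 0.0], (n_tet, 1))
    else:
        fibre = np.asarray(fibre)[:n_tet]
    cell_data = {k: np.asarray(v)[:n_tet] for k, v in cell_data.items()}
    mesh = VentricularMesh(
        node_coordinates=points,
        tetrahedra=tets,
        element_fibre=fibre,
        element_region=np.asarray(label[:n_tet], dtype=np.int8),
        surface_triangles=tris,
        surface_labels=np.asarray(label[n_tet:], dtype=np.int8),
    )
    return mesh, point_data, cell_data


def write_carp(mesh: VentricularMesh, basename) -> None:
    """Write CARP-style .pts / .elem / .lon text files (0-based indices)."""
    base = Path(basename)
    with open(base.with_suffix(".pts"), "w") as f:
        f.write(f"{mesh.n_nodes}\n")
        for p in mesh.node_coordinates:
            f.write(f"{float(p[0])!r} {float(p[1])!r} {float(p[2])!r}\n")
    with open(base.with_suffix(".elem"), "w") as f:
        f.write(f"{mesh.n_elements}\n")
        for tet, reg in zip(mesh.tetrahedra, mesh.element_region):
            f.write(f"Tt {tet[0]} {tet[1]} {tet[2]} {tet[3]} {int(reg)}\n")
    with open(base.with_suffix(".lon"), "w") as f:
        f.write("1\n")
        for v in mesh.element_fibre:
            f.write(f"{float(v[0])!r} {float(v[1])!r} {float(v[2])!r}\n")
    # boundary triangles + labels in a .surf side file (no canonical slot in
    # the triple); read_carp rebuilds the mesh with them
    with open(base.with_suffix(".surf"), "w") as f:
        f.write(f"{len(mesh.surface_triangles)}\n")
        for tri, lab in zip(mesh.surface_triangles, mesh.surface_labels):
            f.write(f"Tr {tri[0]} {tri[1]} {tri[2]} {int(lab)}\n")


def read_carp(basename) -> VentricularMesh:
    """Read a CARP-style mesh triple written by :func:`write_carp`."""
    base = Path(basename)
    with open(base.with_suffix(".pts")) as f:
        n = int(f.readline())
        pts = np.loadtxt(f, max_rows=n).reshape(n, 3)
    tets, regs = [], []
    with open(base.with_suffix(".elem")) as f:
        n = int(f.readline())
        for _ in range(n):
            parts = f.readline().split()
            if parts[0] != "Tt":
                raise ValueError("only tetrahedral (Tt) elements are supported")
            tets.append([int(x) for x in parts[1:5]])
            regs.append(int(parts[5]) if len(parts) > 5 else 0)
    with open(base.with_suffix(".lon")) as f:
        f.readline()
        lon = np.loadtxt(f).reshape(len(tets), -1)[:, :3]
    tris, labs = [], []
    surf = base.with_suffix(".surf")
    if surf.exists():
        with open(surf) as f:
            n = int(f.readline())
            for _ in range(n):
                parts = f.readline().split()
                tris.append([int(x) for x in parts[1:4]])
                labs.append(int(parts[4]))
    tris = np.array(tris, dtype=np.int64).reshape(-1, 3)
    return VentricularMesh(
        node_coordinates=pts,
        tetrahedra=np.array(tets, dtype=np.int64),
        element_fibre=lon,
        element_region=np.array(regs, dtype=np.int8),
        surface_triangles=tris,
        surface_labels=np.array(labs, dtype=np.int8),
    )


def write_coordinates_csv(coords, aha, path) -> None:
    df = pd.DataFrame(
        {
            "node_id": np.arange(len(coords.z)),
            "z": coords.z,
            "rho": coords.rho,
            "phi": coords.phi,
            "nu": coords.nu,
            "segment": aha.segment if aha is not None else 0,
        }
    )
    df.to_csv(path, index=False)


def write_response_csv(matrix, path) -> None:
    matrix.records.to_csv(path, index=False)


def write_manifest(obj: dict, path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True, default=str))
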