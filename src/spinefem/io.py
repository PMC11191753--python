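"""Mesh and result export: ASCII VTU (with a matching reader), Gmsh MSH 4.1
and per-region STL surfaces, plus YAML round-tripping for run configs."""

from __future__ import annotations

import os
import xml.etree.ElementTree as ET
from typing import Dict, Optional

import numpy as np

from .meshing import Mesh

_VTK_TYPE = {4: 10, 10: 24}   # nodes per element -> VTK cell type


def write_vtu(mesh: Mesh, path: str,
              point_data: Optional[Dict[str, np.ndarray]] = None,
              cell_data: Optional[Dict[str, np.ndarray]] = None) -> str:
    """Write the mesh (plus optional fields) as an ASCII .vtu file."""
    n, e = mesh.n_nodes, mesh.n_elements
    npe = mesh.tets.shape[1]
    lines = ['<?xml version="1.0"?>',
             '<VTKFile type="UnstructuredGrid" version="0.1" '
             'byte_order="LittleEndian">',
             ' <UnstructuredGrid>',
             f'  <Piece NumberOfPoints="{n}" NumberOfCells="{e}">',
             '   <Points>',
             '    <DataArray type="Float64" NumberOfComponents="3" '
             'format="ascii">']
    lines += [" ".join(f"{v:.10g}" for v in row) for row in mesh.nodes]
    lines += ['    </DataArray>', '   </Points>', '   <Cells>',
              '    <DataArray type="Int64" Name="connectivity" '
              'format="ascii">']
    lines += [" ".join(str(int(v)) for v in row) for row in mesh.tets]
    lines += ['    </DataArray>',
              '    <DataArray type="Int64" Name="offsets" format="ascii">',
              " ".join(str(npe * (i + 1)) for i in range(e)),
              '    </DataArray>',
              '    <DataArray type="UInt8" Name="types" format="ascii">',
              " ".join(str(_VTK_TYPE[npe]) for _ in range(e)),
              '    </DataArray>', '   </Cells>']

    cell_data = dict(cell_data or {})
    cell_data.setdefault("region", mesh.region_ids.astype(np.int64))
    lines.append('   <CellData>')
    for name, arr in cell_data.items():
        arr = np.asarray(arr)
        typ = "Int64" if np.issubdtype(arr.dtype, np.integer) else "Float64"
        lines.append(f'    <DataArray type="{typ}" Name="{name}" '
                     f'format="ascii">')
        lines.append(" ".join(f"{v:.10g}" for v in arr))
        lines.append('    </DataArray>')
    lines.append('   </CellData>')

    point_data = dict(point_data or {})
    # surface groups exported as 0/1 point masks
    for gname, ids in mesh.node_sets.items():
        mask = np.zeros(n)
        mask[ids] = 1.0
        point_data.setdefault(f"set_{gname}", mask)
    lines.append('   <PointData>')
    for name, arr in point_data.items():
        arr = np.asarray(arr, dtype=float)
        nc = 1 if arr.ndim == 1 else arr.shape[1]
        lines.append(f'    <DataArray type="Float64" Name="{name}" '
                     f'NumberOfComponents="{nc}" format="ascii">')
        if arr.ndim == 1:
            lines.append(" ".join(f"{v:.10g}" for v in arr))
        else:
            lines += [" ".join(f"{v:.10g}" for v in row) for row in arr]
        lines.append('    </DataArray>')
    lines.append('   </PointData>')

    lines += ['  </Piece>', ' </UnstructuredGrid>', '</VTKFile>']
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")
    return path


def read_vtu(path: str):
    """Read an ASCII .vtu written by :func:`write_vtu`.

    Returns (nodes, cells, cell_data, point_data).
    """
    root = ET.parse(path).getroot()
    piece = root.find(".//Piece")

    def parse(elem, dtype=float):
        return np.fromstring(" ".join(elem.itertext()), sep=" ", dtype=float
                             ).astype(dtype)

    nodes = parse(piece.find("Points/DataArray")).reshape(-1, 3)
    arrays = {d.get("Name"): d for d in piece.findall("Cells/DataArray")}
    conn = parse(arrays["connectivity"], np.int64)
    offs = parse(arrays["offsets"], np.int64)
    npe = int(offs[0])
    cells = conn.reshape(-1, npe)
    cell_data = {}
    for d in piece.findall("CellData/DataArray"):
        dt = np.int64 if d.get("type") == "Int64" else float
        cell_data[d.get("Name")] = parse(d, dt)
    point_data = {}
    for d in piece.findall("PointData/DataArray"):
        nc = int(d.get("NumberOfComponents", "1"))
        arr = parse(d)
        point_data[d.get("Name")] = arr.reshape(-1, nc) if nc > 1 else arr
    return nodes, cells, cell_data, point_data


def write_msh(mesh: Mesh, path: str) -> str:
    """Write a minimal Gmsh MSH 4.1 ASCII file with region tags."""
    npe = mesh.tets.shape[1]
    etype = 4 if npe == 4 else 11
    # Gmsh TET10 edge-node ordering differs from VTK in the last three nodes
    perm = list(range(npe))
    if npe == 10:
        perm = [0, 1, 2, 3, 4, 5, 6, 7, 9, 8]
    out = ["$MeshFormat", "4.1 0 8", "$EndMeshFormat", "$Entities",
           f"0 0 0 {len(mesh.region_names)}"]
    for i, name in enumerate(mesh.region_names):
        out.append(f"{i + 1} 0 0 0 0 0 0 0 0")
    out.append("$EndEntities")
    out += ["$Nodes", f"1 {mesh.n_nodes} 1 {mesh.n_nodes}",
            f"3 1 0 {mesh.n_nodes}"]
    out += [str(i + 1) for i in range(mesh.n_nodes)]
    out += [" ".join(f"{v:.10g}" for v in row) for row in mesh.nodes]
    out.append("$EndNodes")
    blocks = []
    eid = 1
    present = [i for i in np.unique(mesh.region_ids)]
    body = []
    for rid in present:
        idx = np.flatnonzero(mesh.region_ids == rid)
        body.append(f"3 {rid + 1} {etype} {len(idx)}")
        for e in idx:
            conn = " ".join(str(int(mesh.tets[e, p]) + 1) for p in perm)
            body.append(f"{eid} {conn}")
            eid += 1
    out += ["$Elements",
            f"{len(present)} {mesh.n_elements} 1 {mesh.n_elements}"]
    out += body
    out.append("$EndElements")
    with open(path, "w") as fh:
        fh.write("\n".join(out) + "\n")
    return path


def _region_boundary_faces(mesh: Mesh, tag: str) -> np.ndarray:
    el = mesh.elements_in(tag)
    faces = mesh.tets[el][:, :4][:, [[1, 2, 3], [0, 3, 2], [0, 1, 3],
                                     [0, 2, 1]]].reshape(-1, 3)
    key = np.sort(faces, axis=1)
    _, inv, cnt = np.unique(key, axis=0, return_inverse=True,
                            return_counts=True)
    return faces[cnt[inv] == 1]


def write_stl(mesh: Mesh, outdir: str) -> Dict[str, str]:
    """One ASCII STL per region (boundary triangles), for visual inspection."""
    os.makedirs(outdir, exist_ok=True)
    paths = {}
    for tag in mesh.region_tags():
        faces = _region_boundary_faces(mesh, tag)
        p = os.path.join(outdir, f"{tag}.stl")
        with open(p, "w") as fh:
            fh.write(f"solid {tag}\n")
            for f in faces:
                a, b, c = mesh.nodes[f]
                n = np.cross(b - a, c - a)
                nn = np.linalg.norm(n)
                n = n / nn if nn > 0 else n
                fh.write(f"facet normal {n[0]:.6g} {n[1]:.6g} {n[2]:.6g}\n"
                         " outer loop\n")
                for v in (a, b, c):
                    fh.write(f"  vertex {v[0]:.6g} {v[1]:.6g} {v[2]:.6g}\n")
                fh.write(" endloop\nendfacet\n")
            fh.write(f"endsolid {tag}\n")
        paths[tag] = p
    return paths
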