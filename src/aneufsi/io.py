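"""Mesh and field I/O: Gmsh MSH 4.1 (tagged round-trip) and VTU/PVD export.

The MSH writer stores boundary tags and region tags as physical groups (2D
and 3D respectively, with the package's canonical ids and names), one
discrete entity per group, so meshes survive a write/read round trip
bit-for-bit and externally generated Gmsh meshes with equivalent physical
groups can be imported.  VTU output is ASCII XML with optional point data,
collected into a PVD collection for time series.
"""

from __future__ import annotations

import os
from xml.sax.saxutils import escape

import numpy as np

from .mesh import FACE_TAGS, REGION_TAGS, TAG_NAMES, MeshError, TaggedMesh


class IOError_(MeshError):
    """Unreadable, unsupported or incompletely tagged mesh file."""


# ---------------------------------------------------------------------------
# MSH 4.1
# ---------------------------------------------------------------------------

def write_mesh(mesh: TaggedMesh, path: str) -> None:
    """Write a tagged mesh as ASCII Gmsh MSH 4.1 with physical groups."""
    face_groups = sorted(set(mesh.face_tags.tolist()))
    region_groups = sorted(set(mesh.region_tags.tolist()))
    lines = ["$MeshFormat", "4.1 0 8", "$EndMeshFormat", "$PhysicalNames",
             str(len(face_groups) + len(region_groups))]
    for t in face_groups:
        lines.append(f'2 {t} "{TAG_NAMES.get(t, f"surface-{t}")}"')
    for t in region_groups:
        lines.append(f'3 {t} "{TAG_NAMES.get(t, f"region-{t}")}"')
    lines.append("$EndPhysicalNames")
    lo = mesh.vertices.min(axis=0)
    hi = mesh.vertices.max(axis=0)
    box = f"{lo[0]:.17g} {lo[1]:.17g} {lo[2]:.17g} {hi[0]:.17g} {hi[1]:.17g} {hi[2]:.17g}"
    lines += ["$Entities", f"0 0 {len(face_groups)} {len(region_groups)}"]
    for t in face_groups:
        lines.append(f"{t} {box} 1 {t} 0")
    for t in region_groups:
        lines.append(f"{t} {box} 1 {t} 0")
    lines.append("$EndEntities")
    n = mesh.num_vertices
    lines += ["$Nodes", f"1 {n} 1 {n}", f"3 {region_groups[0]} 0 {n}"]
    lines += [str(i + 1) for i in range(n)]
    lines += [f"{x:.17g} {y:.17g} {z:.17g}" for x, y, z in mesh.vertices]
    lines.append("$EndNodes")

    blocks = []
    eid = 1
    for t in face_groups:
        faces = mesh.faces[mesh.face_tags == t] + 1
        rows = [f"{eid + i} " + " ".join(map(str, f)) for i, f in enumerate(faces)]
        eid += len(faces)
        blocks.append((2, t, 2, rows))
    for t in region_groups:
        cells = mesh.cells[mesh.region_tags == t] + 1
        rows = [f"{eid + i} " + " ".join(map(str, c)) for i, c in enumerate(cells)]
        eid += len(cells)
        blocks.append((3, t, 4, rows))
    total = eid - 1
    lines += ["$Elements", f"{len(blocks)} {total} 1 {total}"]
    for dim, tag, etype, rows in blocks:
        lines.append(f"{dim} {tag} {etype} {len(rows)}")
        lines += rows
    lines.append("$EndElements")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def read_mesh(path: str) -> TaggedMesh:
    """Read an ASCII MSH 4.1 file with tagged physical groups."""
    if not os.path.exists(path):
        raise IOError_(f"mesh file not found: {path}")
    with open(path) as fh:
        tokens = fh.read().split("\n")
    sections: dict[str, list[str]] = {}
    i = 0
    while i < len(tokens):
        line = tokens[i].strip()
        if line.startswith("$") and not line.startswith("$End"):
            name = line[1:]
            j = i + 1
            body = []
            while j < len(tokens) and tokens[j].strip() != f"$End{name}":
                body.append(tokens[j])
                j += 1
            sections[name] = body
            i = j + 1
        else:
            i += 1
    if "MeshFormat" in sections:
        ver = sections["MeshFormat"][0].split()[0]
        if not ver.startswith("4"):
            raise IOError_(f"unsupported MSH version {ver} (need 4.x ASCII)")
    if "Nodes" not in sections or "Elements" not in sections:
        raise IOError_("MSH file lacks Nodes/Elements sections")

    # physical names (optional; canonical ids are used as fallback)
    phys_name: dict[tuple[int, int], str] = {}
    if "PhysicalNames" in sections:
        for row in sections["PhysicalNames"][1:]:
            parts = row.split(maxsplit=2)
            if len(parts) == 3:
                phys_name[(int(parts[0]), int(parts[1]))] = parts[2].strip().strip('"')
    # entity -> physical tag
    ent_phys: dict[tuple[int, int], int] = {}
    if "Entities" in sections:
        counts = list(map(int, sections["Entities"][0].split()))
        row = 1
        for dim, cnt in zip(range(4), counts):
            for _ in range(cnt):
                parts = sections["Entities"][row].split()
                row += 1
                nbox = 6 if dim > 0 else 3
                nphys = int(parts[1 + nbox])
                if nphys > 0:
                    ent_phys[(dim, int(parts[0]))] = int(parts[2 + nbox])

    body = sections["Nodes"]
    nblocks = int(body[0].split()[0])
    ntotal = int(body[0].split()[1])
    row = 1
    tag_to_idx: dict[int, int] = {}
    coords = np.empty((ntotal, 3))
    pos = 0
    for _ in range(nblocks):
        _, _, _, nb = map(int, body[row].split()[:4])
        row += 1
        tags = [int(body[row + k].split()[0]) for k in range(nb)]
        row += nb
        for k in range(nb):
            xyz = list(map(float, body[row + k].split()[:3]))
            tag_to_idx[tags[k]] = pos
            coords[pos] = xyz
            pos += 1
        row += nb

    body = sections["Elements"]
    nblocks = int(body[0].split()[0])
    row = 1
    faces, face_tags, cells, region_tags = [], [], [], []
    for _ in range(nblocks):
        dim, etag, etype, nb = map(int, body[row].split()[:4])
        row += 1
        phys = ent_phys.get((dim, etag), etag)
        for k in range(nb):
            ids = [tag_to_idx[int(t)] for t in body[row + k].split()[1:]]
            if etype == 2:
                faces.append(ids)
                face_tags.append(phys)
            elif etype == 4:
                cells.append(ids)
                region_tags.append(phys)
        row += nb
    if not cells:
        raise IOError_("MSH file contains no tetrahedra")
    if not faces:
        raise IOError_("MSH file has no tagged boundary triangles "
                       f"(missing groups: {', '.join(FACE_TAGS)})")
    # map non-canonical physical ids through their names where possible
    name_to_face = dict(FACE_TAGS)
    name_to_region = dict(REGION_TAGS)
    ft = np.asarray(face_tags, dtype=np.int64)
    rt = np.asarray(region_tags, dtype=np.int64)
    for (dim, pid), nm in phys_name.items():
        if dim == 2 and nm in name_to_face:
            ft[ft == pid] = name_to_face[nm]
        if dim == 3 and nm in name_to_region:
            rt[rt == pid] = name_to_region[nm]
    return TaggedMesh(coords, np.asarray(cells), np.asarray(faces), ft, rt)


# ---------------------------------------------------------------------------
# VTU / PVD
# ---------------------------------------------------------------------------

def write_vtu(path: str, vertices: np.ndarray, cells: np.ndarray,
              point_data: dict[str, np.ndarray] | None = None,
              cell_data: dict[str, np.ndarray] | None = None) -> None:
    """ASCII VTU (unstructured grid of tetrahedra) with optional field data."""
    vertices = np.asarray(vertices, dtype=float)
    cells = np.asarray(cells, dtype=np.int64)
    n, m = len(vertices), len(cells)

    def arr(name, data):
        data = np.asarray(data, dtype=float)
        ncomp = 1 if data.ndim == 1 else data.shape[1]
        flat = " ".join(f"{v:.9g}" for v in data.ravel())
        return (f'<DataArray type="Float64" Name="{escape(name)}" '
                f'NumberOfComponents="{ncomp}" format="ascii">{flat}</DataArray>')

    parts = ['<?xml version="1.0"?>',
             '<VTKFile type="UnstructuredGrid" version="0.1" byte_order="LittleEndian">',
             '<UnstructuredGrid>',
             f'<Piece NumberOfPoints="{n}" NumberOfCells="{m}">', "<Points>",
             arr("Points", vertices), "</Points>", "<Cells>",
             '<DataArray type="Int64" Name="connectivity" format="ascii">'
             + " ".join(map(str, cells.ravel())) + "</DataArray>",
             '<DataArray type="Int64" Name="offsets" format="ascii">'
             + " ".join(str(4 * (i + 1)) for i in range(m)) + "</DataArray>",
             '<DataArray type="UInt8" Name="types" format="ascii">'
             + " ".join(["10"] * m) + "</DataArray>", "</Cells>"]
    if point_data:
        parts.append("<PointData>")
        parts += [arr(k, v) for k, v in point_data.items()]
        parts.append("</PointData>")
    if cell_data:
        parts.append("<CellData>")
        parts += [arr(k, v) for k, v in cell_data.items()]
        parts.append("</CellData>")
    parts += ["</Piece>", "</UnstructuredGrid>", "</VTKFile>"]
    with open(path, "w") as fh:
        fh.write("\n".join(parts))


def write_pvd(path: str, entries: list[tuple[float, str]]) -> None:
    """PVD collection referencing VTU snapshots as (time, filename)."""
    rows = ['<?xml version="1.0"?>',
            '<VTKFile type="Collection" version="0.1"><Collection>']
    rows += [f'<DataSet timestep="{t:.9g}" file="{escape(f)}"/>' for t, f in entries]
    rows += ["</Collection></VTKFile>"]
    with open(path, "w") as fh:
        fh.write("\n".join(rows))
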