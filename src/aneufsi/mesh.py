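"""Tagged tetrahedral meshes.

The mesh container used throughout the package: simplicial volume meshes with
named boundary-face tags (inlet, outlet, fluid-structure interface, exterior,
fixed plane) and per-cell region tags (lumen, artery wall, aneurysm-bulge
wall).  Coordinates are stored in millimetres, matching the benchmark's
geometry description; solvers convert to SI internally.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

# Canonical tag ids shared by meshing, I/O and solvers.  Face tags are
# 2D physical groups, region tags 3D physical groups in MSH terms.
FACE_TAGS = {"inlet": 1, "outlet": 2, "interface": 3, "exterior": 4, "fixed-plane": 5}
REGION_TAGS = {"lumen": 10, "artery-wall": 11, "bulge-wall": 12}
TAG_NAMES = {v: k for k, v in {**FACE_TAGS, **REGION_TAGS}.items()}

MM = 1e-3  # metres per millimetre


class MeshError(ValueError):
    """Raised for topological or tagging defects of a mesh."""


@dataclass
class TaggedMesh:
    """Tetrahedral mesh with tagged boundary triangles and cell regions.

    Attributes
    ----------
    vertices : (N, 3) float array, millimetres.
    cells : (M, 4) int array of vertex indices, positively oriented.
    faces : (F, 3) int array of boundary triangles.
    face_tags : (F,) int array, values from :data:`FACE_TAGS`.
    region_tags : (M,) int array, values from :data:`REGION_TAGS`.
    """

    vertices: np.ndarray
    cells: np.ndarray
    faces: np.ndarray
    face_tags: np.ndarray
    region_tags: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.vertices = np.ascontiguousarray(self.vertices, dtype=np.float64)
        self.cells = np.ascontiguousarray(self.cells, dtype=np.int64)
        self.faces = np.ascontiguousarray(self.faces, dtype=np.int64)
        self.face_tags = np.ascontiguousarray(self.face_tags, dtype=np.int64)
        if self.region_tags is None:
            self.region_tags = np.full(len(self.cells), REGION_TAGS["lumen"], dtype=np.int64)
        self.region_tags = np.ascontiguousarray(self.region_tags, dtype=np.int64)
        self.orient_positive()

    # -- basic measures -------------------------------------------------
    @property
    def num_vertices(self) -> int:
        return len(self.vertices)

    @property
    def num_cells(self) -> int:
        return len(self.cells)

    def cell_volumes(self) -> np.ndarray:
        """Signed tetrahedron volumes in mm^3."""
        v = self.vertices
        t = self.cells
        e = v[t[:, 1:]] - v[t[:, :1]]
        return np.linalg.det(e) / 6.0

    def orient_positive(self) -> None:
        vol = self.cell_volumes()
        flip = vol < 0
        if np.any(flip):
            c = self.cells[flip]
            self.cells[flip] = c[:, [0, 1, 3, 2]]

    def face_areas_normals(self) -> tuple[np.ndarray, np.ndarray]:
        """Areas (mm^2) and outward unit normals of the boundary faces."""
        v = self.vertices
        f = self.faces
        cr = np.cross(v[f[:, 1]] - v[f[:, 0]], v[f[:, 2]] - v[f[:, 0]])
        area = 0.5 * np.linalg.norm(cr, axis=1)
        n = cr / (2.0 * area[:, None] + 1e-300)
        # orient outward: compare with vector from adjacent cell centroid
        cell_of = self.face_cells()
        cc = v[self.cells[cell_of]].mean(axis=1)
        fc = v[f].mean(axis=1)
        sign = np.sign(np.einsum("ij,ij->i", n, fc - cc))
        sign[sign == 0] = 1.0
        return area, n * sign[:, None]

    def face_cells(self) -> np.ndarray:
        """Index of the unique cell adjacent to each boundary face."""
        if not hasattr(self, "_face_cells"):
            key_to_cell = {}
            tf = _cell_faces(self.cells)
            for ci in range(len(self.cells)):
                for k in range(4):
                    key = tuple(sorted(tf[ci, k]))
                    if key in key_to_cell:
                        key_to_cell[key] = -1  # interior
                    else:
                        key_to_cell[key] = ci
            out = np.empty(len(self.faces), dtype=np.int64)
            for i, tri in enumerate(self.faces):
                ci = key_to_cell.get(tuple(sorted(tri)), None)
                if ci is None or ci < 0:
                    raise MeshError(f"boundary face {i} is not a boundary facet of the cell complex")
                out[i] = ci
            self._face_cells = out
        return self._face_cells

    # -- tag queries ----------------------------------------------------
    def faces_where(self, name: str) -> np.ndarray:
        tag = FACE_TAGS[name]
        return self.faces[self.face_tags == tag]

    def vertex_set(self, name: str) -> np.ndarray:
        """Sorted unique vertex indices carried by faces of the given tag."""
        return np.unique(self.faces_where(name))

    def cells_where(self, name: str) -> np.ndarray:
        return self.cells[self.region_tags == REGION_TAGS[name]]

    def require_tags(self, names: tuple[str, ...]) -> None:
        present = set(self.face_tags.tolist())
        missing = [n for n in names if FACE_TAGS[n] not in present]
        if missing:
            raise MeshError(f"mesh is missing boundary tag group(s): {', '.join(missing)}")

    # -- validation ------------------------------------------------------
    def check_watertight(self) -> None:
        """Every facet shared by exactly 2 cells, or by 1 cell and 1 tagged face."""
        counts: dict[tuple, int] = {}
        tf = _cell_faces(self.cells).reshape(-1, 3)
        for tri in tf:
            key = tuple(sorted(tri))
            counts[key] = counts.get(key, 0) + 1
        bkeys = {tuple(sorted(tri)) for tri in self.faces}
        for key, c in counts.items():
            if c == 2:
                if key in bkeys:
                    raise MeshError("interior facet carries a boundary tag")
            elif c == 1:
                if key not in bkeys:
                    raise MeshError("untagged boundary facet found")
            else:
                raise MeshError("facet shared by more than two cells")

    def copy(self) -> "TaggedMesh":
        return TaggedMesh(
            self.vertices.copy(), self.cells.copy(), self.faces.copy(),
            self.face_tags.copy(), self.region_tags.copy(),
        )


_FACE_LOCAL = np.array([[1, 2, 3], [0, 3, 2], [0, 1, 3], [0, 2, 1]])


def _cell_faces(cells: np.ndarray) -> np.ndarray:
    """(M, 4, 3) local faces of each tetrahedron, outward-ordered."""
    return cells[:, _FACE_LOCAL]


def extract_boundary(cells: np.ndarray) -> np.ndarray:
    """Boundary triangles of a tet complex (facets appearing exactly once)."""
    tf = _cell_faces(cells).reshape(-1, 3)
    skey = np.sort(tf, axis=1)
    order = np.lexsort(skey.T)
    sk = skey[order]
    tfo = tf[order]
    dup_prev = np.zeros(len(sk), dtype=bool)
    dup_prev[1:] = np.all(sk[1:] == sk[:-1], axis=1)
    dup_next = np.zeros(len(sk), dtype=bool)
    dup_next[:-1] = dup_prev[1:]
    unique = ~(dup_prev | dup_next)
    return tfo[unique]
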