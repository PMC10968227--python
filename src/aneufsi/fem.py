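"""Linear (P1) tetrahedral finite-element assembly utilities.

Vectorized element arithmetic shared by the flow, mesh-motion and solid
solvers.  All routines here take coordinates in metres; conversion from the
millimetre-based mesh container happens in the solver constructors.
"""

from __future__ import annotations

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

# consistent P1 mass weights: int lam_i lam_j dV = V * (1 + delta_ij) / 20
MASS_W = (np.ones((4, 4)) + np.eye(4)) / 20.0


def tet_volumes(verts: np.ndarray, cells: np.ndarray) -> np.ndarray:
    e = verts[cells[:, 1:]] - verts[cells[:, :1]]
    return np.linalg.det(e) / 6.0


def shape_gradients(verts: np.ndarray, cells: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Volumes and constant gradients of the barycentric shape functions.

    Returns ``(vol (M,), grad (M, 4, 3))`` with ``grad[:, i]`` the gradient of
    the shape function of local vertex ``i``.
    """
    e = verts[cells[:, 1:]] - verts[cells[:, :1]]  # (M,3,3) rows: edges
    vol = np.linalg.det(e) / 6.0
    inv = np.linalg.inv(e)  # columns of inv are grads of lam_1..3? rows below
    g = np.empty((len(cells), 4, 3))
    g[:, 1:, :] = np.transpose(inv, (0, 2, 1))
    g[:, 0, :] = -g[:, 1:, :].sum(axis=1)
    return vol, g


def assemble(rows: np.ndarray, cols: np.ndarray, vals: np.ndarray, n: int, m: int | None = None):
    m = n if m is None else m
    return sp.coo_matrix((vals.ravel(), (rows.ravel(), cols.ravel())), shape=(n, m)).tocsr()


def scalar_laplacian(verts: np.ndarray, cells: np.ndarray, coeff: np.ndarray) -> sp.csr_matrix:
    """Assemble ``K_ij = sum_K c_K int grad(lam_i).grad(lam_j)``."""
    vol, g = shape_gradients(verts, cells)
    ke = np.einsum("k,kid,kjd->kij", coeff * vol, g, g)
    rows = np.repeat(cells, 4, axis=1)
    cols = np.tile(cells, (1, 4))
    return assemble(rows, cols, ke.reshape(len(cells), -1), len(verts))


def mass_matrix(verts: np.ndarray, cells: np.ndarray, lumped: bool = False):
    vol = tet_volumes(verts, cells)
    n = len(verts)
    if lumped:
        m = np.zeros(n)
        np.add.at(m, cells, np.repeat(vol[:, None] / 4.0, 4, axis=1))
        return sp.diags(m).tocsr()
    ke = vol[:, None, None] * MASS_W
    rows = np.repeat(cells, 4, axis=1)
    cols = np.tile(cells, (1, 4))
    return assemble(rows, cols, ke.reshape(len(cells), -1), n)


def apply_dirichlet(A: sp.csr_matrix, b: np.ndarray, dofs: np.ndarray, values: np.ndarray):
    """Row/column elimination of Dirichlet dofs (returns a new system).

    Keeps the matrix pattern symmetric: columns are moved to the right-hand
    side, rows replaced by the identity.
    """
    n = A.shape[0]
    xd = np.zeros(n)
    xd[dofs] = values
    b2 = b - A @ xd
    keep = np.ones(n)
    keep[dofs] = 0.0
    P = sp.diags(keep)
    Id = sp.diags(1.0 - keep)
    A2 = (P @ A @ P + Id).tocsr()
    b2 = keep * b2
    b2[dofs] = values
    return A2, b2


def solve_sparse(A: sp.csr_matrix, b: np.ndarray) -> np.ndarray:
    return spla.spsolve(A.tocsc(), b)


def vertex_areas(verts: np.ndarray, faces: np.ndarray, n_verts: int) -> np.ndarray:
    """Lumped area (one third of adjacent triangle areas) per surface vertex."""
    cr = np.cross(verts[faces[:, 1]] - verts[faces[:, 0]], verts[faces[:, 2]] - verts[faces[:, 0]])
    area = 0.5 * np.linalg.norm(cr, axis=1)
    out = np.zeros(n_verts)
    np.add.at(out, faces, np.repeat(area[:, None] / 3.0, 3, axis=1))
    return out


def vertex_normals(verts: np.ndarray, faces: np.ndarray, n_verts: int,
                   face_normals: np.ndarray, face_areas: np.ndarray) -> np.ndarray:
    """Area-weighted vertex normals of a tagged surface."""
    out = np.zeros((n_verts, 3))
    w = face_normals * face_areas[:, None] / 3.0
    for k in range(3):
        np.add.at(out, faces[:, k], w)
    norm = np.linalg.norm(out, axis=1)
    nz = norm > 0
    out[nz] /= norm[nz, None]
    return out


def element_size(vol: np.ndarray) -> np.ndarray:
    """Characteristic element length: edge of the regular tet of equal volume."""
    return (6.0 * np.sqrt(2.0) * np.abs(vol)) ** (1.0 / 3.0)


def expand_dofs(idx: np.ndarray, ncomp: int = 3) -> np.ndarray:
    """Vertex indices -> interleaved vector dof indices (x0,y0,z0,x1,...)."""
    return (idx[:, None] * ncomp + np.arange(ncomp)[None, :]).ravel()


class AssemblyPattern:
    """Precomputed scatter pattern for repeated element-matrix assembly.

    The (row, col) layout of element contributions is fixed by the mesh, so
    the expensive duplicate-summing CSR conversion is done once; subsequent
    assemblies reduce to a weighted bincount into the cached sparsity.
    """

    def __init__(self, gd: np.ndarray, n: int) -> None:
        nloc = gd.shape[1]
        rows = np.repeat(gd, nloc, axis=1).ravel()
        cols = np.tile(gd, (1, nloc)).ravel()
        order = np.lexsort((cols, rows))
        rs, cs = rows[order], cols[order]
        new = np.ones(len(rs), dtype=bool)
        new[1:] = (rs[1:] != rs[:-1]) | (cs[1:] != cs[:-1])
        slot_of_sorted = np.cumsum(new) - 1
        self._slot = np.empty(len(rows), dtype=np.int64)
        self._slot[order] = slot_of_sorted
        ur, uc = rs[new], cs[new]
        self.nnz = int(new.sum())
        self._indices = uc
        self._indptr = np.searchsorted(ur, np.arange(n + 1))
        self.shape = (n, n)

    def assemble(self, ke: np.ndarray) -> sp.csr_matrix:
        data = np.bincount(self._slot, weights=ke.ravel(), minlength=self.nnz)
        return sp.csr_matrix((data, self._indices, self._indptr), shape=self.shape)
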