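"""Stabilized ALE finite-element solver for transient incompressible flow.

Equal-order P1-P1 velocity/pressure tetrahedral elements with residual-based
variational-multiscale stabilization (SUPG/PSPG + grad-div, quasi-static
subscales with the time-step term retained in the stabilization parameter),
BDF2 time stepping (BDF1 start-up), Picard linearization of the convective
term ``(v - vm) . grad v`` and a resistance outlet applied as a weak normal
traction.  The fluid mesh follows the fluid-structure interface through a
variable-diffusivity extension solve with diffusivity equal to the inverse
squared distance to the interface, which makes near-interface cells move
almost rigidly and protects the boundary layer.

All internal arithmetic is SI (metres, Pa, seconds); meshes come in as
millimetre-based :class:`~aneufsi.mesh.TaggedMesh`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla
from scipy.spatial import cKDTree

from . import fem
from .mesh import FACE_TAGS, MM, TaggedMesh


class SteppingError(RuntimeError):
    """Nonlinear divergence, linear-solver failure, or an inverted cell."""


@dataclass(frozen=True)
class FluidParams:
    """Newtonian blood model: density (kg/m^3), dynamic viscosity (Pa s)."""

    rho: float = 1000.0
    mu: float = 0.004
    body_force: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        if self.rho <= 0 or self.mu <= 0:
            raise ValueError("fluid density and viscosity must be positive")


@dataclass
class FlowState:
    """Velocity (m/s) and pressure (Pa) fields at time ``t`` on the fluid mesh."""

    v: np.ndarray
    p: np.ndarray
    t: float

    def copy(self) -> "FlowState":
        return FlowState(self.v.copy(), self.p.copy(), self.t)


@dataclass
class MeshMotion:
    """Fluid-mesh displacement (m) and mesh velocity (m/s) on the vertices."""

    d_mesh: np.ndarray
    vm: np.ndarray

    @classmethod
    def zero(cls, n: int) -> "MeshMotion":
        return cls(np.zeros((n, 3)), np.zeros((n, 3)))


def _bdf_coeffs(prev2_exists: bool) -> tuple[float, float, float]:
    """(a0, a1, a2) of (a0 v + a1 v_n + a2 v_nn)/dt; BDF1 on the first step."""
    return (1.5, -2.0, 0.5) if prev2_exists else (1.0, -1.0, 0.0)


class FluidSolver:
    """Transient stabilized Navier-Stokes on a (possibly moving) tet mesh."""

    def __init__(self, mesh: TaggedMesh, params: FluidParams | None = None,
                 picard_tol: float = 1e-6, picard_maxit: int = 20,
                 picard_minit: int = 1, picard_atol: float = 1e-9) -> None:
        self.mesh = mesh
        self.params = params or FluidParams()
        self.picard_tol = picard_tol
        self.picard_maxit = picard_maxit
        self.picard_minit = picard_minit
        self.picard_atol = picard_atol   # RMS velocity floor (m/s)
        self.verts0 = mesh.vertices * MM
        self.cells = mesh.cells
        self.n = len(self.verts0)
        area, nrm = mesh.face_areas_normals()
        self.face_area = area * MM * MM
        self.face_normal = nrm
        self.inlet_verts = mesh.vertex_set("inlet")
        self.wall_verts = mesh.vertex_set("interface")
        self.outlet_faces = np.flatnonzero(mesh.face_tags == FACE_TAGS["outlet"])
        self.inlet_faces = np.flatnonzero(mesh.face_tags == FACE_TAGS["inlet"])
        self._last_system = None
        self._pattern = None
        self._gd = None
        self._outlet_w = None
        self._dc_lu = None

    # -- fluxes ----------------------------------------------------------
    def boundary_flux(self, v: np.ndarray, faces_idx: np.ndarray) -> float:
        """Outward volumetric flux (m^3/s) through the given boundary faces."""
        f = self.mesh.faces[faces_idx]
        vf = v[f].mean(axis=1)
        return float(np.einsum("i,ij,ij->", self.face_area[faces_idx],
                               vf, self.face_normal[faces_idx]))

    def outlet_flow_ml_s(self, v: np.ndarray) -> float:
        return self.boundary_flux(v, self.outlet_faces) * 1e6

    def inlet_flow_ml_s(self, v: np.ndarray) -> float:
        return -self.boundary_flux(v, self.inlet_faces) * 1e6

    # -- assembly --------------------------------------------------------
    def _outlet_weights(self) -> np.ndarray:
        """Nodal weight vector w (m^2) with q_out [m^3/s] = w . v."""
        if self._outlet_w is None:
            w = np.zeros(4 * self.n)
            for fi in self.outlet_faces:
                contrib = self.face_normal[fi] * self.face_area[fi] / 3.0
                for vtx in self.mesh.faces[fi]:
                    w[3 * vtx:3 * vtx + 3] += contrib
            self._outlet_w = w
        return self._outlet_w

    def _assemble(self, coords, w_conv, vn, vnn, a0, a1, a2, dt,
                  outlet_model=None, outlet_scale=1.0, body_force=None):
        rho, mu = self.params.rho, self.params.mu
        f_body = np.asarray(self.params.body_force if body_force is None
                            else body_force, dtype=float)
        cells = self.cells
        m = len(cells)
        if np.any(fem.tet_volumes(coords, cells) <= 0):
            raise SteppingError("mesh motion inverted a cell; reduce the time step")
        vol, g = fem.shape_gradients(coords, cells)
        h = fem.element_size(vol)

        we = w_conv[cells]                      # (m,4,3) nodal convective velocity
        wbar = we.mean(axis=1)
        speed = np.linalg.norm(wbar, axis=1)
        tau_m = 1.0 / (2.0 * rho / dt + 4.0 * mu / h ** 2 + 2.0 * rho * speed / h)
        tau_c = mu + 0.5 * rho * speed * h

        cbar = np.einsum("md,mjd->mj", wbar, g)          # wbar . grad(lam_j)
        wk_g = np.einsum("mkd,mjd->mkj", we, g)          # w_k . grad(lam_j)
        gg = np.einsum("mid,mjd->mij", g, g)

        vne = vn[cells]
        vnne = vnn[cells]
        hist = a1 * vne + a2 * vnne                      # (m,4,3)
        hist_bar = hist.mean(axis=1)

        # scalar (component-diagonal) velocity block
        S = (rho * a0 / dt) * vol[:, None, None] * fem.MASS_W \
            + rho * vol[:, None, None] * np.einsum("ik,mkj->mij", fem.MASS_W, wk_g) \
            + mu * vol[:, None, None] * gg
        s_i = rho * cbar                                  # SUPG test weight
        r_j = rho * (a0 / (4.0 * dt)) + rho * cbar        # residual coeff on v_j
        tv = tau_m * vol
        S = S + tv[:, None, None] * np.einsum("mi,mj->mij", s_i, r_j)

        ke = np.zeros((m, 16, 16))
        i3 = np.arange(3)
        # velocity-velocity
        kvv = S[:, :, None, :, None] * np.eye(3)[None, None, :, None, :]
        kvv = kvv + np.einsum("m,mja,mic->miajc", mu * vol, g, g)
        kvv = kvv + np.einsum("m,mia,mjc->miajc", tau_c * vol, g, g)
        ke[:, :12, :12] = kvv.reshape(m, 12, 12)
        # velocity-pressure
        kvp = -(vol[:, None, None, None] / 4.0) * g[:, :, :, None] * np.ones((1, 1, 1, 4)) \
            + tv[:, None, None, None] * np.einsum("mi,mja->miaj", s_i, g)
        ke[:, :12, 12:] = kvp.reshape(m, 12, 4)
        # pressure-velocity
        kpv = (vol[:, None, None, None] / 4.0) * np.einsum("mjc,i->mijc", g, np.ones(4)) \
            + tv[:, None, None, None] * np.einsum("mic,mj->mijc", g, r_j)
        ke[:, 12:, :12] = kpv.reshape(m, 4, 12)
        # pressure-pressure (PSPG)
        ke[:, 12:, 12:] = tv[:, None, None] * gg

        be = np.zeros((m, 16))
        # Galerkin history + body force
        rhs_v = -(rho / dt) * np.einsum("ij,mjd->mid", fem.MASS_W, hist) * vol[:, None, None]
        rhs_v = rhs_v + (vol[:, None, None] / 4.0) * f_body
        # stabilization history (R0 = rho/dt hist_bar - f)
        r0 = (rho / dt) * hist_bar - f_body
        rhs_v = rhs_v - tv[:, None, None] * s_i[:, :, None] * r0[:, None, :]
        be[:, :12] = rhs_v.reshape(m, 12)
        be[:, 12:] = -tv[:, None] * np.einsum("mic,mc->mi", g, r0)

        if self._pattern is None:
            gd = np.empty((m, 16), dtype=np.int64)
            gd[:, :12] = (3 * cells[:, :, None] + i3).reshape(m, 12)
            gd[:, 12:] = 3 * self.n + cells
            self._gd = gd
            self._pattern = fem.AssemblyPattern(gd, 4 * self.n)
        gd = self._gd
        A = self._pattern.assemble(ke)
        b = np.zeros(4 * self.n)
        np.add.at(b, gd.ravel(), be.ravel())

        # resistance outlet: traction -(P0 + Rd q_out) n on the outlet faces.
        # The flux feedback Rd*q_out(v) is treated IMPLICITLY via a rank-one
        # block on the outlet dofs: evaluated explicitly it forms a positive
        # feedback loop with the wall compliance whose converged-in-time map
        # is period-2 unstable (the solution doubles every two steps once the
        # resistance is active, even though each coupled step converges).
        if outlet_model is not None:
            w = self._outlet_weights()
            s = float(outlet_scale)
            b -= 1e3 * s * outlet_model.P0 * w
            idx = np.flatnonzero(w)
            block = (1e9 * s * outlet_model.Rd) * np.outer(w[idx], w[idx])
            rows = np.repeat(idx, len(idx))
            cols = np.tile(idx, len(idx))
            A = A + sp.coo_matrix((block.ravel(), (rows, cols)),
                                  shape=A.shape)
        return A, b

    # -- linear solve with factorization reuse -----------------------------
    _DC_TOL = 1e-9
    _DC_MAXIT = 8

    def _solve_linear(self, A, b, x0=None):
        """Solve A x = b exactly, reusing the last LU factorization.

        Between coupling subiterations (and often between time steps) the
        matrix changes only slightly, while a fresh factorization costs ~50x
        a triangular solve.  Defect correction with the cached factors,
        x <- x + LU^-1 (b - A x), is iterated to a 1e-9 relative residual, so
        the returned solution matches a direct solve; if the cached factors
        have gone stale the loop stalls and the matrix is refactorized.
        """
        bn = np.linalg.norm(b)
        if self._dc_lu is not None and bn > 0.0:
            x = x0.copy() if x0 is not None else self._dc_lu.solve(b)
            r_prev = np.inf
            for _ in range(self._DC_MAXIT):
                r = b - A @ x
                rn = np.linalg.norm(r)
                if rn <= self._DC_TOL * bn:
                    return x
                if r_prev < np.inf and rn > 0.5 * r_prev:
                    break  # not contracting fast enough: refactorize
                x = x + self._dc_lu.solve(r)
                r_prev = rn
        self._dc_lu = spla.splu(A)
        return self._dc_lu.solve(b)

    # -- time step -------------------------------------------------------
    def advance(self, prev: FlowState, prev2: FlowState | None,
                motion: MeshMotion | None, dt: float, t_new: float,
                inlet_values: np.ndarray | None = None,
                wall_velocity: np.ndarray | None = None,
                outlet_model=None, body_force=None, outlet_scale: float = 1.0,
                extra_dirichlet: tuple[np.ndarray, np.ndarray] | None = None) -> FlowState:
        """Advance the flow by one step of size ``dt`` to time ``t_new``.

        ``inlet_values``: (n_inlet, 3) Dirichlet velocities on the inlet
        vertex set (in the order of ``self.inlet_verts``); ``wall_velocity``:
        full (N, 3) field whose interface entries provide the moving-wall
        Dirichlet data (defaults to no slip).
        """
        if dt <= 0:
            raise ValueError("dt must be positive")
        a0, a1, a2 = _bdf_coeffs(prev2 is not None)
        vn = prev.v
        vnn = prev2.v if prev2 is not None else np.zeros_like(vn)
        coords = self.verts0 if motion is None else self.verts0 + motion.d_mesh
        vm = np.zeros_like(vn) if motion is None else motion.vm

        dir_dofs, dir_vals = self._dirichlet(inlet_values, wall_velocity,
                                             extra_dirichlet)
        a_k = (2.0 * vn - vnn) if prev2 is not None else vn.copy()
        x = np.concatenate([a_k.ravel(), prev.p])
        q_out = self.outlet_flow_ml_s(a_k)

        for it in range(self.picard_maxit):
            om = None
            if outlet_model is not None:
                # outlet_scale ramps the resistance pressure in with the
                # inflow ramp; during the ramp the outlet traction is also
                # switched off while the resistance model predicts suction,
                # so start-up never applies a suction step to the undeformed
                # wall (the cycle itself stays positive)
                pe = outlet_model.P0 + outlet_model.Rd * q_out
                if outlet_scale >= 1.0 or pe > 0.0:
                    om = outlet_model
            A, b = self._assemble(coords, a_k - vm, vn, vnn, a0, a1, a2, dt,
                                  outlet_model=om, outlet_scale=outlet_scale,
                                  body_force=body_force)
            A_d, b_d = fem.apply_dirichlet(A, b, dir_dofs, dir_vals)
            try:
                x = self._solve_linear(A_d.tocsc(), b_d, x)
            except RuntimeError as exc:  # pragma: no cover
                raise SteppingError(f"linear solve failed at t={t_new}: {exc}") from exc
            if not np.all(np.isfinite(x)):
                raise SteppingError(f"non-finite solution at t={t_new}")
            v_new = x[:3 * self.n].reshape(-1, 3)
            scale = max(np.linalg.norm(v_new),
                        self.picard_atol * np.sqrt(3.0 * self.n))
            dv = np.linalg.norm(v_new - a_k) / scale
            a_k = v_new
            q_out = self.outlet_flow_ml_s(v_new)
            if dv < self.picard_tol and it + 1 >= self.picard_minit:
                break
        else:
            # picard_maxit == 1 is the documented semi-implicit mode (one
            # sweep with BDF-extrapolated convection); otherwise require
            # at least rough convergence
            if self.picard_maxit > 1 and dv > 100 * self.picard_tol:
                raise SteppingError(
                    f"Picard iterations did not converge at t={t_new} (dv={dv:.2e})")
        self._last_system = (A, b, x)
        return FlowState(a_k, x[3 * self.n:], t_new)

    def _dirichlet(self, inlet_values, wall_velocity, extra=None):
        dofs = [fem.expand_dofs(self.inlet_verts), fem.expand_dofs(self.wall_verts)]
        if inlet_values is None:
            inlet_values = np.zeros((len(self.inlet_verts), 3))
        wall = np.zeros((len(self.wall_verts), 3)) if wall_velocity is None \
            else wall_velocity[self.wall_verts]
        vals = [np.asarray(inlet_values).ravel(), wall.ravel()]
        if extra is not None:
            dofs.append(np.asarray(extra[0], dtype=np.int64))
            vals.append(np.asarray(extra[1], dtype=float))
        dofs = np.concatenate(dofs)
        vals = np.concatenate(vals)
        # de-duplicate (a vertex can sit on both inlet rim and wall: wall wins)
        _, first = np.unique(dofs[::-1], return_index=True)
        keep = len(dofs) - 1 - first
        return dofs[keep], vals[keep]

    # -- consistent boundary traction -------------------------------------
    def traction_nodal_forces(self, tag: str = "interface") -> np.ndarray:
        """Consistent nodal forces  f_i = int_G (sigma_f . n) phi_i dG  (N).

        Evaluated variationally from the converged residual of the last
        ``advance`` call; n is the outward fluid normal, so these are the
        forces the fluid exerts on the tagged surface.
        """
        if self._last_system is None:
            raise SteppingError("no converged flow state available yet")
        if tag not in FACE_TAGS:
            raise ValueError(f"unknown boundary tag {tag!r}")
        A, b, x = self._last_system
        r = A @ x - b
        verts = self.mesh.vertex_set(tag)
        out = np.zeros((self.n, 3))
        out[verts] = r[:3 * self.n].reshape(-1, 3)[verts]
        return out


# ---------------------------------------------------------------------------
# mesh motion
# ---------------------------------------------------------------------------

class MeshMotionSolver:
    """Extension of interface displacement into the fluid mesh.

    Solves div(gamma grad d) = 0 per displacement component with
    gamma = 1 / max(dist, floor)^2, dist the distance to the interface
    (computed once on the reference mesh, floored to avoid a singular
    coefficient at the wall).  Dirichlet: d = interface displacement on the
    interface, d = 0 on the other tagged fluid boundaries.
    """

    def __init__(self, mesh: TaggedMesh, fixed_tags: tuple[str, ...] = ("inlet", "outlet"),
                 gamma_floor: float = 0.02 * MM) -> None:
        self.mesh = mesh
        verts = mesh.vertices * MM
        cells = mesh.cells
        self.n = len(verts)
        self.interface_verts = mesh.vertex_set("interface")
        fixed = [mesh.vertex_set(t) for t in fixed_tags
                 if np.any(mesh.face_tags == FACE_TAGS[t])]
        self.fixed_verts = (np.unique(np.concatenate(fixed)) if fixed
                            else np.empty(0, dtype=np.int64))
        self.fixed_verts = np.setdiff1d(self.fixed_verts, self.interface_verts)

        tree = cKDTree(verts[self.interface_verts])
        cent = verts[cells].mean(axis=1)
        dist, _ = tree.query(cent)
        gamma = 1.0 / np.maximum(dist, gamma_floor) ** 2
        # quality stiffening: flat cells deform rigidly instead of inverting
        vol = fem.tet_volumes(verts, cells)
        edges = verts[cells]
        emax = np.zeros(len(cells))
        for i in range(4):
            for j in range(i + 1, 4):
                emax = np.maximum(emax, np.linalg.norm(edges[:, i] - edges[:, j], axis=1))
        quality = fem.element_size(vol) / emax
        gamma = gamma * np.clip((0.4 / np.maximum(quality, 1e-6)) ** 2, 1.0, 1e6)
        K = fem.scalar_laplacian(verts, cells, gamma)
        dir_idx = np.concatenate([self.interface_verts, self.fixed_verts])
        keep = np.ones(self.n)
        keep[dir_idx] = 0.0
        P = sp.diags(keep)
        Id = sp.diags(1.0 - keep)
        self._K = K
        self._keep = keep
        self._lu = spla.splu((P @ K @ P + Id).tocsc())

    def solve(self, interface_displacement: np.ndarray) -> np.ndarray:
        """Extend (Ni, 3) interface displacement (m) to the whole mesh."""
        if interface_displacement.shape != (len(self.interface_verts), 3):
            raise ValueError("interface displacement shape mismatch")
        d = np.zeros((self.n, 3))
        for c in range(3):
            xd = np.zeros(self.n)
            xd[self.interface_verts] = interface_displacement[:, c]
            rhs = self._keep * (-(self._K @ xd))
            rhs[self.interface_verts] = interface_displacement[:, c]
            d[:, c] = self._lu.solve(rhs)
        return d


def solve_mesh_motion(mesh: TaggedMesh, interface_displacement: np.ndarray,
                      prev: MeshMotion | None = None,
                      prev2: MeshMotion | None = None, dt: float = 1.0,
                      solver: MeshMotionSolver | None = None) -> MeshMotion:
    """One-shot mesh-motion solve with BDF-consistent mesh velocity.

    ``vm = (a0 d + a1 d_n + a2 d_nn) / dt`` with the same BDF stencil as the
    flow solver, so the discrete interface velocity seen by the fluid matches
    the interface displacement history exactly.
    """
    solver = solver or MeshMotionSolver(mesh)
    d = solver.solve(interface_displacement)
    a0, a1, a2 = _bdf_coeffs(prev2 is not None)
    dn = prev.d_mesh if prev is not None else np.zeros_like(d)
    dnn = prev2.d_mesh if prev2 is not None else np.zeros_like(d)
    vm = (a0 * d + a1 * dn + a2 * dnn) / dt
    return MeshMotion(d_mesh=d, vm=vm)


def fluid_traction(solver: FluidSolver, state: FlowState,
                   surface: str = "interface") -> np.ndarray:
    """Per-vertex traction vectors (Pa) on a tagged surface.

    Consistent nodal forces divided by the lumped vertex areas of the
    surface triangulation (on the current configuration).
    """
    forces = solver.traction_nodal_forces(surface)
    faces = solver.mesh.faces_where(surface)
    areas = fem.vertex_areas(solver.verts0, faces, solver.n)
    verts = np.unique(faces)
    tr = np.zeros_like(forces)
    tr[verts] = forces[verts] / areas[verts, None]
    return tr
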