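"""Mixed displacement-pressure finite elements for the hyperelastic wall.

The arterial wall is an isochoric neo-Hookean solid with a Simo-Taylor
volumetric law,

    U(J) = k/4 (J^2 - 1) - k/2 ln J,      W(Cbar) = mu/2 (tr Cbar - 3),

solved in a total-Lagrangian mixed (u, ps) form on linear tetrahedra: the
volumetric Cauchy stress ps is an independent vertex field tied to the
dilatation through the nonlinear law ps = U'(J) = k/2 (J - 1/J), and the
deviatoric Cauchy stress is dev[sigma] = mu J^(-5/3) dev[F F^T].  Equal-order
interpolation is stabilized by an element-Laplacian pressure term scaled by
h^2/(2 mu).  Inertia uses BDF2 (BDF1 start-up).  Newton element Jacobians
are formed by complex-step differentiation of the element residual, which is
exact to round-off.

Young's moduli are assigned per mesh region: the aneurysm bulge is ten times
softer than the parent artery, the calibration that reproduces in vivo
observed pulsation volume amplitudes.

SI units internally (m, Pa, kg); meshes are millimetre-based.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from . import fem
from .boundary_conditions import SolidConstraints
from .mesh import MM, REGION_TAGS, TaggedMesh


class KinematicError(ValueError):
    """det F <= 0: non-physical deformation state."""


class SteppingError(RuntimeError):
    pass


# ---------------------------------------------------------------------------
# material
# ---------------------------------------------------------------------------

def material_from_engineering(E: float, nu: float) -> tuple[float, float]:
    """Shear and bulk moduli from Young's modulus and Poisson ratio.

    mu = E / (2 (1 + nu)),  kappa = E / (3 (1 - 2 nu)); unit-preserving.
    """
    if not 0.0 < nu < 0.5:
        raise ValueError(f"Poisson ratio must lie in (0, 0.5), got {nu}")
    if nu >= 0.4999:
        raise ValueError(f"nu = {nu} is numerically incompressible; "
                         "the bulk modulus would dwarf round-off")
    return E / (2.0 * (1.0 + nu)), E / (3.0 * (1.0 - 2.0 * nu))


@dataclass(frozen=True)
class SolidParams:
    """Wall tissue parameters (SI).

    ``young`` maps region names to Young's moduli in Pa; ``nu`` is shared.
    Defaults: bulge 0.75 MPa, parent artery 10x stiffer, nu = 0.45,
    density 1000 kg/m^3.
    """

    rho: float = 1000.0
    nu: float = 0.45
    young: dict = field(default_factory=lambda: {
        "artery-wall": 7.5e6, "bulge-wall": 0.75e6, "lumen": 7.5e6})

    def moduli(self, region_name: str) -> tuple[float, float]:
        return material_from_engineering(self.young[region_name], self.nu)


def stress_neo_hookean(F: np.ndarray, mu: float, kappa: float):
    """Volumetric Cauchy stress ps and deviatoric Cauchy stress dev[sigma].

    ps = U'(J) = kappa/2 (J - 1/J)  and  dev[sigma] = mu J^(-5/3) dev[F F^T].
    Accepts a single (3, 3) deformation gradient or a batch (..., 3, 3).
    """
    F = np.asarray(F, dtype=float)
    J = np.linalg.det(F)
    if np.any(J <= 0):
        raise KinematicError("det F <= 0")
    B = F @ np.swapaxes(F, -1, -2)
    trB = np.trace(B, axis1=-2, axis2=-1)
    dev = B - (trB / 3.0)[..., None, None] * np.eye(3)
    ps = 0.5 * kappa * (J - 1.0 / J)
    dev_sigma = mu * J[..., None, None] ** (-5.0 / 3.0) * dev
    return ps, dev_sigma


def second_piola_kirchhoff(C: np.ndarray, mu: float, kappa: float) -> np.ndarray:
    """S(C) with the volumetric law substituted (displacement form)."""
    C = np.asarray(C, dtype=float)
    J2 = np.linalg.det(C)
    J = np.sqrt(J2)
    Cinv = np.linalg.inv(C)
    I1 = np.trace(C, axis1=-2, axis2=-1)
    S_iso = mu * J[..., None, None] ** (-2.0 / 3.0) * (
        np.eye(3) - (I1 / 3.0)[..., None, None] * Cinv)
    S_vol = 0.5 * kappa * (J2 - 1.0)[..., None, None] * Cinv
    return S_iso + S_vol


def material_tangent(C: np.ndarray, mu: float, kappa: float) -> np.ndarray:
    """Analytic dS/dC (minor-symmetrized) of :func:`second_piola_kirchhoff`."""
    C = np.asarray(C, dtype=float)
    J2 = np.linalg.det(C)
    J = np.sqrt(J2)
    Ci = np.linalg.inv(C)
    I1 = np.trace(C)
    I = np.eye(3)
    CiCi = np.einsum("ij,kl->ijkl", Ci, Ci)
    dCi = -0.5 * (np.einsum("ik,jl->ijkl", Ci, Ci) + np.einsum("il,jk->ijkl", Ci, Ci))
    dev_part = I - (I1 / 3.0) * Ci
    dS_iso = mu * J ** (-2.0 / 3.0) * (
        -(1.0 / 3.0) * np.einsum("ij,kl->ijkl", dev_part, Ci)
        - (1.0 / 3.0) * np.einsum("kl,ij->ijkl", I, Ci)
        - (I1 / 3.0) * dCi)
    dS_vol = 0.5 * kappa * (J2 * CiCi + (J2 - 1.0) * dCi)
    return dS_iso + dS_vol


# ---------------------------------------------------------------------------
# state
# ---------------------------------------------------------------------------

@dataclass
class SolidState:
    """Displacement (m), velocity (m/s) and volumetric stress (Pa) fields."""

    u: np.ndarray
    udot: np.ndarray
    ps: np.ndarray
    t: float

    @classmethod
    def zero(cls, n: int, t: float = 0.0) -> "SolidState":
        return cls(np.zeros((n, 3)), np.zeros((n, 3)), np.zeros(n), t)

    def copy(self) -> "SolidState":
        return SolidState(self.u.copy(), self.udot.copy(), self.ps.copy(), self.t)


# ---------------------------------------------------------------------------
# solver
# ---------------------------------------------------------------------------

class SolidSolver:
    """Total-Lagrangian Newton solver for the mixed u-ps wall problem."""

    def __init__(self, mesh: TaggedMesh, params: SolidParams | None = None,
                 constraints: SolidConstraints | None = None,
                 newton_tol: float = 1e-8, newton_maxit: int = 25,
                 stab_coeff: float = 0.25) -> None:
        self.mesh = mesh
        self.params = params or SolidParams()
        self.newton_tol = newton_tol
        self.newton_maxit = newton_maxit
        self.verts0 = mesh.vertices * MM
        self.cells = mesh.cells
        self.n = len(self.verts0)
        self.vol0, self.g0 = fem.shape_gradients(self.verts0, self.cells)
        name_of = {v: k for k, v in REGION_TAGS.items()}
        mu_k = np.array([self.params.moduli(name_of[t]) for t in mesh.region_tags])
        self.mu_e = mu_k[:, 0]
        self.kappa_e = mu_k[:, 1]
        h = fem.element_size(self.vol0)
        self._stab = fem.scalar_laplacian(
            self.verts0, self.cells, stab_coeff * h ** 2 / (2.0 * self.mu_e))
        self._mass = fem.mass_matrix(self.verts0, self.cells)  # unit density
        if constraints is None:
            from .boundary_conditions import solid_constraints
            constraints = solid_constraints(mesh)
        self.fixed = constraints.fixed_vertices
        self._fixed_dofs = fem.expand_dofs(self.fixed)
        gd = np.empty((len(self.cells), 16), dtype=np.int64)
        gd[:, :12] = (3 * self.cells[:, :, None] + np.arange(3)).reshape(-1, 12)
        gd[:, 12:] = 3 * self.n + self.cells
        self._gd = gd
        self._pattern = None
        self._lu = None            # cached Newton factorization (modified Newton)
        self._lu_key = None

    # -- element residual (complex-step differentiable) -------------------
    def _element_residual(self, ue, pe):
        g0, vol0 = self.g0, self.vol0
        F = np.eye(3, dtype=ue.dtype) + np.einsum("mja,mjb->mab", ue, g0)
        J = np.linalg.det(F)
        if np.any(J.real <= 0):
            raise KinematicError("element inversion: det F <= 0")
        C = np.einsum("mca,mcb->mab", F, F)
        I1 = np.trace(C, axis1=-2, axis2=-1)
        Ji = 1.0 / J
        Cinv = np.linalg.inv(C)
        S_iso = self.mu_e[:, None, None] * (J ** (-2.0 / 3.0))[:, None, None] * (
            np.eye(3, dtype=ue.dtype) - (I1 / 3.0)[:, None, None] * Cinv)
        pbar = pe.mean(axis=1)
        S = S_iso + (pbar * J)[:, None, None] * Cinv
        P1 = np.einsum("mab,mbc->mac", F, S)
        r = np.empty((len(vol0), 16), dtype=ue.dtype)
        r[:, :12] = (vol0[:, None, None] * np.einsum("mab,mib->mia", P1, g0)).reshape(-1, 12)
        Up = 0.5 * self.kappa_e * (J - Ji)
        rp = (Up[:, None] / 4.0 - pe @ fem.MASS_W) * (vol0 / self.kappa_e)[:, None]
        r[:, 12:] = rp
        return r

    def _assemble(self, u, p):
        ue = u[self.cells]
        pe = p[self.cells]
        r_el = self._element_residual(ue, pe)
        res = np.zeros(4 * self.n)
        np.add.at(res, self._gd.ravel(), r_el.ravel())
        # complex-step element Jacobian
        m = len(self.cells)
        ke = np.empty((m, 16, 16))
        h = 1e-30
        x = np.concatenate([ue.reshape(m, 12), pe], axis=1).astype(complex)
        scale_p = np.maximum(self.kappa_e, 1.0)
        for k in range(16):
            xp = x.copy()
            step = h if k < 12 else h * scale_p
            if np.ndim(step) == 0:
                xp[:, k] += 1j * step
            else:
                xp[:, k] += 1j * step
            rc = self._element_residual(xp[:, :12].reshape(m, 4, 3), xp[:, 12:])
            ke[:, :, k] = rc.imag / (step if np.ndim(step) == 0 else step[:, None])
        if self._pattern is None:
            self._pattern = fem.AssemblyPattern(self._gd, 4 * self.n)
        K = self._pattern.assemble(ke)
        # pressure stabilization (linear): r_p -= tau Lap p
        Sb = self._stab
        res[3 * self.n:] -= Sb @ p
        K = K - sp.bmat([[sp.csr_matrix((3 * self.n, 3 * self.n)), None],
                         [None, Sb]], format="csr")
        return res, K

    def _solve_newton(self, u0, p0, ext_forces, inertia):
        """inertia: None (quasi-static) or (coef, rhs_field) with
        residual += coef * M u - M rhs_field (per component)."""
        u = u0.copy()
        p = p0.copy()
        fext = np.zeros(4 * self.n)
        fext[:3 * self.n] = np.asarray(ext_forces).ravel()
        f_scale = max(np.linalg.norm(fext), 1e-12)
        rho = self.params.rho
        M = self._mass

        def residual_only(u_, p_):
            ue = u_[self.cells]
            pe = p_[self.cells]
            r_el = self._element_residual(ue, pe)
            res_ = np.zeros(4 * self.n)
            np.add.at(res_, self._gd.ravel(), r_el.ravel())
            res_[3 * self.n:] -= self._stab @ p_
            if inertia is not None:
                coef_, rhs_ = inertia
                for c in range(3):
                    res_[c:3 * self.n:3] += rho * (coef_ * (M @ u_[:, c])
                                                   - M @ rhs_[:, c])
            res_ -= fext
            res_[self._fixed_dofs] = 0.0
            return res_

        def refresh_jacobian(u_, p_):
            res_, K = self._assemble(u_, p_)
            if inertia is not None:
                coef_, _ = inertia
                blocks = sp.kron(M * rho * coef_, sp.eye(3), format="csr")
                K = K + sp.bmat([[blocks, None],
                                 [None, sp.csr_matrix((self.n, self.n))]],
                                format="csr")
            Kd, _ = fem.apply_dirichlet(K, np.zeros(4 * self.n), self._fixed_dofs,
                                        np.zeros(len(self._fixed_dofs)))
            self._lu = spla.splu(Kd.tocsc())
            self._lu_key = (inertia[0] if inertia is not None else None)

        # modified Newton: the factorization is reused across iterations (and
        # calls) while the residual keeps dropping; it is refreshed whenever
        # progress degrades, recovering full Newton behaviour when needed
        rnorm = np.linalg.norm(residual_only(u, p))
        fresh = False
        if self._lu is None or self._lu_key != (inertia[0] if inertia is not None else None):
            refresh_jacobian(u, p)
            fresh = True
        best = rnorm
        stall = 0
        for it in range(self.newton_maxit):
            if rnorm < self.newton_tol * max(1.0, f_scale):
                break
            if it >= 8 and not fresh:
                # modified Newton is not contracting: fall back to full Newton
                refresh_jacobian(u, p)
                fresh = True
            res = residual_only(u, p)
            dx = self._lu.solve(-res)
            if not np.all(np.isfinite(dx)):
                raise SteppingError("Newton update is non-finite")
            du = dx[:3 * self.n].reshape(-1, 3)
            dp = dx[3 * self.n:]
            # nonmonotone backtracking: prefer a decreasing step, otherwise
            # take the best admissible fraction (lets the iteration traverse
            # limit points of the thin shell instead of deadlocking)
            alpha, cand = 1.0, None
            for _ in range(12):
                try:
                    rt = np.linalg.norm(residual_only(u + alpha * du, p + alpha * dp))
                except KinematicError:
                    alpha *= 0.5
                    continue
                if cand is None or rt < cand[1]:
                    cand = (alpha, rt)
                if rt < rnorm:
                    break
                alpha *= 0.5
            if cand is None:
                # every fraction of the step inverts an element
                if fresh:
                    raise SteppingError("Newton line search failed: element inversion")
                refresh_jacobian(u, p)
                fresh = True
                continue
            alpha, rt = cand
            was_fresh = fresh
            u = u + alpha * du
            p = p + alpha * dp
            rnorm = rt
            if rt < 0.99 * best:
                best = rt
                stall = 0
                fresh = False
            else:
                stall += 1
                if not was_fresh:
                    refresh_jacobian(u, p)
                    fresh = True
                elif stall > 8:
                    raise SteppingError(
                        f"Newton stalled (it {it}, |r|={rnorm:.3e})")
                else:
                    fresh = False
        else:
            raise SteppingError(
                f"Newton did not converge ({self.newton_maxit} its, |r|={rnorm:.3e})")
        return u, p

    # -- public drivers ---------------------------------------------------
    def static_solve(self, ext_forces: np.ndarray,
                     state0: SolidState | None = None) -> SolidState:
        """Quasi-static equilibrium under dead nodal loads (N per vertex)."""
        s0 = state0 or SolidState.zero(self.n)
        u, p = self._solve_newton(s0.u, s0.ps, ext_forces, inertia=None)
        return SolidState(u, np.zeros_like(u), p, s0.t)

    def advance(self, prev: SolidState, prev2: SolidState | None,
                ext_forces: np.ndarray, dt: float) -> SolidState:
        """One dynamic step with BDF2 inertia (BDF1 on the first step)."""
        if dt <= 0:
            raise ValueError("dt must be positive")
        bdf2 = prev2 is not None
        a0, a1, a2 = (1.5, -2.0, 0.5) if bdf2 else (1.0, -1.0, 0.0)
        un = prev.u
        unn = prev2.u if bdf2 else np.zeros_like(un)
        vn = prev.udot
        vnn = prev2.udot if bdf2 else np.zeros_like(vn)
        # udot = (a0 u + a1 un + a2 unn)/dt ; uddot = (a0 udot + a1 vn + a2 vnn)/dt
        coef = (a0 / dt) ** 2
        rhs_field = -(a0 / dt) * (a1 * un + a2 * unn) / dt - (a1 * vn + a2 * vnn) / dt
        u, p = self._solve_newton(prev.u, prev.ps, ext_forces, inertia=(coef, rhs_field))
        udot = (a0 * u + a1 * un + a2 * unn) / dt
        return SolidState(u, udot, p, prev.t + dt)

    # -- post-processing --------------------------------------------------
    def cauchy_stress(self, state: SolidState) -> np.ndarray:
        """Per-element Cauchy stress ps I + dev[sigma] (mixed-field ps)."""
        ue = state.u[self.cells]
        F = np.eye(3) + np.einsum("mja,mjb->mab", ue, self.g0)
        J = np.linalg.det(F)
        if np.any(J <= 0):
            raise KinematicError("det F <= 0")
        B = F @ np.swapaxes(F, -1, -2)
        trB = np.trace(B, axis1=1, axis2=2)
        dev = B - (trB / 3.0)[:, None, None] * np.eye(3)
        dev_sigma = self.mu_e[:, None, None] * (J ** (-5.0 / 3.0))[:, None, None] * dev
        pbar = state.ps[self.cells].mean(axis=1)
        return pbar[:, None, None] * np.eye(3) + dev_sigma

    def strain_energy(self, state: SolidState) -> float:
        """Stored hyperelastic energy int (U + W) dV0 (J, i.e. N m)."""
        ue = state.u[self.cells]
        F = np.eye(3) + np.einsum("mja,mjb->mab", ue, self.g0)
        J = np.linalg.det(F)
        C = np.einsum("mca,mcb->mab", F, F)
        I1b = np.trace(C, axis1=1, axis2=2) * J ** (-2.0 / 3.0)
        U = 0.25 * self.kappa_e * (J ** 2 - 1.0) - 0.5 * self.kappa_e * np.log(J)
        W = 0.5 * self.mu_e * (I1b - 3.0)
        return float(np.sum(self.vol0 * (U + W)))


def pressure_load(mesh: TaggedMesh, tag: str, pressure: float) -> np.ndarray:
    """Dead nodal forces (N) of a uniform pressure on a tagged surface.

    The traction is ``-pressure * n`` with n the outward surface normal of
    the solid, i.e. a positive pressure pushes into the body (use a negative
    value, or the "interface" tag of a shell, for inflation).
    """
    from .mesh import FACE_TAGS
    area, nrm = mesh.face_areas_normals()
    idx = np.flatnonzero(mesh.face_tags == FACE_TAGS[tag])
    out = np.zeros((len(mesh.vertices), 3))
    for fi in idx:
        f = -pressure * nrm[fi] * area[fi] * MM * MM / 3.0
        for vtx in mesh.faces[fi]:
            out[vtx] += f
    return out
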