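"""Partitioned fluid-structure coupling with Aitken dynamic relaxation.

Per time step, a Dirichlet-to-Neumann fixed point is iterated to
convergence: a predicted solid displacement moves the fluid mesh, the fluid
is solved with the interface velocity as Dirichlet data, the resulting
interface traction loads the solid, and the new solid displacement updates
the prediction through dynamic under-relaxation.  The relaxation factor
follows the momentum-accelerated Aitken Delta^2 recursion

    w_k = -w_{k-1} * r_{k-1}^T (r_k - r_{k-1}) / ||r_k - r_{k-1}||^2,

seeded with a fixed w0 for the first two sub-increments.  Time is advanced
only once the node-count-scaled residual norm drops below the coupling
tolerance (1e-5 mm by default).  This sub-iterated strong coupling is what
keeps the slender-walled, density-matched haemodynamic problem stable
against the added-mass effect.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .fluid_ale import FlowState, FluidSolver, MeshMotion, MeshMotionSolver, _bdf_coeffs
from .fluid_ale import SteppingError as FluidSteppingError
from .solid_mech import KinematicError, SolidSolver, SolidState
from .solid_mech import SteppingError as SolidSteppingError

MM_PER_M = 1000.0


class CouplingError(RuntimeError):
    pass


@dataclass(frozen=True)
class CouplingConfig:
    """Fixed-point controls: tolerance in millimetres, initial relaxation."""

    tol_fsi: float = 1e-5          # mm, on the node-scaled residual norm
    omega0: float = 0.1
    max_subiters: int = 50
    omega_clamp: tuple[float, float] = (1e-4, 2.0)
    max_update: float = 0.05       # mm, trust-region cap on one relax update

    def __post_init__(self) -> None:
        if self.tol_fsi <= 0:
            raise ValueError("tol_fsi must be positive")
        if not 0.0 < self.omega0 <= 1.0:
            raise ValueError("omega0 must lie in (0, 1]")


@dataclass
class CouplingState:
    """Per-step iteration log: residual norms (mm) and relaxation factors."""

    k: int = 0
    r_norms: list = field(default_factory=list)
    omegas: list = field(default_factory=list)


# ---------------------------------------------------------------------------
# elementary operations
# ---------------------------------------------------------------------------

def fsi_residual(u_new: np.ndarray, u_pred: np.ndarray) -> tuple[np.ndarray, float]:
    """r = u_new - u_pred and its Euclidean norm scaled by the node count.

    Fields are metres; the returned norm is in millimetres, matching the
    coupling tolerance convention.
    """
    u_new = np.asarray(u_new)
    u_pred = np.asarray(u_pred)
    if u_new.shape != u_pred.shape:
        raise ValueError("residual operands live on different node sets")
    r = u_new - u_pred
    n_nodes = r.reshape(-1, r.shape[-1]).shape[0] if r.ndim > 1 else len(r)
    return r, float(np.linalg.norm(r)) * MM_PER_M / n_nodes


def aitken_omega(omega_prev: float, r_prev: np.ndarray, r_curr: np.ndarray,
                 clamp: tuple[float, float] = (1e-4, 2.0)) -> float:
    """Aitken Delta^2 relaxation update (valid from the second sub-increment).

    The factor's magnitude is clamped to ``clamp`` while its sign is kept:
    strongly added-mass-coupled problems legitimately need very small (and
    occasionally negative) relaxation factors.  Raises on a degenerate
    (stalled) denominator.
    """
    dr = np.asarray(r_curr) - np.asarray(r_prev)
    den = float(np.vdot(dr, dr))
    if den == 0.0:
        raise ZeroDivisionError("Aitken update degenerate: residual stalled")
    omega = -omega_prev * float(np.vdot(r_prev, dr)) / den
    if clamp is None:
        return omega
    lo, hi = clamp
    sign = 1.0 if omega >= 0 else -1.0
    return float(sign * np.clip(abs(omega), lo, hi))


def relax(u_pred: np.ndarray, r: np.ndarray, omega: float) -> np.ndarray:
    """u_pred_next = u_pred + omega * r."""
    return np.asarray(u_pred) + omega * np.asarray(r)


def predict_displacement(u_t: np.ndarray | None,
                         u_t_minus_1: np.ndarray | None) -> np.ndarray:
    """Linear extrapolation 2 u_t - u_{t-1}; falls back on shorter history."""
    if u_t is None:
        raise ValueError("predictor needs at least the current level or zeros")
    if u_t_minus_1 is None:
        return np.array(u_t, copy=True)
    return 2.0 * np.asarray(u_t) - np.asarray(u_t_minus_1)


# ---------------------------------------------------------------------------
# coupled step
# ---------------------------------------------------------------------------

class FSIDriver:
    """Couples a :class:`FluidSolver`, :class:`SolidSolver` and mesh motion.

    The fluid and solid meshes must have vertex-matched interface
    triangulations (as produced by the package's meshing, where the solid is
    extruded from the fluid interface), so tractions and displacements
    transfer without interpolation.
    """

    def __init__(self, fluid: FluidSolver, solid: SolidSolver,
                 motion: MeshMotionSolver, cfg: CouplingConfig | None = None) -> None:
        self.fluid = fluid
        self.solid = solid
        self.motion = motion
        self.cfg = cfg or CouplingConfig()
        # interface vertex correspondence (exact coordinate match)
        fv = fluid.mesh.vertex_set("interface")
        sv = solid.mesh.vertex_set("interface")
        fc = fluid.mesh.vertices[fv]
        scv = solid.mesh.vertices[sv]
        from scipy.spatial import cKDTree
        d, j = cKDTree(scv).query(fc)
        if len(fv) != len(sv) or d.max() > 1e-9:
            raise CouplingError("fluid and solid interface meshes are not conforming")
        self.fluid_iverts = fv
        self.solid_iverts = sv[j]          # aligned with fluid_iverts
        self._mm_hist: list[MeshMotion] = []

    def interface_disp_from_solid(self, u_solid: np.ndarray) -> np.ndarray:
        return u_solid[self.solid_iverts]

    def coupled_step(self, flow_prev: FlowState, flow_prev2: FlowState | None,
                     solid_prev: SolidState, solid_prev2: SolidState | None,
                     dt: float, t_new: float,
                     inlet_values: np.ndarray | None = None,
                     outlet_model=None, outlet_scale: float = 1.0):
        """Advance fluid + solid by one strongly coupled time step.

        Returns ``(flow, solid, motion, log)``; raises
        :class:`CouplingError` after ``max_subiters`` non-converged
        sub-increments.
        """
        cfg = self.cfg
        a0, a1, a2 = _bdf_coeffs(flow_prev2 is not None)
        un = solid_prev.u
        unn = solid_prev2.u if solid_prev2 is not None else None
        u_pred = predict_displacement(un, unn)
        dn = self._mm_hist[-1].d_mesh if self._mm_hist else np.zeros((self.fluid.n, 3))
        dnn = self._mm_hist[-2].d_mesh if len(self._mm_hist) > 1 else np.zeros_like(dn)

        log = CouplingState()
        omega = cfg.omega0
        r_prev = None
        flow = solid = motion = None
        for k in range(cfg.max_subiters):
            try:
                iface_d = self.interface_disp_from_solid(u_pred)
                d_mesh = self.motion.solve(iface_d)
                vm = (a0 * d_mesh + a1 * dn + a2 * dnn) / dt
                motion = MeshMotion(d_mesh=d_mesh, vm=vm)
                flow = self.fluid.advance(flow_prev, flow_prev2, motion, dt, t_new,
                                          inlet_values=inlet_values,
                                          wall_velocity=vm,
                                          outlet_model=outlet_model,
                                          outlet_scale=outlet_scale)
                forces = -self.fluid.traction_nodal_forces("interface")
                solid_load = np.zeros((self.solid.n, 3))
                solid_load[self.solid_iverts] = forces[self.fluid_iverts]
                solid = self.solid.advance(solid_prev, solid_prev2, solid_load, dt)
            except (FluidSteppingError, SolidSteppingError, KinematicError) as e:
                # transient added-mass excursion (inverted fluid cell or a
                # non-solvable solid load): pull the prediction halfway back
                # towards the last converged level and retry
                if np.max(np.abs(u_pred - un)) < 1e-15:
                    raise CouplingError(
                        f"subproblem unsolvable at t={t_new} (subiter {k}) even "
                        f"from the last converged interface level: {e}") from e
                u_pred = 0.5 * (u_pred + un)
                omega = 0.5 * cfg.omega0
                r_prev = None
                continue
            r, r_norm = fsi_residual(solid.u, u_pred)
            log.k = k + 1
            log.r_norms.append(r_norm)
            log.omegas.append(omega)
            if r_norm < cfg.tol_fsi:
                break
            if k >= 1 and r_prev is not None:
                try:
                    omega = aitken_omega(omega, r_prev, r, clamp=cfg.omega_clamp)
                except ZeroDivisionError:
                    omega = cfg.omega0
            # anti-oscillation safeguard: a period-2 limit cycle of the
            # relaxed map shows up as r_k ~ r_{k-2} without contraction;
            # bisect the factor until the iteration contracts again
            if len(log.r_norms) >= 3 and \
                    log.r_norms[-1] >= 0.9 * log.r_norms[-3]:
                omega = 0.5 * abs(omega)
            # trust region: cap the largest nodal move of one relax update
            step_mm = abs(omega) * float(np.abs(r).max()) * MM_PER_M
            scale = min(1.0, cfg.max_update / step_mm) if step_mm > 0 else 1.0
            u_pred = relax(u_pred, r, scale * omega)
            r_prev = r
        else:
            raise CouplingError(
                f"FSI fixed point not reached at t={t_new}: residuals {log.r_norms}")
        self._mm_hist.append(motion)
        if len(self._mm_hist) > 2:
            self._mm_hist.pop(0)
        return flow, solid, motion, log
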