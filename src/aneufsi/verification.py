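"""Solver verification fixtures against independent analytic oracles.

Each check builds a small structured fixture, runs the production solvers on
it and compares against a closed form from :mod:`aneufsi.analytic` (or a
qualitative physical property for the travelling pressure wave).  They are
deliberately modest in size so the whole battery runs on one workstation
core in minutes; the report dictionaries state measured value, expectation
and tolerance.
"""

from __future__ import annotations

import numpy as np

from . import analytic
from .boundary_conditions import SolidConstraints
from .coupling import CouplingConfig, FSIDriver
from .fluid_ale import FlowState, FluidParams, FluidSolver, MeshMotionSolver
from .geometry import (MeshParams, make_sphere_shell_fixture, make_tube_fixture,
                       make_tube_shell)
from .mesh import MM
from .solid_mech import SolidParams, SolidSolver, SolidState, pressure_load


def _tube_inlet_parabola(mesh, solver, v_center):
    pts = mesh.vertices[solver.inlet_verts] * MM
    a = mesh.vertices[np.unique(mesh.faces_where("interface"))]
    radius = np.hypot(a[:, 0], a[:, 2]).max() * MM
    rho2 = (pts[:, 0] ** 2 + pts[:, 2] ** 2) / radius ** 2
    iv = np.zeros((len(pts), 3))
    iv[:, 1] = v_center * (1.0 - rho2)
    return iv, radius


def poiseuille_fixture(radius_mm: float = 2.0, length_mm: float = 8.0,
                       resolution: float = 0.7):
    """Steady tube flow at 4 mL/s; returns (solver, state, radius_m)."""
    bl = MeshParams(bl_growth=1.6, bl_first_layer=0.1, bl_total=0.3,
                    core_size=resolution)
    mesh = make_tube_fixture(radius_mm, length_mm, resolution, bl=bl)
    fs = FluidSolver(mesh)
    q = 4e-6
    a = radius_mm * MM
    v_center = 2.0 * q / (np.pi * a * a)
    iv, _ = _tube_inlet_parabola(mesh, fs, v_center)
    rest = FlowState(np.zeros((mesh.num_vertices, 3)), np.zeros(mesh.num_vertices), 0.0)
    st = fs.advance(rest, None, None, dt=50.0, t_new=50.0, inlet_values=iv)
    return fs, st, a


def poiseuille_check() -> dict:
    fs, st, a = poiseuille_fixture()
    mesh = fs.mesh
    from .fluid_ale import fluid_traction
    tr = fluid_traction(fs, st, "interface")
    wv = fs.wall_verts
    pos = mesh.vertices[wv]
    nrm = pos.copy()
    nrm[:, 1] = 0.0
    nrm /= np.linalg.norm(nrm, axis=1, keepdims=True)
    tt = tr[wv] - np.einsum("ij,ij->i", tr[wv], nrm)[:, None] * nrm
    inner = (pos[:, 1] > 2.0) & (pos[:, 1] < 6.0)
    measured = float(np.linalg.norm(tt[inner], axis=1).mean())
    expected = analytic.poiseuille_wall_shear(4e-6, a, fs.params.mu)
    rel = abs(measured - expected) / expected
    return {"name": "poiseuille", "measured": measured, "expected": expected,
            "tol": 0.02, "rel_error": rel, "passed": rel < 0.02}


def womersley_check(n_steps: int = 80) -> dict:
    """Oscillatory pipe flow vs the Bessel-series solution, L2 over a period."""
    radius_mm, length_mm = 2.0, 4.0
    period = 0.8
    omega = 2 * np.pi / period
    rho, mu = 1000.0, 0.004
    grad_p = 4000.0   # body-force amplitude, Pa/m
    bl = MeshParams(bl_growth=1.6, bl_first_layer=0.15, bl_total=0.3, core_size=0.5)
    mesh = make_tube_fixture(radius_mm, length_mm, 0.5, bl=bl)
    fs = FluidSolver(mesh, FluidParams(rho=rho, mu=mu))
    a = radius_mm * MM
    pts = mesh.vertices * MM
    r = np.hypot(pts[:, 0], pts[:, 2])
    r = np.minimum(r, a)

    def exact(t):
        return analytic.womersley_velocity(r, t, a, rho, mu, omega, grad_p)

    def state_at(t):
        v = np.zeros((len(pts), 3))
        v[:, 1] = exact(t)
        return FlowState(v, np.zeros(len(pts)), t)

    dt = period / n_steps
    prev2, prev = state_at(-dt), state_at(0.0)
    out_verts = np.unique(mesh.faces_where("outlet"))
    extra_dofs = (3 * out_verts[:, None] + np.arange(3)).ravel()
    num, den = 0.0, 0.0
    interior = (pts[:, 1] > 0.001) & (pts[:, 1] < 0.003)
    for k in range(1, n_steps + 1):
        t = k * dt
        ue = exact(t)
        iv = np.zeros((len(fs.inlet_verts), 3))
        iv[:, 1] = ue[fs.inlet_verts]
        ev = np.zeros((len(out_verts), 3))
        ev[:, 1] = ue[out_verts]
        st = fs.advance(prev, prev2, None, dt, t, inlet_values=iv,
                        body_force=(0.0, grad_p * np.cos(omega * t), 0.0),
                        extra_dirichlet=(extra_dofs, ev.ravel()))
        prev2, prev = prev, st
        num += np.sum((st.v[interior, 1] - ue[interior]) ** 2)
        den += np.sum(ue[interior] ** 2)
    rel = float(np.sqrt(num / den))
    return {"name": "womersley", "measured": rel, "expected": 0.0, "tol": 0.03,
            "rel_error": rel, "passed": rel < 0.03,
            "womersley_number": analytic.womersley_number(a, period, rho, mu)}


def inflation_check() -> dict:
    """Thin spherical shell under internal pressure vs the Laplace law."""
    radius_mm, thick_mm, p = 10.0, 0.25, 100.0
    shell = make_sphere_shell_fixture(radius_mm, thick_mm, layers=2, subdiv=2)
    v = shell.vertices
    pins = np.array([np.argmax(v[:, 0]), np.argmax(v[:, 1]), np.argmax(v[:, 2])])
    E = 0.75e6
    params = SolidParams(young={"artery-wall": E, "bulge-wall": E, "lumen": E})
    ss = SolidSolver(shell, params, SolidConstraints(pins))
    st = ss.static_solve(pressure_load(shell, "interface", p))
    sig = ss.cauchy_stress(st)
    cent = shell.vertices[shell.cells].mean(axis=1)
    nrm = cent / np.linalg.norm(cent, axis=1, keepdims=True)
    snn = np.einsum("mi,mij,mj->m", nrm, sig, nrm)
    hoop = float(((np.trace(sig, axis1=1, axis2=2) - snn) / 2).mean())
    expected = analytic.laplace_hoop_stress(p, radius_mm * MM, thick_mm * MM)
    rel = abs(hoop - expected) / expected
    return {"name": "inflation", "measured": hoop, "expected": expected,
            "tol": 0.05, "rel_error": rel, "passed": rel < 0.05}


def _pressure_wave_setup(resolution: float = 1.6):
    """Elastic straight tube, pressure pulse at one end (classic FSI benchmark)."""
    radius_mm, length_mm, thick_mm = 5.0, 50.0, 1.0
    mesh = make_tube_fixture(radius_mm, length_mm, resolution)
    solid = make_tube_shell(mesh, thick_mm, layers=1)
    E = 3.0e6
    sparams = SolidParams(rho=1200.0, nu=0.3,
                          young={"artery-wall": E, "bulge-wall": E, "lumen": E})
    fs = FluidSolver(mesh, FluidParams(rho=1000.0, mu=0.003))
    from .boundary_conditions import solid_constraints
    ss = SolidSolver(solid, sparams, solid_constraints(solid))
    mm = MeshMotionSolver(mesh, gamma_floor=0.2 * MM)
    return mesh, fs, ss, mm


def pressure_wave_check(n_steps: int = 12, dt: float = 1e-4,
                        cfg: CouplingConfig | None = None,
                        collect_iters: bool = False) -> dict:
    """A pressure pulse at the tube end must travel downstream monotonically."""
    from .boundary_conditions import OutletModel
    mesh, fs, ss, mm = _pressure_wave_setup()
    # slender shell + matched densities: a strongly added-mass-coupled case,
    # started with a gentler relaxation and a tight trust region
    cfg = cfg or CouplingConfig(tol_fsi=1e-5, omega0=0.02, max_subiters=120,
                                max_update=0.005)
    driver = FSIDriver(fs, ss, mm, cfg)
    f_prev = FlowState(np.zeros((mesh.num_vertices, 3)), np.zeros(mesh.num_vertices), 0.0)
    f_prev2 = None
    s_prev = SolidState.zero(ss.n)
    s_prev2 = None
    pulse_kpa = 1.3332
    peaks = []
    iters = []
    sv = ss.mesh.vertices
    for k in range(1, n_steps + 1):
        t = k * dt
        # pulse applied for 3 ms through the weak outlet traction (y = L end)
        p_now = pulse_kpa if t <= 3e-3 else 0.0
        om = OutletModel(P0=p_now, Rd=1e-12)
        flow, solid_st, motion, log = driver.coupled_step(
            f_prev, f_prev2, s_prev, s_prev2, dt, t, inlet_values=None,
            outlet_model=om)
        f_prev2, f_prev = f_prev, flow
        s_prev2, s_prev = s_prev, solid_st
        iters.append(log.k)
        mag = np.linalg.norm(solid_st.u, axis=1)
        peaks.append(float(np.average(sv[:, 1], weights=np.maximum(mag, 1e-18) ** 2)))
    # the wave enters at y = L and travels towards y = 0
    drops = np.diff(peaks)
    monotone = bool(np.all(drops[2:] < 1e-9))
    out = {"name": "pressure_wave", "measured": peaks, "expected":
           "displacement-energy centroid moves monotonically downstream",
           "tol": None, "passed": monotone, "subiters": iters}
    if collect_iters:
        out["mean_subiters"] = float(np.mean(iters))
    return out


def rigid_limit_check(n_steps: int = 8, dt: float = 2e-3) -> dict:
    """Coupled solver with a near-rigid wall must match the pure-CFD run."""
    mesh = make_tube_fixture(2.0, 10.0, 0.65)
    fs_r = FluidSolver(mesh)
    fs_c = FluidSolver(mesh)
    solid = make_tube_shell(mesh, 0.25, layers=1)
    stiff = SolidParams(young={k: 7.5e6 * 1e6 for k in
                               ("artery-wall", "bulge-wall", "lumen")})
    from .boundary_conditions import solid_constraints, OutletModel
    ss = SolidSolver(solid, stiff, solid_constraints(solid))
    mm = MeshMotionSolver(mesh, gamma_floor=0.2 * MM)
    driver = FSIDriver(fs_c, ss, mm, CouplingConfig(tol_fsi=1e-6))
    a = 2e-3
    v_center = 2 * 4e-6 / (np.pi * a * a)
    iv, _ = _tube_inlet_parabola(mesh, fs_r, v_center)
    om = OutletModel(P0=1.0, Rd=0.1)
    n = mesh.num_vertices
    fr = FlowState(np.zeros((n, 3)), np.zeros(n), 0.0)
    fr2 = None
    fc, fc2 = fr.copy(), None
    sp, sp2 = SolidState.zero(ss.n), None
    max_iface = 0.0
    for k in range(1, n_steps + 1):
        t = k * dt
        ramp = min(t / (4 * dt), 1.0)
        st_r = fs_r.advance(fr, fr2, None, dt, t, inlet_values=ramp * iv,
                            outlet_model=om)
        fr2, fr = fr, st_r
        st_c, sol, motion, _ = driver.coupled_step(fc, fc2, sp, sp2, dt, t,
                                                   inlet_values=ramp * iv,
                                                   outlet_model=om)
        fc2, fc = fc, st_c
        sp2, sp = sp, sol
        max_iface = max(max_iface, float(np.linalg.norm(
            motion.d_mesh, axis=1).max()) / MM)
    rel = float(np.linalg.norm(fc.v - fr.v) / np.linalg.norm(fr.v))
    return {"name": "rigid_limit", "measured": rel, "expected": 0.0, "tol": 5e-3,
            "rel_error": rel, "max_interface_disp_mm": max_iface,
            "passed": rel < 5e-3 and max_iface < 1e-4}
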