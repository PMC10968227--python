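"""Inflow waveform, inlet profile, resistance outlet and solid constraints.

The parent-vessel inflow is a parabolic (Poiseuille-shaped) velocity profile
whose centreline amplitude follows a pulsatile internal-carotid-like waveform
V(t): a 0.2 s linear start-up ramp followed by a periodic pulse of period
T = 0.8 s, amplitude-calibrated so that the cycle-averaged volumetric flow
equals a target (4 mL/s by default).  The outlet carries a resistance
pressure condition P = P0 + Rd * Q_out emulating the downstream vasculature.
Solid walls are clamped on the inflow/outflow plane y = 0 and traction-free
on the exterior surface.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .geometry import CaseGeometryParams
from .mesh import FACE_TAGS, MeshError, TaggedMesh

KPA_PER_MMHG = 0.1333223684


class BoundaryConditionError(ValueError):
    pass


# ---------------------------------------------------------------------------
# waveform
# ---------------------------------------------------------------------------

def _periodic_gaussian(s: np.ndarray, mu: float, sig: float) -> np.ndarray:
    d = (s - mu + 0.5) % 1.0 - 0.5
    return np.exp(-0.5 * (d / sig) ** 2)


def ica_pulse_shape(n: int = 512, peak_factor: float = 1.63) -> tuple[np.ndarray, np.ndarray]:
    """Synthetic internal-carotid-like pulse, unit mean, given peak/mean ratio.

    A sharp systolic peak near 15% of the cycle and a broader dicrotic bump
    near 42% ride on a diastolic baseline; the deviation from baseline is
    rescaled so the peak-to-mean ratio is exactly ``peak_factor`` (1.63 gives
    a peak Reynolds number of ~520 in the 4 mm parent vessel at 4 mL/s).
    """
    s = np.arange(n) / n
    f = 1.0 + 1.2 * _periodic_gaussian(s, 0.15, 0.07) + 0.5 * _periodic_gaussian(s, 0.42, 0.10)
    f /= f.mean()
    beta = (peak_factor - 1.0) / (f.max() - 1.0)
    f = 1.0 + beta * (f - 1.0)
    f /= f.mean()
    return s, f


@dataclass
class Waveform:
    """Ramped periodic centreline-velocity waveform.

    ``shape_s``/``shape_v`` sample one period on [0, 1) with unit mean
    (periodic linear interpolation); ``scale`` (m/s) is the calibrated
    centreline-velocity multiplier.  V(t) rises linearly from zero over
    ``ramp_duration`` to the periodic pulse, which then repeats with period
    ``period``.
    """

    period: float = 0.8
    ramp_duration: float = 0.2
    shape_s: np.ndarray = field(default_factory=lambda: ica_pulse_shape()[0])
    shape_v: np.ndarray = field(default_factory=lambda: ica_pulse_shape()[1])
    scale: float = 1.0

    def __post_init__(self) -> None:
        self.shape_s = np.asarray(self.shape_s, dtype=float)
        self.shape_v = np.asarray(self.shape_v, dtype=float)
        if np.any(self.shape_v <= 0):
            raise BoundaryConditionError("waveform shape samples must be positive "
                                         "(reverse inlet flow is unsupported)")
        m = self.shape_v.mean()
        if abs(m - 1.0) > 1e-10:
            self.shape_v = self.shape_v / m

    def shape_at(self, phase: np.ndarray) -> np.ndarray:
        """Periodic linear interpolation of the unit-mean shape."""
        ph = np.asarray(phase, dtype=float) % 1.0
        s = np.concatenate([self.shape_s, [1.0]])
        v = np.concatenate([self.shape_v, self.shape_v[:1]])
        return np.interp(ph, s, v)

    def __call__(self, t):
        """Centreline velocity V(t) in m/s."""
        t = np.asarray(t, dtype=float)
        phase = (t - self.ramp_duration) / self.period
        v = self.scale * self.shape_at(phase)
        out = np.where(t < self.ramp_duration,
                       np.clip(t / max(self.ramp_duration, 1e-300), 0, 1)
                       * self.scale * self.shape_at(0.0), v)
        return out if out.ndim else float(out)


def build_waveform(shape_spec: tuple[np.ndarray, np.ndarray] | None = None,
                   target_mean_flow: float = 4.0,
                   inlet_area: float | None = None,
                   geom: CaseGeometryParams | None = None,
                   period: float = 0.8, ramp_duration: float = 0.2) -> Waveform:
    """Calibrate the waveform amplitude to a target cycle-mean flow.

    Parameters
    ----------
    shape_spec : optional ``(s, v)`` samples of one period (unit mean enforced).
    target_mean_flow : mL/s, cycle-averaged volumetric flow through the inlet.
    inlet_area : mm^2; defaults to the case-R inlet disc area.

    The parabolic profile's disc average is half the centreline value, so the
    calibration is exact: scale = 2 * Q_mean / A.
    """
    if target_mean_flow <= 0:
        raise BoundaryConditionError("target_mean_flow must be positive")
    geom = geom or CaseGeometryParams()
    if inlet_area is None:
        inlet_area = np.pi * geom.tube_radius ** 2
    s, v = shape_spec if shape_spec is not None else ica_pulse_shape()
    area_m2 = inlet_area * 1e-6
    q_m3s = target_mean_flow * 1e-6
    scale = 2.0 * q_m3s / area_m2
    return Waveform(period=period, ramp_duration=ramp_duration,
                    shape_s=s, shape_v=v, scale=scale)


def waveform_to_csv(wf: Waveform, path, n: int = 512) -> None:
    t = wf.ramp_duration + wf.period * np.arange(n) / n
    np.savetxt(path, np.stack([t, wf(t)], axis=1), delimiter=",",
               header="t_s,V_m_per_s", comments="")


def waveform_from_csv(path, **kwargs) -> Waveform:
    data = np.loadtxt(path, delimiter=",", skiprows=1)
    t, v = data[:, 0], data[:, 1]
    period = kwargs.pop("period", 0.8)
    s = ((t - t[0]) / period) % 1.0
    order = np.argsort(s)
    wf = Waveform(period=period, shape_s=s[order], shape_v=v[order] / v.mean(), **kwargs)
    wf.scale = v.mean()
    return wf


# ---------------------------------------------------------------------------
# inlet profile / outlet model
# ---------------------------------------------------------------------------

def inlet_velocity(x: np.ndarray, t: float, wf: Waveform,
                   geom: CaseGeometryParams | None = None) -> np.ndarray:
    """Parabolic inlet velocity (m/s) at point(s) ``x`` (mm) on the inlet disc.

    v = V(t) (1 - (rho / r)^2) e_y with rho the in-disc distance from the
    inlet centre; zero at the rim, V(t) on the centreline.
    """
    geom = geom or CaseGeometryParams()
    x = np.atleast_2d(np.asarray(x, dtype=float))
    center = np.array([geom.torus_major_radius, 0.0, 0.0])
    rho = np.sqrt((x[:, 0] - center[0]) ** 2 + x[:, 2] ** 2)
    if np.any(np.abs(x[:, 1]) > 1e-6) or np.any(rho > geom.tube_radius * (1 + 1e-9)):
        raise BoundaryConditionError("point is not on the inlet disc")
    v = np.zeros_like(x)
    v[:, 1] = wf(t) * (1.0 - (rho / geom.tube_radius) ** 2)
    return v if len(v) > 1 else v[0]


@dataclass(frozen=True)
class OutletModel:
    """Resistance outlet: P = P0 + Rd * Q_out (kPa, with Q_out in mL/s)."""

    P0: float = -3.7      # kPa
    Rd: float = 1.31      # kPa * s / mL

    def __post_init__(self) -> None:
        if self.Rd <= 0:
            raise BoundaryConditionError("hydraulic resistance Rd must be positive")


def outlet_pressure(q_out_ml_s, model: OutletModel | None = None):
    """Outlet pressure in kPa for an instantaneous outlet flux in mL/s."""
    model = model or OutletModel()
    return model.P0 + model.Rd * np.asarray(q_out_ml_s, dtype=float)


def inlet_flow_series(wf: Waveform, t: np.ndarray,
                      geom: CaseGeometryParams | None = None) -> np.ndarray:
    """Volumetric inflow Q(t) in mL/s (parabolic disc mean is half the peak)."""
    geom = geom or CaseGeometryParams()
    area_m2 = np.pi * (geom.tube_radius * 1e-3) ** 2
    return 0.5 * wf(np.asarray(t)) * area_m2 * 1e6


# ---------------------------------------------------------------------------
# dimensionless numbers
# ---------------------------------------------------------------------------

def waveform_stats(wf: Waveform, fluid=None, geom: CaseGeometryParams | None = None) -> dict:
    """Mean/peak flow, peak Reynolds and Womersley numbers of the inflow.

    Re_peak = rho Q_peak D / (mu A);  Wo = (D/2) sqrt(2 pi rho / (T mu)).
    """
    from .fluid_ale import FluidParams
    fluid = fluid or FluidParams()
    geom = geom or CaseGeometryParams()
    D = geom.inlet_diameter * 1e-3
    A = np.pi * (D / 2) ** 2
    t = wf.ramp_duration + wf.period * np.arange(4096) / 4096
    q = inlet_flow_series(wf, t, geom)  # mL/s
    q_peak = q.max() * 1e-6
    q_mean = q.mean() * 1e-6
    re_peak = fluid.rho * q_peak * D / (fluid.mu * A)
    wo = (D / 2) * np.sqrt(2 * np.pi * fluid.rho / (wf.period * fluid.mu))
    return {"mean_flow_ml_s": q_mean * 1e6, "peak_flow_ml_s": q_peak * 1e6,
            "peak_reynolds": re_peak, "womersley": wo}


# ---------------------------------------------------------------------------
# solid constraints
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SolidConstraints:
    """Homogeneous Dirichlet vertex set; everything else is traction-free."""

    fixed_vertices: np.ndarray


def solid_constraints(mesh: TaggedMesh, tol: float = 1e-6) -> SolidConstraints:
    """Clamp solid nodes on the inflow/outflow plane y = 0.

    Uses the fixed-plane face tag when present, otherwise the |y| < tol (mm)
    predicate; the exterior surface carries no constraint (traction-free).
    """
    if np.any(mesh.face_tags == FACE_TAGS["fixed-plane"]):
        fixed = mesh.vertex_set("fixed-plane")
    else:
        fixed = np.flatnonzero(np.abs(mesh.vertices[:, 1]) < tol)
    if len(fixed) == 0:
        raise MeshError("no solid nodes on the fixation plane y=0")
    return SolidConstraints(fixed_vertices=np.asarray(fixed, dtype=np.int64))
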