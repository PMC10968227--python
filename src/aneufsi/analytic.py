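"""Closed-form reference solutions used for verification.

Independent analytic oracles (they never call the finite-element code):
steady Poiseuille pipe flow, the Womersley pulsatile pipe-flow series, the
thin-shell Laplace law and spherical-cap volumes.
"""

from __future__ import annotations

import numpy as np
from scipy.special import jv


def poiseuille_wall_shear(q: float, a: float, mu: float) -> float:
    """Wall shear magnitude 4 mu Q / (pi a^3) of steady pipe flow (SI)."""
    return 4.0 * mu * q / (np.pi * a ** 3)


def poiseuille_pressure_drop(q: float, a: float, mu: float, length: float) -> float:
    """8 mu L Q / (pi a^4) (SI)."""
    return 8.0 * mu * length * q / (np.pi * a ** 4)


def womersley_number(radius: float, period: float, rho: float, mu: float) -> float:
    """alpha = R sqrt(omega rho / mu) with omega = 2 pi / T (SI)."""
    return radius * np.sqrt(2.0 * np.pi * rho / (period * mu))


def womersley_velocity(r: np.ndarray, t: np.ndarray, radius: float, rho: float,
                       mu: float, omega: float, grad_p: float) -> np.ndarray:
    """Axial velocity of oscillatory pipe flow driven by G cos(omega t).

    G is the pressure-gradient (or body-force) amplitude in Pa/m; the
    solution is u(r, t) = Re{ (i G / rho omega) [1 - J0(z r/R)/J0(z)] e^{i omega t} }
    with z = i^{3/2} alpha, alpha the Womersley number.  Broadcasts r and t.
    """
    alpha = radius * np.sqrt(omega * rho / mu)
    z = 1j ** 1.5 * alpha
    r = np.asarray(r, dtype=float)
    t = np.asarray(t, dtype=float)
    prof = 1.0 - jv(0, z * r / radius) / jv(0, z)
    phase = np.exp(1j * omega * t)
    return np.real((1j * grad_p / (rho * omega)) * prof * phase)


def laplace_hoop_stress(pressure: float, radius: float, thickness: float) -> float:
    """Mean in-plane stress P a / (2 h) of a pressurized thin spherical shell."""
    return pressure * radius / (2.0 * thickness)


def spherical_cap_volume(a: float, h: float) -> float:
    """Volume pi h^2 (3 a - h) / 3 of a cap of height h on a sphere of radius a."""
    return np.pi * h * h * (3.0 * a - h) / 3.0
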