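"""Wall-shear metrics, plane integrals, bulge volume and peak delays."""

import numpy as np
import pytest

from aneufsi.analytic import spherical_cap_volume
from aneufsi.geometry import _icosphere, make_tube_fixture
from aneufsi.haemodynamics import (MetricError, WallSeries,
                                   aneurysm_volume_variation, bulge_avg_wss,
                                   field_difference, osi, peak_delay,
                                   swirl_rate, tawss, volume_above_plane,
                                   wall_shear_vector)


def _series(times, tau, n_verts=None, y=None):
    n = tau.shape[1]
    verts = np.zeros((n, 3))
    if y is not None:
        verts[:, 1] = y
    normals = np.tile([0.0, 0.0, 1.0], (n, 1))
    areas = np.ones(n)
    return WallSeries(np.asarray(times), tau, verts, normals, areas)


class TestWallShearVector:
    def test_pure_pressure_has_no_shear(self):
        sigma = -1234.0 * np.eye(3)
        n = np.array([0.0, 1.0, 0.0])
        assert np.allclose(wall_shear_vector(sigma, n), 0.0)

    def test_newtonian_shear_flow(self):
        """v = (gd*y, 0, 0) against wall normal e_y: |tau| = mu * gd."""
        mu, gd = 0.004, 250.0
        grad_v = np.zeros((3, 3))
        grad_v[0, 1] = gd
        sigma = -50.0 * np.eye(3) + mu * (grad_v + grad_v.T)
        tau = wall_shear_vector(sigma, np.array([0.0, 1.0, 0.0]))
        assert np.linalg.norm(tau) == pytest.approx(mu * gd, rel=1e-12)
        assert tau[0] == pytest.approx(mu * gd)

    def test_poiseuille_wall_shear_magnitude(self):
        """Analytic sigma of pipe flow at the wall: 4 mu Q / (pi a^3)."""
        mu, q, a = 0.004, 4e-6, 2e-3
        gd = 4.0 * q / (np.pi * a ** 3)     # wall shear rate * mu = shear
        grad_v = np.zeros((3, 3))
        grad_v[1, 0] = -gd                   # dv_y/dr at the wall, r along x
        sigma = mu * (grad_v + grad_v.T)
        tau = wall_shear_vector(sigma, np.array([1.0, 0.0, 0.0]))
        assert np.linalg.norm(tau) == pytest.approx(2.546, rel=1e-3)

    def test_tangency(self, rng):
        sigma = rng.normal(size=(3, 3))
        n = np.array([0.0, 0.0, 1.0])
        assert abs(wall_shear_vector(sigma, n) @ n) < 1e-12

    def test_non_unit_normal_rejected(self):
        with pytest.raises(MetricError):
            wall_shear_vector(np.eye(3), np.array([0.0, 0.0, 2.0]))


class TestOSI:
    def test_constant_direction_zero(self):
        t = np.linspace(0, 0.8, 81)
        tau = np.zeros((81, 1, 3))
        tau[:, 0, 0] = 1.0 + 0.5 * np.sin(2 * np.pi * t / 0.8)
        assert osi(_series(t, tau))[0] == pytest.approx(0.0, abs=1e-12)

    def test_half_period_reversal_is_half(self):
        t = np.linspace(0, 1, 201)
        tau = np.zeros((201, 1, 3))
        tau[:, 0, 0] = np.where(t < 0.5, 2.0, -2.0)
        assert osi(_series(t, tau))[0] == pytest.approx(0.5, abs=5e-3)

    def test_uniformly_rotating_shear_is_half(self):
        t = np.linspace(0, 1, 721)
        tau = np.zeros((721, 2, 3))
        tau[:, 0, 0] = np.cos(2 * np.pi * t)
        tau[:, 0, 1] = np.sin(2 * np.pi * t)
        tau[:, 1, :] = 0.0                       # zero-shear vertex: OSI = 0
        vals = osi(_series(t, tau))
        assert vals[0] == pytest.approx(0.5, abs=1e-4)
        assert vals[1] == 0.0

    def test_bounds_for_random_histories(self, rng):
        t = np.linspace(0, 0.8, 41)
        tau = rng.normal(size=(41, 50, 3))
        vals = osi(_series(t, tau))
        assert np.all((vals >= 0.0) & (vals <= 0.5))


class TestTAWSS:
    def test_constant_magnitude(self):
        t = np.linspace(1.0, 1.8, 11)
        tau = np.zeros((11, 1, 3))
        tau[:, 0, 2] = 2.0
        assert tawss(_series(t, tau))[0] == pytest.approx(2.0, rel=1e-12)

    def test_half_sine_bump_mean(self):
        """|tau| = sin(pi s): the exact window mean is 2/pi."""
        t = np.linspace(0, 1, 2001)
        tau = np.zeros((2001, 1, 3))
        tau[:, 0, 0] = np.sin(np.pi * t)
        assert tawss(_series(t, tau))[0] == pytest.approx(2 / np.pi, rel=1e-5)

    def test_dominates_mean_vector_norm(self, rng):
        t = np.linspace(0, 0.8, 33)
        tau = rng.normal(size=(33, 20, 3))
        s = _series(t, tau)
        mean_vec = np.linalg.norm(np.trapezoid(tau, t, axis=0), axis=-1) / 0.8
        assert np.all(tawss(s) >= mean_vec - 1e-12)


class TestBulgeAverage:
    def test_uniform_field(self):
        t = np.linspace(0, 1, 5)
        tau = np.zeros((5, 4, 3))
        tau[..., 0] = 3.0
        s = _series(t, tau, y=np.array([9.0, 9.5, 10.0, 11.0]))
        assert np.allclose(bulge_avg_wss(s, 8.0), 3.0)

    def test_area_weighted_two_patches(self):
        t = np.linspace(0, 1, 3)
        tau = np.zeros((3, 2, 3))
        tau[:, 0, 0] = 1.0
        tau[:, 1, 0] = 3.0
        s = _series(t, tau, y=np.array([9.0, 9.0]))
        assert np.allclose(bulge_avg_wss(s, 8.0), 2.0)   # equal areas

    def test_empty_region_raises(self):
        t = np.linspace(0, 1, 3)
        tau = np.zeros((3, 2, 3))
        s = _series(t, tau, y=np.array([1.0, 2.0]))
        with pytest.raises(MetricError):
            bulge_avg_wss(s, 8.0)


@pytest.fixture(scope="module")
def tube():
    return make_tube_fixture(2.0, 10.0, 0.4)


class TestSwirlRate:
    def test_uniform_upward_flow(self, tube):
        v = np.zeros((tube.num_vertices, 3))
        v[:, 1] = 0.25
        q = swirl_rate(tube.vertices, tube.cells, v, plane_height=5.0)
        assert q == pytest.approx(0.25 * np.pi * 4.0, rel=0.01)

    def test_quiescent_is_zero(self, tube):
        v = np.zeros((tube.num_vertices, 3))
        assert swirl_rate(tube.vertices, tube.cells, v, 5.0) == 0.0

    def test_antisymmetric_field_positive_part(self, tube):
        """v_y = c x: zero net flux; the upward part is the half-disc integral."""
        c = 100.0  # 1/s
        v = np.zeros((tube.num_vertices, 3))
        v[:, 1] = c * tube.vertices[:, 0] * 1e-3
        q_pos = swirl_rate(tube.vertices, tube.cells, v, 5.0, positive_part=True)
        q_net = swirl_rate(tube.vertices, tube.cells, v, 5.0, positive_part=False)
        exact = c * (2.0 / 3.0) * 2.0 ** 3 * 1e-3   # int max(x,0) over the disc
        assert q_pos == pytest.approx(exact, rel=0.02)
        assert abs(q_net) < 0.02 * exact

    def test_plane_outside_lumen_raises(self, tube):
        v = np.zeros((tube.num_vertices, 3))
        with pytest.raises(MetricError):
            swirl_rate(tube.vertices, tube.cells, v, 40.0)


@pytest.fixture(scope="module")
def sphere():
    v, f = _icosphere(4)
    return 10.0 * v, f


class TestBulgeVolume:

    def test_spherical_cap_closed_form(self):
        """Cap cut 2 mm below the centre: V = pi h^2 (3a - h)/3, h = a + 2."""
        v, f = _icosphere(5)    # fine tessellation: volume deficit ~0.05%
        vol = volume_above_plane(10.0 * v, f, -2.0)
        assert vol == pytest.approx(spherical_cap_volume(10.0, 12.0), rel=1e-3)

    def test_undeformed_state_is_zero_percent(self, sphere):
        verts, tris = sphere
        pct, dv = aneurysm_volume_variation(verts, verts, tris, -2.0)
        assert pct == 0.0 and dv == 0.0

    def test_uniform_inflation_first_order(self, sphere):
        """Inflating by delta << a adds about delta * cap area."""
        verts, tris = sphere
        delta = 0.01
        inflated = verts * (1 + delta / 10.0)
        _, dv = aneurysm_volume_variation(inflated, verts, tris, -2.0)
        a, h = 10.0, 12.0
        cap_area = 2 * np.pi * a * h
        assert dv == pytest.approx(delta * cap_area, rel=0.05)

    def test_open_surface_above_cut_raises(self, sphere):
        verts, tris = sphere
        with pytest.raises(MetricError):
            volume_above_plane(verts, tris[:-20], -2.0)


class TestPeakDelay:
    def test_identical_series(self):
        t = np.linspace(1.0, 1.8, 400)
        y = np.sin(2 * np.pi * (t - 1.0) / 0.8)
        assert peak_delay(t, y, t, y) == 0.0

    def test_constructed_shift_recovered(self):
        t = np.linspace(1.0, 1.8, 801)       # 1 ms sampling
        a = np.sin(2 * np.pi * (t - 1.016) / 0.8)
        b = np.sin(2 * np.pi * (t - 1.0) / 0.8)
        assert peak_delay(t, a, t, b) == pytest.approx(16.0, abs=1.0)

    def test_antisymmetry(self):
        t = np.linspace(1.0, 1.8, 801)
        a = np.exp(-((t - 1.3) / 0.05) ** 2)
        b = np.exp(-((t - 1.35) / 0.05) ** 2)
        assert peak_delay(t, a, t, b) == pytest.approx(-peak_delay(t, b, t, a),
                                                       abs=1e-9)

    def test_flat_series_rejected(self):
        t = np.linspace(0, 1, 10)
        with pytest.raises(MetricError):
            peak_delay(t, np.ones(10), t, np.sin(t))


class TestFieldDifference:
    def test_identical_fields_zero_map(self, rng):
        a = rng.normal(size=50)
        assert np.all(field_difference(a, a.copy()) == 0.0)

    def test_swap_negates(self, rng):
        a, b = rng.normal(size=50), rng.normal(size=50)
        assert np.allclose(field_difference(a, b), -field_difference(b, a))

    def test_mean_linearity(self, rng):
        a, b = rng.normal(size=50), rng.normal(size=50)
        assert field_difference(a, b).mean() == pytest.approx(a.mean() - b.mean())

    def test_shape_mismatch_rejected(self):
        with pytest.raises(MetricError):
            field_difference(np.zeros(3), np.zeros(4))
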