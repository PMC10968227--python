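"""Haemodynamic metrics: WSS, TAWSS, OSI and the case diagnostics.

The wall shear vector is the tangential traction

    tau_WSS = sigma_f . n - (n . sigma_f . n) n,

recorded per surface vertex over a metric window covering one cardiac cycle.
From it follow the time-averaged WSS magnitude (TAWSS) and the oscillatory
shear index

    OSI = 1/2 (1 - ||int tau dt|| / int ||tau|| dt)  in [0, 1/2],

zero for unidirectional shear and 1/2 for perfectly reversing shear.  The
module also computes the bulge diagnostics used to compare rigid and
compliant wall modelling: the surface-averaged WSS over the bulge (y > 8 mm),
the swirl rate (upward-going flow through the horizontal plane at the
aneurysm centre), the aneurysm volume above the cut plane, and peak-to-peak
time delays between scalar series.

Lengths in millimetres, stresses in Pa, flows in mL/s.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .mesh import TaggedMesh


class MetricError(ValueError):
    pass


# ---------------------------------------------------------------------------
# wall shear
# ---------------------------------------------------------------------------

def wall_shear_vector(sigma_f: np.ndarray, n: np.ndarray) -> np.ndarray:
    """Tangential projection of the traction sigma_f . n (unit normal n).

    Accepts single or batched stress tensors (..., 3, 3) and normals (..., 3).
    """
    n = np.asarray(n, dtype=float)
    if not np.allclose(np.linalg.norm(n, axis=-1), 1.0, atol=1e-8):
        raise MetricError("wall normal must be unit length")
    t = np.einsum("...ij,...j->...i", np.asarray(sigma_f, dtype=float), n)
    return t - np.einsum("...i,...i->...", t, n)[..., None] * n


def project_tangential(tractions: np.ndarray, normals: np.ndarray) -> np.ndarray:
    """Tangential part of per-vertex traction vectors."""
    tn = np.einsum("...i,...i->...", tractions, normals)
    return tractions - tn[..., None] * normals


def viscous_wall_shear(coords_mm: np.ndarray, cells: np.ndarray,
                       v: np.ndarray, mu: float, wall_verts: np.ndarray,
                       normals: np.ndarray) -> np.ndarray:
    """Wall-shear vectors (Pa) from the cell-averaged viscous stress.

    Evaluates ``mu (grad v + grad v^T) n`` with the element-constant P1
    velocity gradient, volume-averaged onto vertices, and projects out the
    normal component.  ``normals`` are outward unit normals at
    ``wall_verts``.  This is the evaluation used for the haemodynamic WSS
    metrics: the variational (residual-based) boundary forces are exact
    discrete momentum fluxes — the right load for a coupled solid — but
    they include the stabilization's flux as well, whose grad-div part
    carries an effective viscosity orders of magnitude above ``mu`` and
    drowns a few-Pa physical shear wherever the discrete velocity is not
    divergence-free cell by cell.
    """
    from .mesh import MM
    from .fem import shape_gradients
    vol, grads = shape_gradients(np.asarray(coords_mm, float) * MM, cells)
    gv = np.einsum("eck,ecd->ekd", grads, v[cells])
    sig = mu * (gv + gv.transpose(0, 2, 1))
    n_verts = len(coords_mm)
    acc = np.zeros((n_verts, 3, 3))
    wsum = np.zeros(n_verts)
    w = np.abs(vol)
    for k in range(4):
        np.add.at(acc, cells[:, k], sig * w[:, None, None])
        np.add.at(wsum, cells[:, k], w)
    acc[wsum > 0] /= wsum[wsum > 0, None, None]
    # sigma.n with n outward of the fluid is the traction on the fluid;
    # the WSS convention is the force the fluid exerts on the wall
    tn = -np.einsum("vij,vj->vi", acc[wall_verts], normals)
    return project_tangential(tn, normals)


@dataclass
class WallSeries:
    """Wall-shear vectors sampled on a surface over the metric window.

    ``times`` (K,) s, ``tau`` (K, N, 3) Pa, plus vertex positions (mm),
    outward unit normals and lumped vertex areas (mm^2) of the surface.
    """

    times: np.ndarray
    tau: np.ndarray
    vertices: np.ndarray
    normals: np.ndarray
    areas: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.tau = np.asarray(self.tau, dtype=float)
        if self.tau.shape[0] != len(self.times):
            raise MetricError("tau must have one sample per time")

    @property
    def window(self) -> float:
        return float(self.times[-1] - self.times[0])

    def check_tangency(self, rtol: float = 1e-6) -> float:
        mag = np.linalg.norm(self.tau, axis=-1)
        dot = np.abs(np.einsum("kni,ni->kn", self.tau, self.normals))
        rel = dot / np.maximum(mag, 1e-300)
        return float(rel[mag > 1e-12 * mag.max()].max(initial=0.0))


def tawss(series: WallSeries) -> np.ndarray:
    """(1/T) int ||tau|| dt per vertex (trapezoid in time)."""
    mag = np.linalg.norm(series.tau, axis=-1)
    return np.trapezoid(mag, series.times, axis=0) / series.window


def osi(series: WallSeries) -> np.ndarray:
    """Oscillatory shear index per vertex, in [0, 1/2]; 0 where shear is zero."""
    if len(series.times) < 2:
        raise MetricError("OSI needs at least two samples over the window")
    vec = np.trapezoid(series.tau, series.times, axis=0)
    mag = np.trapezoid(np.linalg.norm(series.tau, axis=-1), series.times, axis=0)
    out = np.zeros(series.tau.shape[1])
    nz = mag > 0
    out[nz] = 0.5 * (1.0 - np.linalg.norm(vec[nz], axis=-1) / mag[nz])
    return np.clip(out, 0.0, 0.5)


def bulge_avg_wss(series: WallSeries, y_cut: float = 8.0) -> np.ndarray:
    """Area-weighted spatial mean of ||tau|| over the bulge surface, per time."""
    sel = series.vertices[:, 1] > y_cut
    if not np.any(sel):
        raise MetricError(f"no wall vertices above y = {y_cut} mm")
    w = series.areas[sel]
    mag = np.linalg.norm(series.tau[:, sel, :], axis=-1)
    return (mag * w).sum(axis=1) / w.sum()


def field_difference(metrics_a: np.ndarray, metrics_b: np.ndarray) -> np.ndarray:
    """Vertex-wise difference map (a - b) on a shared surface."""
    a = np.asarray(metrics_a)
    b = np.asarray(metrics_b)
    if a.shape != b.shape:
        raise MetricError("difference maps need identical reference surfaces")
    return a - b


# ---------------------------------------------------------------------------
# plane slicing: swirl rate
# ---------------------------------------------------------------------------

_TET_EDGES = [(0, 1), (0, 2), (0, 3), (1, 2), (1, 3), (2, 3)]


def _plane_polygons(coords, cells, values, y0):
    """Cross-section polygons of tets cut by the plane y = y0.

    Yields (points (k, 3), vals (k,)) with points ordered around the polygon.
    """
    d = coords[:, 1] - y0
    dc = d[cells]
    cut = (dc.min(axis=1) < 0) & (dc.max(axis=1) > 0)
    for tet in cells[cut]:
        pts, vals = [], []
        for i, j in _TET_EDGES:
            di, dj = d[tet[i]], d[tet[j]]
            if di * dj < 0:
                w = di / (di - dj)
                pts.append((1 - w) * coords[tet[i]] + w * coords[tet[j]])
                vals.append((1 - w) * values[tet[i]] + w * values[tet[j]])
        for vtx in tet:  # vertices exactly on the plane
            if d[vtx] == 0.0:
                pts.append(coords[vtx])
                vals.append(values[vtx])
        if len(pts) < 3:
            continue
        pts = np.asarray(pts)
        vals = np.asarray(vals)
        c = pts.mean(axis=0)
        ang = np.arctan2(pts[:, 2] - c[2], pts[:, 0] - c[0])
        order = np.argsort(ang)
        yield pts[order], vals[order]


def _clip_positive(poly_pts, poly_vals):
    """Clip a planar polygon with linear vertex values to the region v >= 0."""
    out_p, out_v = [], []
    k = len(poly_pts)
    for i in range(k):
        p1, v1 = poly_pts[i], poly_vals[i]
        p2, v2 = poly_pts[(i + 1) % k], poly_vals[(i + 1) % k]
        if v1 >= 0:
            out_p.append(p1)
            out_v.append(v1)
        if (v1 < 0) != (v2 < 0):
            w = v1 / (v1 - v2)
            out_p.append((1 - w) * p1 + w * p2)
            out_v.append(0.0)
    return np.asarray(out_p), np.asarray(out_v)


def _integrate_linear(poly_pts, poly_vals):
    """Exact integral of a linear field over a planar polygon (fan rule)."""
    total = 0.0
    for i in range(1, len(poly_pts) - 1):
        p = poly_pts[[0, i, i + 1]]
        v = poly_vals[[0, i, i + 1]]
        area = 0.5 * np.linalg.norm(np.cross(p[1] - p[0], p[2] - p[0]))
        total += area * v.mean()
    return total


def swirl_rate(coords_mm: np.ndarray, cells: np.ndarray, v_m_s: np.ndarray,
               plane_height: float = 10.0, positive_part: bool = True) -> float:
    """Upward-going flow rate (mL/s) through the plane y = plane_height.

    Integrates max(v_y, 0) over the plane's intersection with the lumen —
    the positive part measures the swirl intensity inside a recirculation,
    whose net flux through the plane would nearly cancel.  Set
    ``positive_part=False`` for the net flux.
    """
    total = 0.0
    seen = False
    for pts, vals in _plane_polygons(coords_mm, cells, v_m_s[:, 1], plane_height):
        seen = True
        if positive_part:
            pts, vals = _clip_positive(pts, vals)
            if len(pts) < 3:
                continue
        total += _integrate_linear(pts, vals)
    if not seen:
        raise MetricError(f"plane y = {plane_height} mm does not intersect the lumen")
    return float(total)  # mm^2 * m/s == mL/s


# ---------------------------------------------------------------------------
# bulge volume
# ---------------------------------------------------------------------------

def oriented_surface(mesh: TaggedMesh, tag: str = "interface") -> np.ndarray:
    """Surface triangles of a tag, consistently oriented outward."""
    from .mesh import FACE_TAGS
    idx = np.flatnonzero(mesh.face_tags == FACE_TAGS[tag])
    tris = mesh.faces[idx].copy()
    _, n_out = mesh.face_areas_normals()
    v = mesh.vertices
    cr = np.cross(v[tris[:, 1]] - v[tris[:, 0]], v[tris[:, 2]] - v[tris[:, 0]])
    flip = np.einsum("ij,ij->i", cr, n_out[idx]) < 0
    tris[flip] = tris[flip][:, [0, 2, 1]]
    return tris


def volume_above_plane(surf_coords: np.ndarray, tris: np.ndarray, y_cut: float) -> float:
    """Volume (mm^3) enclosed above y = y_cut by a closed outward surface.

    Divergence-theorem evaluation of int (y - y_cut) n_y dA over the surface
    clipped to y > y_cut; the cap on the cut plane contributes nothing.
    """
    edges = np.sort(np.concatenate([tris[:, [0, 1]], tris[:, [1, 2]], tris[:, [2, 0]]]), axis=1)
    uniq, counts = np.unique(edges, axis=0, return_counts=True)
    # odd-count edges are genuinely open; even non-manifold contacts still
    # close the flux integral.  Open rims below the cut plane are fine.
    open_edges = uniq[counts % 2 == 1]
    if len(open_edges) and surf_coords[open_edges.ravel(), 1].max() > y_cut:
        raise MetricError("surface is open above the cut plane: "
                          "cannot integrate a volume")
    total = 0.0
    for tri in tris:
        p = surf_coords[tri]
        d = p[:, 1] - y_cut
        if np.all(d <= 0):
            continue
        if np.all(d >= 0):
            poly = p
        else:
            poly, _ = _clip_positive(p, d)
            if len(poly) < 3:
                continue
        for i in range(1, len(poly) - 1):
            q = poly[[0, i, i + 1]]
            va = 0.5 * np.cross(q[1] - q[0], q[2] - q[0])
            total += (q[:, 1].mean() - y_cut) * va[1]
    return float(total)


def aneurysm_volume_variation(surf_coords: np.ndarray, ref_coords: np.ndarray,
                              tris: np.ndarray, y_cut: float = 8.0) -> tuple[float, float]:
    """(% variation, mm^3 change) of the bulge volume vs the reference state."""
    v = volume_above_plane(surf_coords, tris, y_cut)
    v0 = volume_above_plane(ref_coords, tris, y_cut)
    if v0 <= 0:
        raise MetricError("reference state encloses no volume above the cut plane")
    return 100.0 * (v - v0) / v0, v - v0


# ---------------------------------------------------------------------------
# time-series diagnostics
# ---------------------------------------------------------------------------

def _refined_argmax(t: np.ndarray, y: np.ndarray) -> float:
    i = int(np.argmax(y))
    if 0 < i < len(y) - 1:
        y0, y1, y2 = y[i - 1], y[i], y[i + 1]
        denom = y0 - 2 * y1 + y2
        if denom != 0:
            return float(t[i] + 0.5 * (y0 - y2) / denom * (t[i + 1] - t[i]))
    return float(t[i])


def peak_delay(times_a: np.ndarray, series_a: np.ndarray,
               times_b: np.ndarray, series_b: np.ndarray) -> float:
    """t(argmax a) - t(argmax b) in milliseconds, parabolic peak refinement."""
    a = np.asarray(series_a, dtype=float)
    b = np.asarray(series_b, dtype=float)
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise MetricError("peak delay of a flat series is undefined")
    return 1000.0 * (_refined_argmax(np.asarray(times_a), a)
                     - _refined_argmax(np.asarray(times_b), b))


def sample_line(coords_mm: np.ndarray, cells: np.ndarray, values: np.ndarray,
                p0: np.ndarray, p1: np.ndarray, n: int = 100) -> tuple[np.ndarray, np.ndarray]:
    """Sample a vertex field along the segment p0 -> p1 (barycentric interp).

    Returns (arc length mm, values); points outside the mesh give NaN.
    """
    from scipy.spatial import cKDTree
    p0 = np.asarray(p0, dtype=float)
    p1 = np.asarray(p1, dtype=float)
    s = np.linspace(0.0, 1.0, n)
    pts = p0 + s[:, None] * (p1 - p0)
    cent = coords_mm[cells].mean(axis=1)
    tree = cKDTree(cent)
    _, near = tree.query(pts, k=min(24, len(cells)))
    out = np.full(n, np.nan)
    for i, p in enumerate(pts):
        for ci in np.atleast_1d(near[i]):
            tet = cells[ci]
            T = np.column_stack([coords_mm[tet[1]] - coords_mm[tet[0]],
                                 coords_mm[tet[2]] - coords_mm[tet[0]],
                                 coords_mm[tet[3]] - coords_mm[tet[0]]])
            try:
                lam = np.linalg.solve(T, p - coords_mm[tet[0]])
            except np.linalg.LinAlgError:
                continue
            bary = np.array([1 - lam.sum(), *lam])
            if np.all(bary > -1e-9):
                out[i] = bary @ values[tet]
                break
    return np.linalg.norm(pts - p0, axis=1), out
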