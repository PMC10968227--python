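"""Parametric geometry and meshing of the idealized sidewall-aneurysm benchmark.

The reference case ("case R") is a curved parent vessel — a half-torus tube
with inlet and outlet discs on the plane y = 0 — carrying a spherical
aneurysm bulge centred above the vessel apex on the symmetry plane z = 0.
The lumen is described implicitly by a signed distance field: torus tube and
sphere blended by a smooth union whose blend width plays the role of the
smoothed neck fillet.  The arterial wall is a constant-thickness shell grown
from the lumen surface along its outward normals.

Fluid meshes are built by sampling the implicit surface (with graded
boundary-layer shells) and interior lattice points, tetrahedralizing with
Delaunay and keeping the inside cells.  Solid meshes are structured
extrusions of the fluid interface triangulation, so the two interface
triangulations are vertex-identical by construction.

Lengths are millimetres throughout this module.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import Delaunay, QhullError

from .mesh import FACE_TAGS, REGION_TAGS, TaggedMesh, extract_boundary


class GeometryError(ValueError):
    """Invalid or degenerate geometric configuration."""


class MeshingError(RuntimeError):
    """Mesh generation failed; the message carries the diagnostic."""


# ---------------------------------------------------------------------------
# parameters
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CaseGeometryParams:
    """Dimensions of case R, in millimetres.

    The torus major radius and the bulge sphere radius are figure-derived
    defaults (the benchmark publishes them only graphically); they are
    consistent with a 4 mm parent vessel whose apex axis sits 3 mm below the
    bulge centre at y = 10 mm.
    """

    inlet_diameter: float = 4.0
    wall_thickness: float = 0.25
    torus_major_radius: float = 7.0
    bulge_radius: float = 3.0
    bulge_center_height: float = 10.0
    neck_fillet_radius: float = 0.5
    bulge_cut_height: float = 8.0

    @property
    def tube_radius(self) -> float:
        return 0.5 * self.inlet_diameter

    def validate(self) -> None:
        for name in ("inlet_diameter", "wall_thickness", "torus_major_radius",
                     "bulge_radius", "bulge_center_height", "neck_fillet_radius",
                     "bulge_cut_height"):
            if getattr(self, name) <= 0:
                raise GeometryError(f"{name} must be positive (got {getattr(self, name)})")
        if self.bulge_cut_height >= self.bulge_center_height:
            raise GeometryError("bulge_cut_height must lie below the bulge centre")
        if self.tube_radius >= self.torus_major_radius:
            raise GeometryError("vessel radius must be smaller than the torus major radius")


@dataclass(frozen=True)
class MeshParams:
    """Mesh sizing, in millimetres.

    ``bl_*`` control the fluid near-wall boundary layer (geometric growth from
    ``bl_first_layer`` by ``bl_growth``, stopping at the first layer whose
    cumulative thickness reaches ``bl_total``); ``core_size`` the isotropic
    interior size, ``solid_layers`` the through-thickness layering of the
    wall shell.
    """

    bl_growth: float = 1.2
    bl_first_layer: float = 0.02
    bl_total: float = 0.3
    core_size: float = 0.17
    solid_layers: int = 6
    solid_layer_thickness: float = 0.042

    def validate(self) -> None:
        if self.bl_growth <= 1:
            raise GeometryError("bl_growth must exceed 1")
        if not (0 < self.bl_first_layer < self.bl_total):
            raise GeometryError("bl_first_layer must be positive and below bl_total")
        if self.core_size <= 0 or self.solid_layers < 1 or self.solid_layer_thickness <= 0:
            raise GeometryError("core_size, solid_layers and solid_layer_thickness must be positive")

    def bl_offsets(self) -> np.ndarray:
        """Cumulative boundary-layer interface depths (first included)."""
        offs = []
        t, c = self.bl_first_layer, 0.0
        while c < self.bl_total - 1e-12:
            c += t
            offs.append(c)
            t *= self.bl_growth
        return np.asarray(offs)


#: coarse "desk" profile used by tests and the scaled-down case-R runs
DESK_MESH = MeshParams(bl_growth=1.6, bl_first_layer=0.39, bl_total=0.4,
                       core_size=1.05, solid_layers=1, solid_layer_thickness=0.25)


# ---------------------------------------------------------------------------
# implicit model of case R
# ---------------------------------------------------------------------------

def _smooth_union(a: np.ndarray, b: np.ndarray, k: float) -> np.ndarray:
    """Polynomial smooth-min of two SDFs; blend width ``k`` rounds the neck."""
    if k <= 0:
        return np.minimum(a, b)
    h = np.clip(0.5 + 0.5 * (b - a) / k, 0.0, 1.0)
    return b * (1.0 - h) + a * h - k * h * (1.0 - h)


@dataclass(frozen=True)
class CaseRModel:
    """Analytic solid model: blended torus-tube + sphere lumen and its shell."""

    params: CaseGeometryParams

    @property
    def bulge_center(self) -> np.ndarray:
        return np.array([0.0, self.params.bulge_center_height, 0.0])

    @property
    def inlet_center(self) -> np.ndarray:
        return np.array([self.params.torus_major_radius, 0.0, 0.0])

    @property
    def outlet_center(self) -> np.ndarray:
        return np.array([-self.params.torus_major_radius, 0.0, 0.0])

    def sdf(self, pts: np.ndarray) -> np.ndarray:
        """Signed distance-like field of the lumen (negative inside)."""
        p = self.params
        pts = np.atleast_2d(pts)
        rad = np.hypot(pts[:, 0], pts[:, 1])
        d_tube = np.hypot(rad - p.torus_major_radius, pts[:, 2]) - p.tube_radius
        d_sph = np.linalg.norm(pts - self.bulge_center, axis=1) - p.bulge_radius
        return _smooth_union(d_tube, d_sph, p.neck_fillet_radius)

    def grad(self, pts: np.ndarray, eps: float = 1e-5) -> np.ndarray:
        pts = np.atleast_2d(pts)
        g = np.empty_like(pts)
        for k in range(3):
            dp = np.zeros(3)
            dp[k] = eps
            g[:, k] = (self.sdf(pts + dp) - self.sdf(pts - dp)) / (2 * eps)
        return g

    def normals(self, pts: np.ndarray) -> np.ndarray:
        g = self.grad(pts)
        return g / np.linalg.norm(g, axis=1, keepdims=True)

    def project_to_surface(self, pts: np.ndarray, iters: int = 6) -> np.ndarray:
        x = np.array(np.atleast_2d(pts), dtype=float)
        for _ in range(iters):
            phi = self.sdf(x)
            g = self.grad(x)
            x = x - phi[:, None] * g / np.maximum(np.einsum("ij,ij->i", g, g), 1e-12)[:, None]
        return x


def build_case_r(params: CaseGeometryParams | None = None) -> CaseRModel:
    """Construct the analytic case-R model, validating the neck topology."""
    params = params or CaseGeometryParams()
    params.validate()
    d_axis = abs(params.bulge_center_height - params.torus_major_radius)
    if d_axis >= params.tube_radius + params.bulge_radius:
        raise GeometryError("bulge sphere does not intersect the vessel: no neck")
    if d_axis + params.bulge_radius <= params.tube_radius:
        raise GeometryError("bulge sphere is swallowed by the vessel lumen")
    if params.neck_fillet_radius >= min(params.bulge_radius, params.tube_radius):
        raise GeometryError("neck fillet radius too large to resolve the neck")
    return CaseRModel(params)


# ---------------------------------------------------------------------------
# point sampling helpers
# ---------------------------------------------------------------------------

def _dedupe(points: np.ndarray, dmin, return_index: bool = False):
    """Greedy thinning: keep points no closer than ``dmin`` (order-stable).

    ``dmin`` may be a scalar or a per-point array (graded spacing); two
    points conflict when closer than the mean of their radii.
    """
    if len(points) == 0:
        return (points, np.empty(0, dtype=np.int64)) if return_index else points
    radii = np.broadcast_to(np.asarray(dmin, dtype=float), (len(points),))
    cell = float(radii.max())
    grid: dict[tuple[int, int, int], list[int]] = {}
    keep: list[int] = []
    keys = np.floor(points / cell).astype(np.int64)
    for i, (p, key) in enumerate(zip(points, map(tuple, keys))):
        ok = True
        for dx in (-1, 0, 1):
            for dy in (-1, 0, 1):
                for dz in (-1, 0, 1):
                    for j in grid.get((key[0] + dx, key[1] + dy, key[2] + dz), ()):
                        d = points[j] - p
                        lim = 0.5 * (radii[i] + radii[j])
                        if d @ d < lim * lim:
                            ok = False
                            break
                    if not ok:
                        break
                if not ok:
                    break
            if not ok:
                break
        if ok:
            grid.setdefault(key, []).append(i)
            keep.append(i)
    keep_a = np.asarray(keep, dtype=np.int64)
    return (points[keep_a], keep_a) if return_index else points[keep_a]


def _fibonacci_sphere(n: int) -> np.ndarray:
    i = np.arange(n) + 0.5
    phi = np.arccos(1 - 2 * i / n)
    theta = np.pi * (1 + 5 ** 0.5) * i
    return np.stack([np.cos(theta) * np.sin(phi), np.sin(theta) * np.sin(phi), np.cos(phi)], axis=1)


def _disc_points(h: float, radius: float) -> np.ndarray:
    """Polar point layout on a unit-normal disc (local 2D coords), rim included."""
    n_r = max(2, int(round(radius / h)))
    pts = [np.zeros((1, 2))]
    for j in range(1, n_r + 1):
        r = radius * j / n_r
        n_c = max(6, int(round(2 * np.pi * r / h)))
        a = 2 * np.pi * np.arange(n_c) / n_c + (0.5 * np.pi * j / n_r)
        pts.append(np.stack([r * np.cos(a), r * np.sin(a)], axis=1))
    return np.concatenate(pts)


# ---------------------------------------------------------------------------
# prism splitting (conforming, min-vertex rule)
# ---------------------------------------------------------------------------

_PRISM_ROT = np.array([
    [0, 1, 2, 3, 4, 5],
    [1, 2, 0, 4, 5, 3],
    [2, 0, 1, 5, 3, 4],
    [3, 5, 4, 0, 2, 1],
    [4, 3, 5, 1, 0, 2],
    [5, 4, 3, 2, 1, 0],
])


def split_prisms(prisms: np.ndarray) -> np.ndarray:
    """Split triangular prisms (bottom v0 v1 v2, top v3 v4 v5) into 3 tets each.

    Quad-face diagonals pass through each quad's smallest global vertex index,
    which makes the decomposition conforming across prisms sharing a quad.
    """
    prisms = np.asarray(prisms, dtype=np.int64)
    pos = np.argmin(prisms, axis=1)
    w = np.take_along_axis(prisms, _PRISM_ROT[pos], axis=1)
    # remaining free quad (w1, w2, w5, w4): diagonal through its min vertex
    diag15 = np.minimum(w[:, 1], w[:, 5]) < np.minimum(w[:, 2], w[:, 4])
    tets = np.empty((len(prisms), 3, 4), dtype=np.int64)
    a = diag15
    tets[a, 0] = w[a][:, [0, 1, 2, 5]]
    tets[a, 1] = w[a][:, [0, 1, 5, 4]]
    tets[a, 2] = w[a][:, [0, 4, 5, 3]]
    b = ~diag15
    tets[b, 0] = w[b][:, [0, 1, 2, 4]]
    tets[b, 1] = w[b][:, [0, 4, 2, 5]]
    tets[b, 2] = w[b][:, [0, 4, 5, 3]]
    return tets.reshape(-1, 4)


# ---------------------------------------------------------------------------
# structured fixtures
# ---------------------------------------------------------------------------

def make_tube_fixture(radius: float, length: float, resolution: float,
                      bl: MeshParams | None = None) -> TaggedMesh:
    """Straight circular tube along +y: inlet y=0, outlet y=length, tagged wall.

    ``resolution`` is the target element size (mm).  With ``bl`` given, the
    cross-section is radially graded near the wall following the boundary
    layer parameters.
    """
    if resolution <= 0:
        raise GeometryError("resolution must be positive")
    if radius <= 0 or length <= 0:
        raise GeometryError("tube dimensions must be positive")
    h = float(resolution)
    if bl is not None:
        offs = bl.bl_offsets()
        if offs[-1] >= radius:
            raise GeometryError("boundary layer exceeds the tube radius")
        wall_radii = radius - offs[::-1]
        inner = wall_radii[0]
        n_in = max(1, int(round(inner / h)))
        radii = np.concatenate([inner * np.arange(1, n_in + 1) / n_in, wall_radii[1:], [radius]])
        radii = np.unique(np.round(radii, 12))
    else:
        n_r = max(2, int(round(radius / h)))
        radii = radius * np.arange(1, n_r + 1) / n_r
    pts2 = [np.zeros((1, 2))]
    for j, r in enumerate(radii):
        n_c = max(6, int(round(2 * np.pi * r / h)))
        a = 2 * np.pi * np.arange(n_c) / n_c + 0.25 * j
        pts2.append(np.stack([r * np.cos(a), r * np.sin(a)], axis=1))
    disc = np.concatenate(pts2)
    try:
        tri2 = Delaunay(disc).simplices
    except QhullError as exc:  # pragma: no cover
        raise MeshingError(f"disc triangulation failed: {exc}") from exc
    # drop degenerate rim slivers (can appear between equal-radius rim points)
    p0, p1, p2 = disc[tri2[:, 0]], disc[tri2[:, 1]], disc[tri2[:, 2]]
    e1, e2 = p1 - p0, p2 - p0
    area2 = np.abs(e1[:, 0] * e2[:, 1] - e1[:, 1] * e2[:, 0])
    tri2 = tri2[area2 > 1e-10 * h * h]

    n_ax = max(1, int(round(length / h)))
    nd = len(disc)
    y = np.linspace(0.0, length, n_ax + 1)
    verts = np.concatenate([
        np.stack([np.repeat(disc[:, 0], 1), np.full(nd, yy), disc[:, 1]], axis=1)
        for yy in y
    ])
    prisms = []
    for k in range(n_ax):
        bot = tri2 + k * nd
        top = tri2 + (k + 1) * nd
        prisms.append(np.concatenate([bot, top], axis=1))
    cells = split_prisms(np.concatenate(prisms))
    faces = extract_boundary(cells)
    fy = verts[faces].mean(axis=1)[:, 1]
    tol = 1e-9 * max(radius, length)
    tags = np.full(len(faces), FACE_TAGS["interface"], dtype=np.int64)
    tags[fy < tol] = FACE_TAGS["inlet"]
    tags[fy > length - tol] = FACE_TAGS["outlet"]
    return TaggedMesh(verts, cells, faces, tags)


def make_box_fixture(lengths: tuple[float, float, float],
                     divisions: tuple[int, int, int],
                     side_tags: dict[str, str] | None = None) -> TaggedMesh:
    """Structured box mesh (6 Kuhn tets per cube), sides tagged by name.

    ``side_tags`` maps "x-", "x+", "y-", "y+", "z-", "z+" to tag names from
    :data:`aneufsi.mesh.FACE_TAGS`; unnamed sides default to "exterior".
    """
    lx, ly, lz = lengths
    nx, ny, nz = divisions
    if min(divisions) < 1 or min(lengths) <= 0:
        raise GeometryError("box dimensions and divisions must be positive")
    side_tags = side_tags or {}
    xs = np.linspace(0, lx, nx + 1)
    ys = np.linspace(0, ly, ny + 1)
    zs = np.linspace(0, lz, nz + 1)
    X, Y, Z = np.meshgrid(xs, ys, zs, indexing="ij")
    verts = np.stack([X.ravel(), Y.ravel(), Z.ravel()], axis=1)

    def vid(i, j, k):
        return (i * (ny + 1) + j) * (nz + 1) + k

    I, J, K = np.meshgrid(np.arange(nx), np.arange(ny), np.arange(nz), indexing="ij")
    c000 = vid(I, J, K).ravel()
    c100 = vid(I + 1, J, K).ravel()
    c010 = vid(I, J + 1, K).ravel()
    c110 = vid(I + 1, J + 1, K).ravel()
    c001 = vid(I, J, K + 1).ravel()
    c101 = vid(I + 1, J, K + 1).ravel()
    c011 = vid(I, J + 1, K + 1).ravel()
    c111 = vid(I + 1, J + 1, K + 1).ravel()
    # Kuhn split: six tets around the main diagonal c000-c111 (conforming)
    tets = np.concatenate([
        np.stack([c000, c100, c110, c111], axis=1),
        np.stack([c000, c110, c010, c111], axis=1),
        np.stack([c000, c010, c011, c111], axis=1),
        np.stack([c000, c011, c001, c111], axis=1),
        np.stack([c000, c001, c101, c111], axis=1),
        np.stack([c000, c101, c100, c111], axis=1),
    ])
    faces = extract_boundary(tets)
    fc = verts[faces].mean(axis=1)
    tol = 1e-9 * max(lengths)
    tags = np.full(len(faces), FACE_TAGS["exterior"], dtype=np.int64)
    side_of = {
        "x-": fc[:, 0] < tol, "x+": fc[:, 0] > lx - tol,
        "y-": fc[:, 1] < tol, "y+": fc[:, 1] > ly - tol,
        "z-": fc[:, 2] < tol, "z+": fc[:, 2] > lz - tol,
    }
    for side, name in side_tags.items():
        tags[side_of[side]] = FACE_TAGS[name]
    return TaggedMesh(verts, tets, faces, tags)


def _icosphere(subdiv: int) -> tuple[np.ndarray, np.ndarray]:
    t = (1 + 5 ** 0.5) / 2
    v = np.array([[-1, t, 0], [1, t, 0], [-1, -t, 0], [1, -t, 0],
                  [0, -1, t], [0, 1, t], [0, -1, -t], [0, 1, -t],
                  [t, 0, -1], [t, 0, 1], [-t, 0, -1], [-t, 0, 1]], dtype=float)
    v /= np.linalg.norm(v, axis=1, keepdims=True)
    f = np.array([[0, 11, 5], [0, 5, 1], [0, 1, 7], [0, 7, 10], [0, 10, 11],
                  [1, 5, 9], [5, 11, 4], [11, 10, 2], [10, 7, 6], [7, 1, 8],
                  [3, 9, 4], [3, 4, 2], [3, 2, 6], [3, 6, 8], [3, 8, 9],
                  [4, 9, 5], [2, 4, 11], [6, 2, 10], [8, 6, 7], [9, 8, 1]])
    for _ in range(subdiv):
        verts = list(map(tuple, v))
        index = {p: i for i, p in enumerate(verts)}
        cache: dict[tuple[int, int], int] = {}
        newf = []

        def mid(a, b):
            key = (min(a, b), max(a, b))
            if key not in cache:
                p = v[a] + v[b]
                p /= np.linalg.norm(p)
                index[tuple(p)] = len(verts)
                verts.append(tuple(p))
                cache[key] = len(verts) - 1
            return cache[key]

        for a, b, c in f:
            ab, bc, ca = mid(a, b), mid(b, c), mid(c, a)
            newf += [[a, ab, ca], [b, bc, ab], [c, ca, bc], [ab, bc, ca]]
        v = np.asarray(verts, dtype=float)
        f = np.asarray(newf)
    return v, f


def extrude_shell(surf_verts: np.ndarray, surf_tris: np.ndarray, normals: np.ndarray,
                  thickness, layers: int) -> TaggedMesh:
    """Extrude a triangulated surface along vertex normals into a layered shell.

    Layer-0 vertices coincide exactly with ``surf_verts`` (the interface);
    boundary faces are tagged interface (inner), exterior (outer) and
    fixed-plane (open rims, if the surface has boundary edges).  ``thickness``
    may be a scalar or a per-vertex array (a concave crease can require a
    locally thinner shell to avoid folding the offset surface).
    """
    ns = len(surf_verts)
    thickness = np.broadcast_to(np.asarray(thickness, dtype=float), (ns,))
    fracs = np.arange(layers + 1) / layers
    verts = np.concatenate([surf_verts + (f * thickness)[:, None] * normals
                            for f in fracs])
    prisms = []
    for k in range(layers):
        bot = surf_tris + k * ns
        top = surf_tris + (k + 1) * ns
        prisms.append(np.concatenate([bot, top], axis=1))
    cells = split_prisms(np.concatenate(prisms))
    faces = extract_boundary(cells)
    layer_of = faces // ns
    tags = np.full(len(faces), FACE_TAGS["fixed-plane"], dtype=np.int64)
    tags[(layer_of == 0).all(axis=1)] = FACE_TAGS["interface"]
    tags[(layer_of == layers).all(axis=1)] = FACE_TAGS["exterior"]
    return TaggedMesh(verts, cells, faces, tags)


def make_sphere_shell_fixture(radius: float, thickness: float, layers: int = 2,
                              subdiv: int = 2) -> TaggedMesh:
    """Closed spherical shell (inner radius ``radius``), for inflation tests."""
    if radius <= 0 or thickness <= 0 or layers < 1:
        raise GeometryError("sphere shell dimensions must be positive")
    v, f = _icosphere(subdiv)
    return extrude_shell(v * radius, f, v.copy(), thickness, layers)


def make_tube_shell(fluid_tube: TaggedMesh, thickness: float, layers: int) -> TaggedMesh:
    """Elastic wall shell of a straight tube, conforming to its wall faces."""
    tris = fluid_tube.faces_where("interface")
    used = np.unique(tris)
    remap = -np.ones(fluid_tube.num_vertices, dtype=np.int64)
    remap[used] = np.arange(len(used))
    sv = fluid_tube.vertices[used]
    normals = sv.copy()
    normals[:, 1] = 0.0
    normals /= np.linalg.norm(normals, axis=1, keepdims=True)
    return extrude_shell(sv, remap[tris], normals, thickness, layers)


# ---------------------------------------------------------------------------
# case-R fluid and solid meshing
# ---------------------------------------------------------------------------

def _tangential_jitter(pts: np.ndarray, normals: np.ndarray, amp,
                       rng: np.random.Generator) -> np.ndarray:
    """Perturb points within their tangent planes (breaks cospherical ties).

    ``amp`` may be scalar or per-point.
    """
    r = rng.normal(size=pts.shape)
    r -= np.einsum("ij,ij->i", r, normals)[:, None] * normals
    n = np.linalg.norm(r, axis=1, keepdims=True)
    amp = np.broadcast_to(np.asarray(amp, dtype=float), (len(pts),))
    return pts + amp[:, None] * r / np.maximum(n, 1e-12)


def _neck_spacing(model: CaseRModel, pts: np.ndarray, h: float) -> np.ndarray:
    """Graded target spacing: refined inside the neck-fillet blend band.

    The 0.5 mm fillet is sub-grid at coarse sizing; without local refinement
    the discrete crease is sharp and its extruded wall shell buckles.  Points
    where the tube and sphere distance fields are both small get spacing
    down to 0.42 h, blending back to h outside the band.
    """
    p = model.params
    rad = np.hypot(pts[:, 0], pts[:, 1])
    d_tube = np.hypot(rad - p.torus_major_radius, pts[:, 2]) - p.tube_radius
    d_sph = np.linalg.norm(pts - model.bulge_center, axis=1) - p.bulge_radius
    m = np.maximum(np.abs(d_tube), np.abs(d_sph))
    w = np.clip(m / (2.5 * p.neck_fillet_radius), 0.0, 1.0)
    # resolve the fillet arc itself (~pi/2 * r_f long) with >= 3 elements, so
    # the outward wall offset is geometrically valid there
    h_neck = min(0.5 * p.neck_fillet_radius, 0.45 * h)
    return h_neck + (h - h_neck) * w


def _case_r_surface_points(model: CaseRModel, h: float, seed: int) -> np.ndarray:
    p = model.params
    R, rt, rb = p.torus_major_radius, p.tube_radius, p.bulge_radius
    h_f = min(0.5 * p.neck_fillet_radius, 0.45 * h)   # finest target spacing
    pts = []
    # tube surface rings along the half-torus arc
    n_arc = max(8, int(round(np.pi * R / h_f)))
    thetas = np.pi * (np.arange(n_arc) + 0.5) / n_arc
    for th in thetas:
        axis = np.array([R * np.cos(th), R * np.sin(th), 0.0])
        rhat = np.array([np.cos(th), np.sin(th), 0.0])
        zhat = np.array([0.0, 0.0, 1.0])
        n_c = max(8, int(round(2 * np.pi * rt / h_f)))
        a = 2 * np.pi * np.arange(n_c) / n_c + 0.5 * th
        ring = axis + rt * (np.cos(a)[:, None] * rhat + np.sin(a)[:, None] * zhat)
        pts.append(ring)
    # bulge sphere
    n_s = max(32, int(round(4 * np.pi * rb * rb / (0.55 * h_f * h_f))))
    pts.append(model.bulge_center + rb * _fibonacci_sphere(n_s))
    pts = np.concatenate(pts)
    pts = pts[model.sdf(pts) < 0.45 * h]  # drop points buried inside the other body
    pts = model.project_to_surface(pts)
    rng = np.random.default_rng(seed + 1)
    h_loc = _neck_spacing(model, pts, h)
    pts = _tangential_jitter(pts, model.normals(pts), 0.12 * h_loc, rng)
    pts = model.project_to_surface(pts)
    pts = pts[pts[:, 1] > 0.45 * h_f]  # the rim circles at y=0 are seeded separately
    h_loc = _neck_spacing(model, pts, h)
    return _dedupe(pts, 0.55 * h_loc)


def _make_boundary_manifold(points: np.ndarray, cells: np.ndarray,
                            max_rounds: int = 25) -> np.ndarray:
    """Remove pinch cells until every boundary edge bounds exactly 2 faces.

    A Delaunay inside-test can keep cell sets whose boundary pinches along an
    edge (4+ incident boundary triangles, e.g. in the concave neck crease);
    such non-manifold seams would make the extruded wall shell self-overlap.
    Deleting the smallest incident cell opens the seam; iterate until clean.
    """
    for _ in range(max_rounds):
        faces = extract_boundary(cells)
        edges = np.sort(np.concatenate([faces[:, [0, 1]], faces[:, [1, 2]],
                                        faces[:, [2, 0]]]), axis=1)
        uniq, inv, counts = np.unique(edges, axis=0, return_inverse=True,
                                      return_counts=True)
        bad = counts > 2
        if not bad.any():
            return cells
        bad_face = np.unique(np.flatnonzero(bad[inv]) % len(faces))
        vols = np.abs(tet_signed_volumes(points, cells))
        drop = set()
        face_key = {tuple(sorted(f)): None for f in faces[bad_face]}
        # map each offending boundary face to its unique adjacent cell
        for ci, cell in enumerate(cells):
            for tri in (cell[[1, 2, 3]], cell[[0, 3, 2]], cell[[0, 1, 3]], cell[[0, 2, 1]]):
                key = tuple(sorted(tri))
                if key in face_key:
                    prev = face_key[key]
                    face_key[key] = ci if prev is None or vols[ci] < vols[prev] else prev
        for ci in face_key.values():
            if ci is not None:
                drop.add(ci)
        if not drop:
            return cells
        mask = np.ones(len(cells), dtype=bool)
        mask[list(drop)] = False
        cells = cells[mask]
    return cells


def tet_signed_volumes(points: np.ndarray, cells: np.ndarray) -> np.ndarray:
    e = points[cells[:, 1:]] - points[cells[:, :1]]
    return np.linalg.det(e) / 6.0


def mesh_fluid(model: CaseRModel, mesh_params: MeshParams | None = None,
               seed: int = 0) -> TaggedMesh:
    """Tetrahedral lumen mesh of case R with a graded near-wall layer."""
    mp = mesh_params or MeshParams()
    mp.validate()
    p = model.params
    if mp.bl_total >= p.tube_radius:
        raise GeometryError("boundary layer total exceeds the vessel radius")
    h = mp.core_size
    rng = np.random.default_rng(seed)

    surf = _case_r_surface_points(model, h, seed)
    normals = model.normals(surf)

    # boundary-layer shells (offset inward, skipping points past the medial axis);
    # mild depth jitter avoids degenerate cospherical stacks in the Delaunay step
    shells = []
    for c in mp.bl_offsets():
        cj = c * (1.0 + rng.uniform(-0.12, 0.12, len(surf)))
        q = surf - cj[:, None] * normals
        q = _tangential_jitter(q, normals, 0.1 * min(h, 3 * mp.bl_first_layer), rng)
        ok = (model.sdf(q) < -0.5 * c) & (q[:, 1] > 1e-6)
        shells.append(q[ok])

    # inlet / outlet discs (rim circle shared with the wall surface)
    discs = []
    for center, sgn in ((model.inlet_center, 1.0), (model.outlet_center, -1.0)):
        loc = _disc_points(h, p.tube_radius)
        d3 = np.stack([center[0] + sgn * loc[:, 0], np.zeros(len(loc)), loc[:, 1]], axis=1)
        discs.append(d3)
    discs = np.concatenate(discs)

    # interior lattice, jittered
    lo = np.array([-(p.torus_major_radius + p.tube_radius), 0.0,
                   -max(p.tube_radius, p.bulge_radius)]) - h
    hi = np.array([p.torus_major_radius + p.tube_radius,
                   p.bulge_center_height + p.bulge_radius, max(p.tube_radius, p.bulge_radius)]) + h
    grids = [np.arange(lo[k], hi[k], h) for k in range(3)]
    G = np.stack(np.meshgrid(*grids, indexing="ij"), axis=-1).reshape(-1, 3)
    G = G + rng.uniform(-0.2 * h, 0.2 * h, G.shape)
    margin = max(mp.bl_total + 0.35 * h, 0.6 * h)
    G = G[(model.sdf(G) < -margin) & (G[:, 1] > 0.6 * h)]

    points = np.concatenate([discs, surf, *shells, G])
    points = _dedupe(points, 0.3 * min(h, mp.bl_first_layer * 3))
    try:
        tri = Delaunay(points)
    except QhullError as exc:
        raise MeshingError(f"Delaunay tetrahedralization failed: {exc}") from exc
    cells = tri.simplices.astype(np.int64)
    cent = points[cells].mean(axis=1)
    keep = (model.sdf(cent) < 0.0) & (cent[:, 1] > 0.0)
    cells = cells[keep]
    if len(cells) == 0:
        raise MeshingError("no interior tetrahedra: sizing too coarse for the geometry")
    cells = _make_boundary_manifold(points, cells)

    # compress unused vertices
    used = np.unique(cells)
    remap = -np.ones(len(points), dtype=np.int64)
    remap[used] = np.arange(len(used))
    verts = points[used]
    cells = remap[cells]

    faces = extract_boundary(cells)
    fy = verts[faces]
    on_plane = np.all(np.abs(fy[:, :, 1]) < 1e-9, axis=1)
    fc = fy.mean(axis=1)
    tags = np.full(len(faces), FACE_TAGS["interface"], dtype=np.int64)
    tags[on_plane & (fc[:, 0] > 0)] = FACE_TAGS["inlet"]
    tags[on_plane & (fc[:, 0] < 0)] = FACE_TAGS["outlet"]
    mesh = TaggedMesh(verts, cells, faces, tags,
                      np.full(len(cells), REGION_TAGS["lumen"], dtype=np.int64))
    return mesh


def mesh_solid(model: CaseRModel, mesh_params: MeshParams | None = None,
               fluid_mesh: TaggedMesh | None = None, seed: int = 0) -> TaggedMesh:
    """Layered wall-shell mesh conforming to the fluid interface triangulation."""
    mp = mesh_params or MeshParams()
    mp.validate()
    t_total = mp.solid_layers * mp.solid_layer_thickness
    if abs(t_total - model.params.wall_thickness) > 0.01 * model.params.wall_thickness:
        raise GeometryError(
            f"solid_layers x solid_layer_thickness = {t_total:.4f} mm differs from the "
            f"wall thickness {model.params.wall_thickness} mm by more than 1%")
    if fluid_mesh is None:
        fluid_mesh = mesh_fluid(model, mp, seed=seed)
    tris = fluid_mesh.faces_where("interface")
    used = np.unique(tris)
    remap = -np.ones(fluid_mesh.num_vertices, dtype=np.int64)
    remap[used] = np.arange(len(used))
    sv = fluid_mesh.vertices[used]
    tris_l = remap[tris]
    normals = model.normals(sv)
    # smooth the extrusion directions across the surface graph: at the sharp
    # discrete neck crease the raw implicit-surface normals of neighbouring
    # vertices diverge and the offset prisms fold
    adj_i = np.concatenate([tris_l[:, [0, 0, 1, 1, 2, 2]].ravel()])
    adj_j = np.concatenate([tris_l[:, [1, 2, 0, 2, 0, 1]].ravel()])
    rim = np.abs(sv[:, 1]) < 1e-9
    for _ in range(3):
        acc = np.zeros_like(normals)
        np.add.at(acc, adj_i, normals[adj_j])
        acc += 2.0 * normals
        normals = acc / np.linalg.norm(acc, axis=1, keepdims=True)
    # rim vertices must extrude within the fixation plane y = 0
    normals[rim, 1] = 0.0
    normals[rim] /= np.linalg.norm(normals[rim], axis=1, keepdims=True)
    # the shell keeps its nominal thickness everywhere, including the concave
    # neck crease: there the offset surfaces of vessel and bulge overlap into
    # the wedge between them, which mimics the physically merged wall (a
    # locally thinned shell would be far too compliant and flap)
    solid = extrude_shell(sv, tris_l, normals, model.params.wall_thickness,
                          mp.solid_layers)
    return tag_regions(solid, model.params.bulge_cut_height)


def tag_regions(mesh: TaggedMesh, cut_height: float) -> TaggedMesh:
    """Label wall cells above the cut plane as bulge-wall, the rest artery-wall."""
    cent_y = mesh.vertices[mesh.cells].mean(axis=1)[:, 1]
    tags = np.where(cent_y > cut_height, REGION_TAGS["bulge-wall"], REGION_TAGS["artery-wall"])
    out = mesh.copy()
    out.region_tags = tags.astype(np.int64)
    return out
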