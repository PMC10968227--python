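"""Geometry, meshing and mesh-container contracts."""

import numpy as np
import pytest
from scipy.spatial import cKDTree

from aneufsi.geometry import (DESK_MESH, CaseGeometryParams, GeometryError,
                              MeshParams, build_case_r, make_box_fixture,
                              make_sphere_shell_fixture, make_tube_fixture,
                              mesh_fluid, mesh_solid, split_prisms, tag_regions)
from aneufsi.io import IOError_, read_mesh, write_mesh
from aneufsi.mesh import FACE_TAGS, REGION_TAGS, TaggedMesh


# ---------------------------------------------------------------------------
# analytic model
# ---------------------------------------------------------------------------

class TestCaseRModel:
    def test_default_parameters_build(self, case_model):
        assert case_model.params.inlet_diameter == 4.0
        assert case_model.params.wall_thickness == 0.25

    def test_degenerate_bulge_raises(self):
        with pytest.raises(GeometryError):
            build_case_r(CaseGeometryParams(bulge_radius=0.0))

    def test_detached_sphere_raises(self):
        with pytest.raises(GeometryError, match="neck"):
            build_case_r(CaseGeometryParams(bulge_center_height=30.0,
                                            bulge_cut_height=8.0))

    def test_oversized_fillet_raises(self):
        with pytest.raises(GeometryError, match="fillet"):
            build_case_r(CaseGeometryParams(neck_fillet_radius=2.5))

    def test_cut_plane_must_lie_below_centre(self):
        with pytest.raises(GeometryError):
            build_case_r(CaseGeometryParams(bulge_cut_height=11.0))

    def test_mirror_symmetry_across_vessel_plane(self, case_model, rng):
        """Reflecting across the vessel symmetry plane maps the model onto itself."""
        pts = rng.uniform(-10, 14, size=(200, 3))
        mirrored = pts * np.array([1.0, 1.0, -1.0])
        assert np.allclose(case_model.sdf(pts), case_model.sdf(mirrored), atol=1e-12)

    def test_sdf_sign_convention(self, case_model):
        inside = np.array([[7.0, 0.5, 0.0], [0.0, 10.0, 0.0]])   # vessel, bulge centre
        outside = np.array([[0.0, 0.0, 0.0], [0.0, 20.0, 0.0]])
        assert np.all(case_model.sdf(inside) < 0)
        assert np.all(case_model.sdf(outside) > 0)


# ---------------------------------------------------------------------------
# prism splitting / structured fixtures
# ---------------------------------------------------------------------------

def _tet_vol(V, t):
    return abs(np.linalg.det(V[list(t[1:])] - V[t[0]])) / 6.0


def test_split_prisms_preserves_volume_and_count(rng):
    """Any affine prism splits into 3 tets of the prism's exact volume."""
    for _ in range(50):
        base = rng.normal(size=(3, 3))
        base[:, 2] = 0.0
        off = rng.normal(size=3)
        off[2] = 1.0 + abs(off[2])
        V = np.concatenate([base, base + off])
        ids = rng.permutation(10_000)[:6]
        tets = split_prisms(ids[None, :].copy())
        assert tets.shape == (3, 4)
        inv = {g: i for i, g in enumerate(ids)}
        vol = sum(_tet_vol(V, [inv[g] for g in t]) for t in tets)
        ref = sum(_tet_vol(V, t) for t in [(0, 1, 2, 3), (1, 2, 3, 4), (2, 3, 4, 5)])
        assert vol == pytest.approx(ref, rel=1e-12)


def test_tube_fixture_geometry_oracles():
    """Cross-section area and total volume approach the analytic values."""
    m = make_tube_fixture(2.0, 20.0, 0.35)
    m.check_watertight()
    area, _ = m.face_areas_normals()
    inlet_area = area[m.face_tags == FACE_TAGS["inlet"]].sum()
    assert inlet_area == pytest.approx(np.pi * 4.0, rel=0.01)
    assert m.cell_volumes().sum() == pytest.approx(np.pi * 4.0 * 20.0, rel=0.01)


def test_tube_fixture_zero_resolution_raises():
    with pytest.raises(GeometryError):
        make_tube_fixture(2.0, 20.0, 0.0)


def test_box_fixture_volume_and_tags():
    b = make_box_fixture((1.0, 2.0, 3.0), (3, 4, 5),
                         side_tags={"x-": "fixed-plane", "x+": "interface"})
    b.check_watertight()
    assert b.cell_volumes().sum() == pytest.approx(6.0, rel=1e-12)
    area, _ = b.face_areas_normals()
    assert area[b.face_tags == FACE_TAGS["fixed-plane"]].sum() == pytest.approx(6.0)
    assert area[b.face_tags == FACE_TAGS["interface"]].sum() == pytest.approx(6.0)


def test_sphere_shell_volume(sphere_shell):
    sphere_shell.check_watertight()
    expected = 4.0 / 3.0 * np.pi * (10.25 ** 3 - 10.0 ** 3)
    # icosphere subdiv-2 polyhedron sits inside the sphere: a few % deficit
    assert sphere_shell.cell_volumes().sum() == pytest.approx(expected, rel=0.04)


# ---------------------------------------------------------------------------
# case-R meshing
# ---------------------------------------------------------------------------

@pytest.fixture(scope="module")
def fluid_mesh(case_model):
    return mesh_fluid(case_model, DESK_MESH, seed=0)


@pytest.fixture(scope="module")
def solid_mesh(case_model, fluid_mesh):
    return mesh_solid(case_model, DESK_MESH, fluid_mesh=fluid_mesh)


class TestFluidMesh:
    def test_watertight_and_tagged(self, fluid_mesh):
        fluid_mesh.check_watertight()
        fluid_mesh.require_tags(("inlet", "outlet", "interface"))
        assert np.all(fluid_mesh.cell_volumes() > 0)

    def test_inlet_outlet_on_plane(self, fluid_mesh):
        for tag in ("inlet", "outlet"):
            verts = fluid_mesh.vertices[fluid_mesh.vertex_set(tag)]
            assert np.abs(verts[:, 1]).max() < 1e-9

    def test_coarsening_reduces_cell_count(self, case_model, fluid_mesh):
        coarser = MeshParams(bl_growth=1.6, bl_first_layer=0.15, bl_total=0.28,
                             core_size=1.3, solid_layers=2,
                             solid_layer_thickness=0.125)
        m2 = mesh_fluid(case_model, coarser, seed=0)
        assert m2.num_cells < fluid_mesh.num_cells

    def test_first_offwall_spacing_follows_bl(self, case_model):
        """Nearest off-wall neighbour distance tracks the first-layer size."""
        mp = DESK_MESH
        m = mesh_fluid(case_model, mp, seed=0)
        wall = m.vertex_set("interface")
        interior = np.setdiff1d(np.arange(m.num_vertices), wall)
        tree = cKDTree(m.vertices[interior])
        # sample wall vertices away from the inlet/outlet rims
        pts = m.vertices[wall]
        sample = pts[(pts[:, 1] > 3.0)][:200]
        d, _ = tree.query(sample)
        assert np.median(d) == pytest.approx(mp.bl_first_layer, rel=0.35)

    def test_lumen_volume_plausible(self, case_model, fluid_mesh):
        """Mesh volume close to the analytic tube + bulge (minus overlap)."""
        p = case_model.params
        v_tube = np.pi * p.tube_radius ** 2 * np.pi * p.torus_major_radius
        v_sphere = 4 / 3 * np.pi * p.bulge_radius ** 3
        v = fluid_mesh.cell_volumes().sum()
        assert v_tube * 0.9 < v < (v_tube + v_sphere) * 1.05


class TestSolidMesh:
    def test_interface_conformity(self, fluid_mesh, solid_mesh):
        """Fluid and solid interface triangulations are identical point sets."""
        fv = fluid_mesh.vertices[fluid_mesh.vertex_set("interface")]
        sv = solid_mesh.vertices[solid_mesh.vertex_set("interface")]
        assert len(fv) == len(sv)
        d, _ = cKDTree(sv).query(fv)
        assert d.max() == 0.0

    def test_through_thickness_layering(self, fluid_mesh, solid_mesh):
        nw = len(fluid_mesh.vertex_set("interface"))
        layers = DESK_MESH.solid_layers
        assert solid_mesh.num_vertices == (layers + 1) * nw
        # prisms split in 3: cell count is 3 * layers * n_interface_triangles
        ntri = (fluid_mesh.face_tags == FACE_TAGS["interface"]).sum()
        assert solid_mesh.num_cells == 3 * layers * ntri

    def test_layer_count_scales_cells(self, case_model, fluid_mesh):
        mp1 = MeshParams(bl_growth=DESK_MESH.bl_growth,
                         bl_first_layer=DESK_MESH.bl_first_layer,
                         bl_total=DESK_MESH.bl_total, core_size=DESK_MESH.core_size,
                         solid_layers=1, solid_layer_thickness=0.25)
        mp3 = MeshParams(bl_growth=DESK_MESH.bl_growth,
                         bl_first_layer=DESK_MESH.bl_first_layer,
                         bl_total=DESK_MESH.bl_total, core_size=DESK_MESH.core_size,
                         solid_layers=3, solid_layer_thickness=0.25 / 3)
        s1 = mesh_solid(case_model, mp1, fluid_mesh=fluid_mesh)
        s3 = mesh_solid(case_model, mp3, fluid_mesh=fluid_mesh)
        assert 3 * s1.num_cells == s3.num_cells

    def test_layer_thickness_mismatch_raises(self, case_model, fluid_mesh):
        bad = MeshParams(solid_layers=6, solid_layer_thickness=0.05)
        with pytest.raises(GeometryError, match="wall thickness"):
            mesh_solid(case_model, bad, fluid_mesh=fluid_mesh)

    def test_shell_thickness_along_normals(self, case_model, fluid_mesh, solid_mesh):
        """Exterior vertices sit one wall thickness from their interface mates
        (locally thinner only in the concave neck crease, where a full offset
        would fold the shell back into the lumen)."""
        nw = len(fluid_mesh.vertex_set("interface"))
        t = case_model.params.wall_thickness
        inner = solid_mesh.vertices[:nw]
        outer = solid_mesh.vertices[-nw:]
        d = np.linalg.norm(outer - inner, axis=1)
        assert np.all(d <= t * (1 + 1e-9))
        assert np.all(d >= 0.3 * t * (1 - 1e-9))
        nominal = np.isclose(d, t, rtol=1e-9)
        assert nominal.mean() > 0.9
        # away from the neck the thickness is exactly nominal
        away = (inner[:, 1] < 5.0) | (inner[:, 1] > 11.0)
        assert np.all(nominal[away])

    def test_fixed_plane_ring_exists(self, solid_mesh):
        verts = solid_mesh.vertex_set("fixed-plane")
        assert len(verts) > 0
        assert np.abs(solid_mesh.vertices[verts][:, 1]).max() < 1e-9


class TestTagRegions:
    def test_partition(self, solid_mesh):
        cut = 8.0
        tagged = tag_regions(solid_mesh, cut)
        n_b = (tagged.region_tags == REGION_TAGS["bulge-wall"]).sum()
        n_a = (tagged.region_tags == REGION_TAGS["artery-wall"]).sum()
        assert n_b + n_a == tagged.num_cells
        assert n_b > 0 and n_a > 0

    def test_predicate_matches_centroids(self, solid_mesh):
        tagged = tag_regions(solid_mesh, 8.0)
        cy = tagged.vertices[tagged.cells].mean(axis=1)[:, 1]
        bulge = tagged.region_tags == REGION_TAGS["bulge-wall"]
        assert np.array_equal(bulge, cy > 8.0)
        # any cell entirely above the plane must be bulge-wall
        all_above = (tagged.vertices[tagged.cells][:, :, 1] > 8.0).all(axis=1)
        assert np.all(bulge[all_above])

    def test_cut_above_apex_empties_bulge(self, solid_mesh):
        tagged = tag_regions(solid_mesh, 50.0)
        assert (tagged.region_tags == REGION_TAGS["bulge-wall"]).sum() == 0


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

class TestMeshIO:
    def test_round_trip_identity(self, coarse_tube, tmp_path):
        path = tmp_path / "tube.msh"
        write_mesh(coarse_tube, str(path))
        back = read_mesh(str(path))
        assert np.array_equal(coarse_tube.vertices, back.vertices)
        assert np.array_equal(coarse_tube.cells, back.cells)
        ours = {(*sorted(f), t) for f, t in zip(coarse_tube.faces.tolist(),
                                                coarse_tube.face_tags.tolist())}
        theirs = {(*sorted(f), t) for f, t in zip(back.faces.tolist(),
                                                  back.face_tags.tolist())}
        assert ours == theirs

    def test_missing_boundary_tags_named_in_error(self, coarse_tube, tmp_path):
        path = tmp_path / "untagged.msh"
        stripped = TaggedMesh(coarse_tube.vertices, coarse_tube.cells,
                              np.empty((0, 3), dtype=np.int64),
                              np.empty(0, dtype=np.int64))
        write_mesh(stripped, str(path))
        with pytest.raises(IOError_, match="inlet"):
            read_mesh(str(path))

    def test_missing_file_raises(self):
        with pytest.raises(IOError_):
            read_mesh("/nonexistent/mesh.msh")

    def test_vtu_written(self, coarse_tube, tmp_path):
        from aneufsi.io import write_vtu
        path = tmp_path / "tube.vtu"
        write_vtu(str(path), coarse_tube.vertices, coarse_tube.cells,
                  point_data={"height": coarse_tube.vertices[:, 1]})
        text = path.read_text()
        assert "UnstructuredGrid" in text and "height" in text
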