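"""Phantom generator: geometry, deformation operators, rasterization."""

import numpy as np
import pytest

from vdmkit.core import CenterlineCurve
from vdmkit.phantom import (
    DeformationSpec,
    IntensityModel,
    PhantomSpec,
    apply_drag,
    apply_radial_bulge,
    apply_sculpt_bulge,
    cos2_window,
    grid_around,
    make_centerline,
    make_tube_mesh,
    rasterize,
    straight_centerline,
)


class TestCenterline:
    def test_straight_segment_length(self):
        cl = straight_centerline(100.0)
        assert cl.length == pytest.approx(100.0, abs=1e-6)

    def test_semicircular_arch_length(self):
        spec = PhantomSpec(ascending_length=0.0, descending_length=0.0,
                          arch_radius=30.0)
        cl = make_centerline(spec)
        assert cl.length == pytest.approx(np.pi * 30.0, abs=0.1)

    def test_candycane_tangents_and_no_self_intersection(self):
        spec = PhantomSpec()
        cl = make_centerline(spec)
        assert np.allclose(np.linalg.norm(cl.tangents, axis=1), 1.0, atol=1e-9)
        # brute force: non-adjacent samples must stay farther apart than the
        # tube diameter
        # (pairs separated by > 40 mm of arc must stay farther apart than
        # the tube diameter; closer pairs are neighbors along the curve)
        pts = cl.resample(2.0).points
        d = np.linalg.norm(pts[:, None] - pts[None, :], axis=-1)
        n = len(pts)
        i, j = np.triu_indices(n, k=20)
        assert d[i, j].min() > 2 * 12.0

    def test_arc_length_monotone(self):
        cl = make_centerline(PhantomSpec())
        assert np.all(np.diff(cl.arc_length) > 0)

    def test_invalid_spec_rejected(self):
        with pytest.raises(ValueError):
            PhantomSpec(arch_radius=-1.0)
        with pytest.raises(ValueError):
            PhantomSpec(ascending_length=-5.0)


class TestTubeMesh:
    def test_cylinder_lateral_area(self, cylinder_mesh):
        area = cylinder_mesh.face_areas().sum()
        analytic = 2 * np.pi * 15.0 * 100.0
        assert area == pytest.approx(analytic, rel=0.005)

    def test_area_converges_with_refinement(self):
        cl = straight_centerline(100.0)
        analytic = 2 * np.pi * 15.0 * 100.0
        errors = []
        for n_circ in (8, 16, 32, 64):
            m = make_tube_mesh(cl, 15.0, n_circ=n_circ, axial_step=2.0)
            errors.append(abs(m.face_areas().sum() - analytic))
        assert all(np.diff(errors) < 0), "area error must shrink monotonically"

    def test_outward_normals(self, cylinder_mesh):
        fn = cylinder_mesh.face_normals()
        centers = cylinder_mesh.vertices[cylinder_mesh.faces].mean(axis=1)
        radial = centers.copy()
        radial[:, 2] = 0
        radial /= np.linalg.norm(radial, axis=1, keepdims=True)
        assert np.all(np.einsum("ij,ij->i", fn, radial) > 0)

    def test_bad_parameters_rejected(self):
        cl = straight_centerline(50.0)
        with pytest.raises(ValueError):
            make_tube_mesh(cl, 15.0, n_circ=4)
        with pytest.raises(ValueError):
            make_tube_mesh(cl, lambda s: s - 25.0)  # radius <= 0 mid-tube


class TestDeformations:
    def test_zero_magnitude_is_identity(self, cylinder_mesh):
        for out in (
            apply_radial_bulge(cylinder_mesh, 50.0, 30.0, 0.0),
            apply_sculpt_bulge(cylinder_mesh, 50.0, 0.0, 30.0, np.pi, 0.0),
            apply_drag(cylinder_mesh, (40.0, 60.0), (0, 0, 0), 10.0),
        ):
            assert np.array_equal(out.vertices, cylinder_mesh.vertices)
            assert np.array_equal(out.faces, cylinder_mesh.faces)

    def test_radial_bulge_apex_radius(self, cylinder_mesh):
        out = apply_radial_bulge(cylinder_mesh, 50.0, 30.0, 2.5)
        s = cylinder_mesh.attrs["s"]
        apex = np.isclose(s, 50.0)
        r = np.linalg.norm(out.vertices[apex][:, :2], axis=1)
        assert np.allclose(r, 17.5, atol=1e-9)

    def test_sculpt_apex_and_compact_support(self, cylinder_mesh):
        out = apply_sculpt_bulge(cylinder_mesh, 50.0, 0.0, 30.0, np.pi / 2, 3.0)
        disp = np.linalg.norm(out.vertices - cylinder_mesh.vertices, axis=1)
        s = cylinder_mesh.attrs["s"]
        th = cylinder_mesh.attrs["theta"]
        apex = np.isclose(s, 50.0) & np.isclose(th, 0.0)
        assert disp[apex] == pytest.approx(3.0, abs=1e-9)
        outside = (np.abs(s - 50.0) > 15.0) | (
            np.abs(np.angle(np.exp(1j * th))) > np.pi / 4
        )
        assert np.all(disp[outside] == 0.0)

    def test_drag_core_and_monotone_falloff(self, cylinder_mesh):
        t = np.array([2.0, -1.0, 3.0])
        out = apply_drag(cylinder_mesh, (40.0, 60.0), t, falloff=15.0)
        s = cylinder_mesh.attrs["s"]
        core = (s >= 40.0) & (s <= 60.0)
        disp = out.vertices - cylinder_mesh.vertices
        assert np.allclose(disp[core], t, atol=1e-12)
        # magnitude decays monotonically with arc distance from the region
        below = s < 40.0
        order = np.argsort(40.0 - s[below])  # increasing distance
        mags = np.linalg.norm(disp[below], axis=1)[order]
        assert np.all(np.diff(mags) <= 1e-12)

    def test_drag_caps_and_errors(self, cylinder_mesh):
        with pytest.raises(ValueError):
            apply_drag(cylinder_mesh, (40.0, 60.0), (20.0, 0, 0), 10.0)
        with pytest.raises(ValueError):
            apply_drag(cylinder_mesh, (40.0, 60.0), (1.0, 0, 0), falloff=0.0)

    def test_connectivity_never_changes(self, cylinder_mesh):
        out = apply_radial_bulge(
            apply_drag(cylinder_mesh, (10.0, 30.0), (0, 1.0, 0), 10.0),
            60.0, 25.0, 1.5,
        )
        assert out.faces.tobytes() == cylinder_mesh.faces.tobytes()

    def test_analytic_displacement_bounded_by_magnitude(self, cylinder_mesh):
        out = apply_radial_bulge(cylinder_mesh, 50.0, 30.0, 2.5)
        disp = np.linalg.norm(np.asarray(out.attrs["analytic_disp"]), axis=1)
        assert disp.max() == pytest.approx(2.5, abs=1e-9)
        assert np.all(disp <= 2.5 + 1e-12)

    def test_window_is_c1_compact(self):
        t = np.linspace(-2, 2, 2001)
        w = cos2_window(t)
        assert w[np.abs(t) >= 1].max() == 0.0
        assert cos2_window(0.0) == 1.0
        # derivative vanishes at the support edge: finite difference check
        eps = 1e-6
        assert abs(cos2_window(1 - eps) - cos2_window(1 - 2 * eps)) / eps < 1e-4


class TestRasterize:
    def test_cylinder_mask_volume(self, cylinder_mesh, cylinder_volume):
        _, mask = cylinder_volume
        vol = mask.data.sum() * np.prod(mask.grid.spacing)
        assert vol == pytest.approx(np.pi * 15.0**2 * 100.0, rel=0.02)

    def test_interior_voxel_exact_lumen_hu(self, cylinder_volume):
        img, mask = cylinder_volume
        g = img.grid
        center = tuple(n // 2 for n in g.shape)
        assert img.data[center] == 350.0

    def test_mask_identical_outside_deformation_support(self, cylinder_mesh):
        bulged = apply_radial_bulge(cylinder_mesh, 50.0, 30.0, 2.5)
        grid = grid_around(bulged.bounds(), (1.25, 1.25, 1.0), 8.0)
        _, m0 = rasterize(cylinder_mesh, grid, IntensityModel())
        _, m1 = rasterize(bulged, grid, IntensityModel())
        zs = grid.origin[2] + np.arange(grid.shape[2]) * grid.spacing[2]
        outside = (zs < 33.0) | (zs > 67.0)  # support is z in [35, 65]
        assert np.array_equal(m0.data[:, :, outside], m1.data[:, :, outside])

    def test_supersampling_reduces_boundary_error(self, cylinder_mesh):
        grid = grid_around(cylinder_mesh.bounds(), (2.0, 2.0, 2.0), 6.0)
        ref_img, _ = rasterize(cylinder_mesh, grid, IntensityModel(supersampling=8))
        errs = []
        for ss in (1, 4):
            img, _ = rasterize(cylinder_mesh, grid, IntensityModel(supersampling=ss))
            boundary = (ref_img.data > 60) & (ref_img.data < 330)
            errs.append(np.abs(img.data - ref_img.data)[boundary].mean())
        assert errs[1] < errs[0]

    def test_grid_must_contain_mesh(self, cylinder_mesh):
        small = grid_around(cylinder_mesh.bounds() * 0.5, (1.25, 1.25, 1.0), 1.0)
        with pytest.raises(ValueError):
            rasterize(cylinder_mesh, small, IntensityModel())

    def test_intensity_model_validation(self):
        with pytest.raises(ValueError):
            IntensityModel(lumen_hu=40.0, background_hu=40.0)
        with pytest.raises(ValueError):
            IntensityModel(supersampling=0)
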