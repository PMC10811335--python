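import numpy as np
import pytest

from vessel4d import phantom as ph
from vessel4d.surface import SurfaceMesh, extract_surface
from vessel4d.validation import (
    CuttingPlane,
    PlanarContour,
    WssSeries,
    compare_contours,
    cut_mesh,
    dice,
    jaccard,
    jaccard_from_dice,
    osi,
    rasterize_contour,
    roi_stats,
    validation_report,
    voxelize_mesh,
)

Z_MID = 36.0


def _icosphere(r=10.0):
    import trimesh

    tm = trimesh.creation.icosphere(subdivisions=3, radius=r)
    return SurfaceMesh(np.asarray(tm.vertices), np.asarray(tm.faces))


def _circle_contour(r, center=(0.0, 0.0), n=256):
    ang = np.linspace(0, 2 * np.pi, n, endpoint=False)
    pts = np.column_stack([center[0] + r * np.cos(ang), center[1] + r * np.sin(ang)])
    plane = CuttingPlane(origin=(0, 0, 0), normal=(0, 0, 1), u=(1, 0, 0), v=(0, 1, 0))
    return PlanarContour(plane, pts)


class TestCutMesh:
    def test_equatorial_cut_of_sphere(self):
        mesh = _icosphere(10.0)
        plane = CuttingPlane(origin=(0, 0, 0), normal=(0, 0, 1))
        loops = cut_mesh(mesh, plane)
        assert len(loops) == 1
        perim = np.linalg.norm(
            np.diff(np.vstack([loops[0].points, loops[0].points[:1]]), axis=0), axis=1
        ).sum()
        assert perim == pytest.approx(2 * np.pi * 10, rel=0.02)

    def test_plane_missing_mesh_returns_empty(self):
        loops = cut_mesh(_icosphere(5.0), CuttingPlane(origin=(0, 0, 50.0), normal=(0, 0, 1)))
        assert loops == []

    def test_phantom_cut_area_matches_analytic(self, quiet_spec):
        mesh = ph.truth_surface(quiet_spec, 50)
        plane = CuttingPlane(origin=quiet_spec.centerline(Z_MID, 50).ravel(),
                             normal=(0, 0, 1))
        loops = cut_mesh(mesh, plane)
        assert len(loops) >= 1
        analytic = ph.analytic_contour(quiet_spec, 50, plane)
        best = min(loops, key=lambda c: np.linalg.norm(c.centroid() - analytic.centroid()))
        assert best.area == pytest.approx(analytic.area, rel=0.03)

    def test_vertex_on_plane_is_tie_broken(self):
        # a tetra with one vertex exactly on the plane still yields closed loops
        verts = np.array([[0, 0, 0.0], [2, 0, 1.0], [0, 2, 1.0], [-1, -1, 1.0],
                          [0.5, 0.5, -1.5]])
        faces = np.array([[0, 1, 2], [0, 2, 3], [0, 3, 1], [1, 3, 4],
                          [1, 4, 2], [2, 4, 3]])
        mesh = SurfaceMesh(verts, faces)
        loops = cut_mesh(mesh, CuttingPlane(origin=(0, 0, 0), normal=(0, 0, 1)))
        for lp in loops:
            assert len(lp.points) >= 3


class TestRasterize:
    def test_square_pixel_count(self):
        sq = PlanarContour(
            CuttingPlane(origin=(0, 0, 0), normal=(0, 0, 1), u=(1, 0, 0), v=(0, 1, 0)),
            np.array([[0, 0], [10, 0], [10, 10], [0, 10.0]]),
        )
        m = rasterize_contour(sq, pixel=0.05)
        assert abs(int(m.sum()) - 200 * 200) <= 4 * 200  # within one boundary ring

    def test_translation_equivariance(self):
        c = _circle_contour(3.0)
        m0 = rasterize_contour(c, pixel=0.05, bounds=(-4, -4, 4, 4))
        shifted = PlanarContour(c.plane, c.points + [7.0, -2.0])
        m1 = rasterize_contour(shifted, pixel=0.05, bounds=(3, -6, 11, 2))
        assert np.array_equal(m0, m1)

    def test_refinement_convergence(self):
        c = _circle_contour(2.5)
        a1 = rasterize_contour(c, pixel=0.05).sum() * 0.05**2
        a2 = rasterize_contour(c, pixel=0.025).sum() * 0.025**2
        assert abs(a1 - a2) / a2 < 0.005

    def test_degenerate_polygon_rejected(self):
        plane = CuttingPlane(origin=(0, 0, 0), normal=(0, 0, 1), u=(1, 0, 0), v=(0, 1, 0))
        sliver = PlanarContour(plane, np.array([[0, 0], [1, 0], [2, 0.0]]))
        with pytest.raises(ValueError, match="degenerate"):
            rasterize_contour(sliver, pixel=0.05)


class TestOverlapMetrics:
    def test_hand_counts(self):
        A = np.array([[1, 1, 0]], dtype=bool)
        B = np.array([[0, 1, 1]], dtype=bool)
        assert jaccard(A, B) == pytest.approx(1 / 3)
        assert dice(A, B) == pytest.approx(0.5)

    def test_equal_and_disjoint(self):
        A = np.eye(5, dtype=bool)
        assert jaccard(A, A) == 1.0 and dice(A, A) == 1.0
        assert jaccard(A, ~A) == 0.0 and dice(A, ~A) == 0.0

    def test_both_empty_undefined(self):
        Z = np.zeros((3, 3), bool)
        with pytest.raises(ValueError):
            jaccard(Z, Z)
        with pytest.raises(ValueError):
            dice(Z, Z)

    def test_identity_links_the_two_measures(self, rng):
        for _ in range(20):
            A = rng.random((30, 30)) > 0.5
            B = rng.random((30, 30)) > 0.3
            assert jaccard(A, B) == pytest.approx(
                jaccard_from_dice(dice(A, B)), abs=1e-9
            )
            assert jaccard(A, B) <= dice(A, B) <= 1.0


class TestCompareContours:
    def test_identical_contours(self):
        c = _circle_contour(2.0)
        rep = compare_contours(c, c)
        assert rep.jac == pytest.approx(1.0, abs=5e-3)
        assert rep.dice == pytest.approx(1.0, abs=5e-3)
        assert rep.centroid_offset == pytest.approx(0.0, abs=1e-9)

    def test_translated_identical_shape(self):
        a = _circle_contour(2.0)
        b = _circle_contour(2.0, center=(2.0, 0.0))
        rep = compare_contours(a, b)
        assert rep.centroid_offset == pytest.approx(2.0, abs=1e-3)
        assert rep.dice < 1.0
        assert rep.dice_centered == pytest.approx(1.0, abs=5e-3)
        assert rep.jac_centered >= rep.jac
        assert rep.dice_centered >= rep.dice

    def test_concentric_circles_closed_form(self):
        rep = compare_contours(_circle_contour(1.0), _circle_contour(2.0))
        assert rep.dice == pytest.approx(0.4, abs=5e-3)
        assert rep.jac == pytest.approx(0.25, abs=5e-3)
        # already concentric: centering changes nothing
        assert rep.jac_centered == pytest.approx(rep.jac, abs=5e-3)


class TestVoxelize:
    def test_truth_mesh_matches_truth_mask(self, quiet_spec, quiet_phase50, low_geo):
        _, mask = quiet_phase50
        mesh = ph.truth_surface(quiet_spec, 50)
        vox = voxelize_mesh(mesh, low_geo)
        assert dice(vox.values, mask.values) >= 0.95

    def test_sphere_volume(self, low_geo):
        mesh = _icosphere(8.0)
        mesh.vertices += [39.0, 39.0, 45.0]
        vox = voxelize_mesh(mesh, low_geo)
        vol = vox.voxel_count * np.prod(low_geo.spacing)
        assert vol == pytest.approx(4 / 3 * np.pi * 8**3, rel=0.05)


class TestRoiStats:
    def test_constant_region(self, quiet_phase50):
        vol, _ = quiet_phase50
        mean, sd = roi_stats(vol, ((0, 10), (0, 10), (0, 10)))
        assert sd == 0.0
        assert mean == pytest.approx(-50.0)  # background HU

    def test_two_value_mix(self):
        from vessel4d.geometry import ImageVolume, VolumeGeometry

        vals = np.zeros((4, 4, 4))
        vals[:2] = 2.0
        vol = ImageVolume(geometry=VolumeGeometry((4, 4, 4), (1, 1, 1)), values=vals)
        mean, _ = roi_stats(vol, ((0, 4), (0, 4), (0, 4)))
        assert mean == pytest.approx(1.0)

    def test_empty_box_rejected(self, quiet_phase50):
        with pytest.raises(ValueError, match="empty"):
            roi_stats(quiet_phase50[0], ((5, 5), (0, 4), (0, 4)))


class TestOsi:
    def test_constant_vector_is_zero(self):
        t = np.linspace(0, 1, 50)
        w = np.tile([1.0, 2.0, 0.5], (50, 1))
        assert osi(WssSeries(t, w)) == pytest.approx(0.0, abs=1e-12)

    def test_perfect_reversal_is_half(self):
        t = np.linspace(0, 1, 2000)
        w = np.where(t[:, None] < 0.5, [1.0, 0, 0], [-1.0, 0, 0])
        assert osi(WssSeries(t, w)) == pytest.approx(0.5, abs=1e-3)

    def test_quarter_turn_rotation_matches_analytic_value(self):
        # |integral| / integral|.| = (2 sqrt 2 / pi) for a uniform 90-degree
        # sweep at constant magnitude -> OSI = 0.5 (1 - 2 sqrt2/pi) ~ 0.0498;
        # cross-checked against fine-grid quadrature of the closed form
        t = np.linspace(0, 1, 4000)
        ang = t * (np.pi / 2)
        w = np.column_stack([np.cos(ang), np.sin(ang), np.zeros_like(ang)])
        expected = 0.5 * (1 - 2 * np.sqrt(2) / np.pi)
        assert osi(WssSeries(t, w)) == pytest.approx(expected, abs=1e-3)
        fine = np.trapezoid(w, x=t, axis=0)
        oracle = 0.5 * (1 - np.linalg.norm(fine) / np.trapezoid(np.linalg.norm(w, axis=1), x=t))
        assert osi(WssSeries(t, w)) == pytest.approx(oracle, abs=1e-12)

    def test_scale_invariance(self, rng):
        t = np.linspace(0, 1, 300)
        w = rng.normal(size=(300, 3))
        assert osi(WssSeries(t, w)) == pytest.approx(osi(WssSeries(t, 7.3 * w)), abs=1e-12)

    def test_zero_magnitude_rejected(self):
        t = np.linspace(0, 1, 10)
        with pytest.raises(ValueError, match="zero WSS"):
            osi(WssSeries(t, np.zeros((10, 3))))


class TestValidationReport:
    def test_self_comparison_and_row_count(self, quiet_spec):
        from vessel4d.propagation import PhaseSequence

        phases = [40.0, 50.0]
        seg_meshes = {p: ph.truth_surface(quiet_spec, p) for p in phases}
        # a legitimate constant-topology sequence: reference mesh plus a
        # slightly shifted copy sharing the same faces array
        base = seg_meshes[40.0]
        shifted = SurfaceMesh.__new__(SurfaceMesh)
        shifted.vertices = base.vertices + [0.2, 0.0, 0.0]
        shifted.faces = base.faces
        seq = PhaseSequence(phases=phases, meshes=[base, shifted], faces=base.faces)
        planes = [
            CuttingPlane(origin=quiet_spec.centerline(z, 50).ravel(), normal=(0, 0, 1))
            for z in (26.0, Z_MID)
        ]
        # references are the segmentation meshes' own cross-sections, so the
        # segmentation rows are exact self-comparisons
        refs = {}
        for p in phases:
            for pos, plane in enumerate(planes):
                refs[(p, pos)] = cut_mesh(seg_meshes[p], plane)[0]
        df = validation_report(seq, seg_meshes, refs, planes)
        assert len(df) == len(phases) * len(planes) * 2
        self_rows = df[df.source == "segmentation"]
        assert (self_rows.jac > 0.99).all()
        assert (self_rows.dice > 0.99).all()
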