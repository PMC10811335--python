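import numpy as np
import pytest

from vessel4d import phantom as ph
from vessel4d import registration as reg
from vessel4d.geometry import BinaryMask, VolumeGeometry
from vessel4d.validation import dice

LOW_VOXEL = 0.8125  # mm, in-plane low-res pixel


# --------------------------------------------------------------------------
# analytic voxelized shapes (partial-volume supersampled, so the discrete
# oracle tracks the continuous transform closely)
# --------------------------------------------------------------------------

def _ellipsoid_mask(geo, R=np.eye(3), scale=1.0, axes=(20.0, 14.0, 10.0), k=3):
    n = geo.shape[0]
    sub = np.arange(n * k) // k - 0.5 + (np.arange(n * k) % k + 0.5) / k
    X, Y, Z = np.meshgrid(sub, sub, sub, indexing="ij")
    c = (n - 1) / 2
    pts = np.stack([X - c, Y - c, Z - c], -1)
    d = (pts @ R) * scale / np.asarray(axes)
    occ = ((d**2).sum(-1) < 1.0).reshape(n, k, n, k, n, k).mean(axis=(1, 3, 5))
    return BinaryMask(geometry=geo, values=occ > 0.5)


@pytest.fixture(scope="module")
def iso_geo():
    return VolumeGeometry(shape=(64, 64, 64), spacing=(1.0, 1.0, 1.0))


@pytest.fixture(scope="module")
def ellipsoid(iso_geo):
    return _ellipsoid_mask(iso_geo)


@pytest.fixture(scope="module")
def quiet_masks(quiet_spec, low_geo):
    return {
        p: ph.generate_phase_volume(quiet_spec, p, low_geo)[1] for p in (50, 60, 90)
    }


class TestRigid:
    def test_self_registration_is_identity(self, ellipsoid):
        r = reg.register_rigid(ellipsoid, ellipsoid)
        probe = np.array([[10.0, 5.0, 2.0]])
        assert np.abs(r.apply(probe) - probe).max() < 1e-3
        angle = np.arccos(np.clip((np.trace(r.A) - 1) / 2, -1, 1))
        assert angle < 1e-4

    def test_translation_recovered(self, quiet_masks, low_geo):
        fixed = quiet_masks[50]
        moving = BinaryMask(geometry=low_geo,
                            values=np.roll(fixed.values, (2, -1, 0), axis=(0, 1, 2)))
        r = reg.register_rigid(fixed, moving)
        shift = r.apply([[0.0, 0.0, 0.0]])[0]
        assert np.allclose(shift, [2 * 0.8125, -0.8125, 0.0], atol=0.1)

    def test_rotation_recovered(self, iso_geo, ellipsoid):
        th = np.radians(5.0)
        Rz = np.array([[np.cos(th), -np.sin(th), 0],
                       [np.sin(th), np.cos(th), 0], [0, 0, 1.0]])
        moving = _ellipsoid_mask(iso_geo, R=Rz)
        r = reg.register_rigid(ellipsoid, moving)
        recovered = np.degrees(np.arctan2(r.A[1, 0], r.A[0, 0]))
        assert recovered == pytest.approx(5.0, abs=0.2)

    def test_empty_mask_rejected(self, iso_geo, ellipsoid):
        empty = BinaryMask(geometry=iso_geo, values=np.zeros(iso_geo.shape, bool))
        with pytest.raises(ValueError, match="empty"):
            reg.register_rigid(ellipsoid, empty)


class TestAffine:
    def test_isotropic_scale_recovered(self, iso_geo, ellipsoid):
        moving = _ellipsoid_mask(iso_geo, scale=1.05)  # object shrunk by 1/1.05
        a = reg.register_affine(ellipsoid, moving)
        recovered = np.linalg.det(a.A) ** (1 / 3)
        assert recovered == pytest.approx(1 / 1.05, rel=0.01)

    def test_never_worse_than_init(self, ellipsoid):
        # self-registration from an already-optimal identity init
        init = reg.AffineTransform.identity()
        a = reg.register_affine(ellipsoid, ellipsoid, init)
        f = reg._smoothed_float(ellipsoid)
        assert (reg._metric_value(f, f, a.to_sitk())
                <= reg._metric_value(f, f, init.to_sitk()) + 1e-12)

    def test_affine_serialization_round_trip(self, tmp_path):
        a = reg.AffineTransform(np.diag([1.1, 0.9, 1.0]), [1, 2, 3], [4, 5, 6])
        a.to_json(tmp_path / "a.json")
        b = reg.AffineTransform.from_json(tmp_path / "a.json")
        assert np.allclose(a.A, b.A) and np.allclose(a.t, b.t) and np.allclose(a.center, b.center)

    def test_orientation_reversal_rejected(self):
        with pytest.raises(ValueError, match="det"):
            reg.AffineTransform(np.diag([-1.0, 1, 1]), np.zeros(3), np.zeros(3))


class TestDeformable:
    def test_self_registration_field_is_tiny(self, quiet_masks):
        chain = reg.register_deformable(
            quiet_masks[50], quiet_masks[50], reg.AffineTransform.identity()
        )
        assert np.abs(chain.field.displacement).max() < 0.1 * LOW_VOXEL

    def test_synthetic_sinusoidal_warp_recovered(self, quiet_spec, quiet_masks, low_geo):
        """2 mm-amplitude smooth sinusoidal warp; mean surface error < 1 voxel."""

        def T(p):
            q = p.copy()
            q[:, 0] += 2.0 * np.sin(2 * np.pi * p[:, 2] / 100.0)
            return q

        def T_inv(q, iters=30):
            p = q.copy()
            for _ in range(iters):
                p = q - (T(p) - p)
            return p

        idx = np.stack(np.meshgrid(*[np.arange(n) for n in low_geo.shape],
                                   indexing="ij"), axis=-1).reshape(-1, 3)
        pts = idx * np.asarray(low_geo.spacing)
        moving = BinaryMask(
            geometry=low_geo,
            values=(quiet_spec.signed_distance(T_inv(pts), 50) < 0).reshape(low_geo.shape),
        )
        chain = reg.register_deformable(quiet_masks[50], moving)
        surf = ph.truth_surface(quiet_spec, 50).vertices[::5]
        mapped = chain.affine.apply(surf)
        mapped = mapped + chain.field.sample(mapped)
        err = np.linalg.norm(mapped - T(surf.copy()), axis=1)
        assert err.mean() < LOW_VOXEL

    def test_adjacent_phase_deformation_recovered(self, quiet_spec, quiet_masks):
        chain = reg.register_deformable(quiet_masks[50], quiet_masks[60])
        surf = ph.truth_surface(quiet_spec, 50).vertices[::5]
        mapped = chain.affine.apply(surf)
        mapped = mapped + chain.field.sample(mapped)
        true = quiet_spec.displace_points(surf, 50, 60)
        assert np.linalg.norm(mapped - true, axis=1).mean() < LOW_VOXEL

    def test_staged_improvement(self, quiet_masks, low_geo):
        # a large phase gap, where each stage has real work to do
        fixed, moving = quiet_masks[50], quiet_masks[90]
        d_raw = dice(fixed.values, moving.values)
        affine = reg.register_affine(fixed, moving)
        id_field = reg.DeformationField(
            geometry=low_geo, displacement=np.zeros(low_geo.shape + (3,))
        )
        aff_chain = reg.TransformChain(affine=affine, field=id_field)
        w_aff = reg.warp_image(aff_chain, moving, output_geometry=low_geo)
        d_aff = dice(fixed.values, w_aff.values > 0.5)
        full = reg.register_deformable(fixed, moving, affine)
        w_full = reg.warp_image(full, moving, output_geometry=low_geo)
        d_full = dice(fixed.values, w_full.values > 0.5)
        assert d_full >= d_aff >= d_raw

    def test_jacobian_positive(self, quiet_masks):
        chain = reg.register_deformable(quiet_masks[50], quiet_masks[60])
        assert reg.jacobian_determinant(chain.field).min() > 0

    def test_masks_beat_raw_images_on_noisy_diastole(self, noisy_spec, low_geo):
        """Registering segmented masks outperforms registering raw volumes
        when the moving phase is the noisy end-diastolic acquisition."""
        v50, m50 = ph.generate_phase_volume(noisy_spec, 50, low_geo)
        v90, m90 = ph.generate_phase_volume(noisy_spec, 90, low_geo)
        ident = reg.AffineTransform.identity()
        ch_raw = reg.register_deformable(v50, v90, ident)
        ch_mask = reg.register_deformable(m50, m90, ident)
        d = {}
        for name, ch in (("raw", ch_raw), ("mask", ch_mask)):
            w = reg.warp_image(ch, m90, output_geometry=low_geo)
            d[name] = dice(m50.values, w.values > 0.5)
        assert d["mask"] > d["raw"]

    def test_chain_save_load_round_trip(self, tmp_path, quiet_masks):
        chain = reg.register_deformable(quiet_masks[50], quiet_masks[60])
        chain.source_phase, chain.target_phase = 50.0, 60.0
        chain.save(tmp_path / "c")
        back = reg.TransformChain.load(tmp_path / "c")
        assert np.allclose(back.affine.A, chain.affine.A)
        assert np.allclose(back.field.displacement, chain.field.displacement, atol=1e-6)
        assert back.target_phase == 60.0


class TestClipMask:
    def test_no_planes_is_identity(self, quiet_masks):
        out = reg.clip_mask(quiet_masks[50], [])
        assert np.array_equal(out.values, quiet_masks[50].values)

    def test_far_plane_is_identity(self, quiet_masks):
        out = reg.clip_mask(quiet_masks[50], [((0, 0, -100.0), (0, 0, 1.0))])
        assert np.array_equal(out.values, quiet_masks[50].values)

    def test_mid_plane_strictly_shrinks(self, quiet_masks):
        out = reg.clip_mask(quiet_masks[50], [((0, 0, 36.0), (0, 0, 1.0))])
        assert 0 < out.voxel_count < quiet_masks[50].voxel_count

    def test_all_removed_rejected(self, quiet_masks):
        with pytest.raises(ValueError, match="entire"):
            reg.clip_mask(quiet_masks[50], [((0, 0, 1000.0), (0, 0, 1.0))])


class TestWarpImage:
    def test_identity_chain_preserves_image(self, quiet_masks, low_geo):
        ident = reg.TransformChain(
            affine=reg.AffineTransform.identity(),
            field=reg.DeformationField(geometry=low_geo,
                                       displacement=np.zeros(low_geo.shape + (3,))),
        )
        w = reg.warp_image(ident, quiet_masks[50], output_geometry=low_geo)
        assert dice(quiet_masks[50].values, w.values > 0.5) > 0.999

    def test_constant_field_shifts_image(self, quiet_masks, low_geo):
        disp = np.zeros(low_geo.shape + (3,))
        disp[..., 2] = 1.5  # one z voxel
        ch = reg.TransformChain(
            affine=reg.AffineTransform.identity(),
            field=reg.DeformationField(geometry=low_geo, displacement=disp),
        )
        w = reg.warp_image(ch, quiet_masks[50], output_geometry=low_geo)
        # pull-back by +1 voxel in z == array shifted one slice toward -z
        expected = np.roll(quiet_masks[50].values, -1, axis=2)
        assert dice(expected, w.values > 0.5) > 0.98

    def test_warp_then_inverse_warp_restores_blob(self, low_geo):
        # analytic warp with an exact analytic inverse (fixed-point)
        def T(p):
            q = p.copy()
            q[:, 0] += 1.5 * np.sin(2 * np.pi * p[:, 2] / 90.0)
            return q

        def T_inv(q, iters=30):
            p = q.copy()
            for _ in range(iters):
                p = q - (T(p) - p)
            return p

        idx = np.stack(np.meshgrid(*[np.arange(n) for n in low_geo.shape],
                                   indexing="ij"), axis=-1).reshape(-1, 3)
        pts = idx * np.asarray(low_geo.spacing)
        blob = np.linalg.norm(pts - [39, 39, 45], axis=1).reshape(low_geo.shape) < 12
        mask = BinaryMask(geometry=low_geo, values=blob)

        def chain_from(fn):
            disp = (fn(pts) - pts).reshape(low_geo.shape + (3,))
            return reg.TransformChain(
                affine=reg.AffineTransform.identity(),
                field=reg.DeformationField(geometry=low_geo, displacement=disp),
            )

        w1 = reg.warp_image(chain_from(T), mask, output_geometry=low_geo)
        m1 = BinaryMask(geometry=low_geo, values=w1.values > 0.5)
        w2 = reg.warp_image(chain_from(T_inv), m1, output_geometry=low_geo)
        assert dice(mask.values, w2.values > 0.5) >= 0.98
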