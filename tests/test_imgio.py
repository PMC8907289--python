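import numpy as np
import pytest

from duograde.imgio import (
    RoiTensor,
    UndefinedRatioError,
    Volume3D,
    VolumeError,
    VolumeFormatError,
    compute_r_ratio,
    crop_to_roi,
    mask_volume_mm3,
    normalize_intensity,
    read_volume,
    resample_isotropic,
    resample_to_reference,
    write_volume,
)

from conftest import make_sphere_mask, make_volume


class TestRoundTrip:
    def test_write_read_identical(self, tmp_path, rng):
        vol = make_volume(rng.standard_normal((8, 8, 8)))
        path = tmp_path / "v.nii.gz"
        write_volume(vol, path)
        back = read_volume(path)
        np.testing.assert_array_equal(back.values, vol.values)
        np.testing.assert_allclose(back.affine, vol.affine, atol=1e-5)

    def test_4d_payload_rejected(self, tmp_path):
        import nibabel as nib

        path = tmp_path / "v4.nii.gz"
        nib.save(nib.Nifti1Image(np.zeros((4, 4, 4, 2)), np.eye(4)), path)
        with pytest.raises(VolumeFormatError):
            read_volume(path)

    def test_malformed_file_rejected(self, tmp_path):
        path = tmp_path / "junk.nii.gz"
        path.write_bytes(b"this is not nifti")
        with pytest.raises(VolumeFormatError):
            read_volume(path)

    def test_mask_role_rejects_nonbinary(self):
        values = np.zeros((4, 4, 4))
        values[1, 1, 1] = 2
        with pytest.raises(VolumeError):
            make_volume(values, role="MASK")

    def test_non_invertible_affine_rejected(self):
        affine = np.eye(4)
        affine[0, 0] = 0
        with pytest.raises(VolumeError):
            Volume3D(np.zeros((4, 4, 4)), affine)


class TestResampleToReference:
    def test_identity_on_same_grid(self, rng):
        vol = make_volume(rng.standard_normal((6, 6, 6)))
        ref = make_volume(np.zeros((6, 6, 6)))
        out = resample_to_reference(vol, ref, "trilinear")
        np.testing.assert_allclose(out.values, vol.values, atol=1e-6)

    def test_constant_preserved_in_fov(self):
        affine = np.diag([2.0, 2.0, 2.0, 1.0])
        vol = make_volume(np.full((10, 10, 10), 3.5), affine)
        ref = make_volume(np.zeros((8, 8, 8)))  # 1 mm grid inside the 2 mm FOV
        out = resample_to_reference(vol, ref, "trilinear")
        np.testing.assert_allclose(out.values, 3.5, atol=1e-6)

    def test_sphere_volume_against_analytic_oracle(self):
        # oracle: analytic sphere volume 4/3 pi r^3
        radius_mm = 12.0
        affine2 = np.diag([2.0, 2.0, 2.0, 1.0])
        mask2 = make_sphere_mask((20, 20, 20), (9.5, 9.5, 9.5), radius_mm / 2.0, affine2)
        ref = make_volume(np.zeros((40, 40, 40)))
        out = resample_to_reference(mask2, ref, "nearest")
        analytic = 4.0 / 3.0 * np.pi * radius_mm**3
        assert mask_volume_mm3(out) == pytest.approx(analytic, rel=0.03)

    def test_disjoint_fov_warns_and_fills(self):
        vol = make_volume(np.ones((4, 4, 4)))
        far = np.eye(4)
        far[:3, 3] = 100.0
        ref = Volume3D(np.zeros((4, 4, 4)), far)
        with pytest.warns(UserWarning, match="do not overlap"):
            out = resample_to_reference(vol, ref)
        assert np.all(out.values == 0)

    def test_nearest_mask_stays_binary(self, rng):
        mask = make_volume((rng.random((9, 9, 9)) > 0.5).astype(np.uint8),
                           np.diag([1.7, 1.7, 1.7, 1.0]), "MASK")
        ref = make_volume(np.zeros((15, 15, 15)))
        out = resample_to_reference(mask, ref)
        assert out.channel_role == "MASK"
        assert set(np.unique(out.values)) <= {0, 1}

    def test_linearity_in_intensity(self, rng):
        values = rng.standard_normal((7, 7, 7))
        affine = np.diag([1.3, 1.3, 1.3, 1.0])
        ref = make_volume(np.zeros((9, 9, 9)))
        out1 = resample_to_reference(make_volume(values, affine), ref, "trilinear")
        out2 = resample_to_reference(make_volume(3.0 * values, affine), ref, "trilinear")
        np.testing.assert_allclose(out2.values, 3.0 * out1.values, atol=1e-5)


class TestResampleIsotropic:
    def test_identity_when_already_isotropic(self, rng):
        vol = make_volume(rng.standard_normal((5, 5, 5)))
        out = resample_isotropic(vol, 1.0)
        np.testing.assert_array_equal(out.values, vol.values)

    def test_2mm_to_1mm_doubles_grid(self):
        vol = make_volume(np.zeros((10, 10, 10)), np.diag([2.0, 2.0, 2.0, 1.0]))
        out = resample_isotropic(vol, 1.0)
        assert out.shape == (20, 20, 20)
        np.testing.assert_allclose(out.spacing, 1.0)

    def test_mask_volume_preserved(self):
        affine2 = np.diag([2.0, 2.0, 2.0, 1.0])
        mask = make_sphere_mask((20, 20, 20), (9.5, 9.5, 9.5), 6.0, affine2)
        before = mask_volume_mm3(mask)
        out = resample_isotropic(mask, 1.0)
        assert mask_volume_mm3(out) == pytest.approx(before, rel=0.03)

    def test_invalid_target(self):
        vol = make_volume(np.zeros((4, 4, 4)))
        with pytest.raises(ValueError):
            resample_isotropic(vol, 0.0)


class TestMaskVolume:
    def test_1000_voxels_at_1mm(self):
        values = np.zeros((12, 12, 12), dtype=np.uint8)
        values.ravel()[:1000] = 1
        assert mask_volume_mm3(make_volume(values, role="MASK")) == 1000.0

    def test_1000_voxels_at_2mm(self):
        values = np.zeros((12, 12, 12), dtype=np.uint8)
        values.ravel()[:1000] = 1
        vol = make_volume(values, np.diag([2.0, 2.0, 2.0, 1.0]), "MASK")
        assert mask_volume_mm3(vol) == 8000.0

    def test_empty_mask(self):
        assert mask_volume_mm3(make_volume(np.zeros((4, 4, 4)), role="MASK")) == 0.0

    def test_requires_mask_role(self):
        with pytest.raises(VolumeError):
            mask_volume_mm3(make_volume(np.zeros((4, 4, 4))))


class TestRRatio:
    def test_identical_masks_give_one(self):
        values = np.zeros((8, 8, 8), dtype=np.uint8)
        values[2:5, 2:5, 2:5] = 1
        a = make_volume(values, role="MASK")
        b = make_volume(values.copy(), role="MASK")
        assert compute_r_ratio(a, b) == 1.0

    def test_arithmetic(self):
        v1 = np.zeros((12, 12, 12), dtype=np.uint8)
        v1.ravel()[:1000] = 1
        v2 = np.zeros((12, 12, 12), dtype=np.uint8)
        v2.ravel()[:1250] = 1
        r = compute_r_ratio(make_volume(v1, role="MASK"), make_volume(v2, role="MASK"))
        assert r == pytest.approx(0.8)

    def test_scale_free(self):
        v1 = np.zeros((8, 8, 8), dtype=np.uint8)
        v1[1:4] = 1
        v2 = np.zeros((8, 8, 8), dtype=np.uint8)
        v2[1:5] = 1
        r1 = compute_r_ratio(make_volume(v1, role="MASK"), make_volume(v2, role="MASK"))
        big = np.diag([2.0, 2.0, 2.0, 1.0])
        r2 = compute_r_ratio(
            make_volume(v1, big, "MASK"), make_volume(v2, big, "MASK")
        )
        assert r1 == pytest.approx(r2)

    def test_empty_flair_mask_undefined(self):
        v1 = np.zeros((4, 4, 4), dtype=np.uint8)
        v1[1, 1, 1] = 1
        with pytest.raises(UndefinedRatioError):
            compute_r_ratio(make_volume(v1, role="MASK"),
                            make_volume(np.zeros((4, 4, 4)), role="MASK"))


class TestCropToRoi:
    def test_full_grid_identity(self, rng):
        t1 = make_volume(rng.standard_normal((8, 8, 8)))
        fl = make_volume(rng.standard_normal((8, 8, 8)), role="FLAIR")
        mask = make_volume(np.ones((8, 8, 8), dtype=np.uint8), role="MASK")
        roi = crop_to_roi(t1, fl, mask, (8, 8, 8))
        np.testing.assert_allclose(roi.values[0], t1.values)
        np.testing.assert_allclose(roi.values[1], fl.values)

    def test_single_voxel_centering_convention(self):
        mask_values = np.zeros((16, 16, 16), dtype=np.uint8)
        mask_values[5, 5, 5] = 1
        t1 = make_volume(np.zeros((16, 16, 16)))
        fl = make_volume(np.zeros((16, 16, 16)), role="FLAIR")
        roi = crop_to_roi(t1, fl, make_volume(mask_values, role="MASK"), (8, 8, 8))
        assert roi.crop_origin == (1, 1, 1)

    def test_centroid_at_center_against_oracle(self, rng):
        for _ in range(10):
            mask_values = np.zeros((24, 24, 24), dtype=np.uint8)
            n = rng.integers(5, 60)
            idx = rng.integers(4, 20, size=(n, 3))
            mask_values[idx[:, 0], idx[:, 1], idx[:, 2]] = 1
            t1 = make_volume(rng.standard_normal((24, 24, 24)))
            fl = make_volume(rng.standard_normal((24, 24, 24)), role="FLAIR")
            roi = crop_to_roi(t1, fl, make_volume(mask_values, role="MASK"), (12, 12, 12))
            # brute-force centroid oracle in source coordinates
            centroid = np.array(np.nonzero(mask_values)).mean(axis=1)
            center_in_crop = centroid - np.array(roi.crop_origin)
            assert np.all(np.abs(center_in_crop - 6.0) <= 1.0)

    def test_cross_channel_alignment(self, rng):
        values = rng.standard_normal((16, 16, 16))
        mask_values = np.zeros((16, 16, 16), dtype=np.uint8)
        mask_values[6:10, 6:10, 6:10] = 1
        t1 = make_volume(values)
        fl = make_volume(values.copy(), role="FLAIR")
        roi = crop_to_roi(t1, fl, make_volume(mask_values, role="MASK"), (8, 8, 8))
        np.testing.assert_array_equal(roi.values[0], roi.values[1])

    def test_empty_mask_rejected(self):
        t1 = make_volume(np.zeros((8, 8, 8)))
        fl = make_volume(np.zeros((8, 8, 8)), role="FLAIR")
        with pytest.raises(VolumeError):
            crop_to_roi(t1, fl, make_volume(np.zeros((8, 8, 8)), role="MASK"), (4, 4, 4))


class TestNormalize:
    def test_constant_maps_to_zero(self):
        out = normalize_intensity(make_volume(np.full((5, 5, 5), 7.0)))
        assert np.all(out.values == 0)

    def test_zscore_over_support(self, rng):
        values = rng.standard_normal((10, 10, 10)) + 5.0
        values[:3] = 0.0  # outside support
        out = normalize_intensity(make_volume(values))
        support = values != 0
        assert out.values[support].mean() == pytest.approx(0.0, abs=1e-6)
        assert out.values[support].std() == pytest.approx(1.0, abs=1e-6)

    def test_idempotent_on_support(self, rng):
        values = rng.standard_normal((10, 10, 10)) * 3 + 2
        once = normalize_intensity(make_volume(values))
        twice = normalize_intensity(once)
        support = values != 0
        np.testing.assert_allclose(
            twice.values[support], once.values[support], atol=1e-9
        )

    def test_nonfinite_rejected(self):
        values = np.zeros((4, 4, 4))
        values[0, 0, 0] = np.inf
        with pytest.raises(VolumeError):
            normalize_intensity(make_volume(values))


def test_roi_tensor_shape_validation():
    with pytest.raises(VolumeError):
        RoiTensor(np.zeros((3, 4, 4, 4)), "s", (0, 0, 0))
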