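"""Volume model, NIfTI I/O, HU calibration, filtering and resampling."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import vqmouse as vq
from vqmouse.core import Grid


# ---------------------------------------------------------------------- I/O
class TestNiftiRoundTrip:
    def test_integer_data_roundtrips_bitwise(self, tmp_path):
        rng = np.random.default_rng(0)
        data = rng.integers(-1000, 1000, size=(16, 16, 16)).astype(np.int16)
        v = vq.Volume(data, spacing_mm=0.472, origin_mm=(1.0, -2.0, 3.0),
                      modality="SPECT")
        p = tmp_path / "v.nii.gz"
        vq.write_volume(v, p)
        r = vq.read_volume(p, modality="SPECT")
        assert np.array_equal(r.data, data)
        assert r.spacing_mm == pytest.approx(0.472, abs=1e-6)
        assert np.allclose(r.origin_mm, v.origin_mm, atol=1e-5)

    def test_float_data_roundtrips_within_eps(self, tmp_path):
        rng = np.random.default_rng(1)
        data = rng.normal(size=(8, 8, 8)).astype(np.float32)
        v = vq.Volume(data, spacing_mm=0.23)
        p = tmp_path / "v.nii"
        vq.write_volume(v, p)
        r = vq.read_volume(p)
        assert np.allclose(r.data, data, atol=np.finfo(np.float32).eps * 8)

    def test_high_resolution_ct_spacing_preserved(self, tmp_path):
        # the reconstruction grid of the source protocol: 0.115 mm voxels
        v = vq.Volume(np.zeros((8, 8, 8)), spacing_mm=0.115)
        p = tmp_path / "ct.nii.gz"
        vq.write_volume(v, p)
        assert vq.read_volume(p).spacing_mm == pytest.approx(0.115, abs=1e-6)

    def test_4d_data_rejected(self, tmp_path):
        import nibabel as nib
        img = nib.Nifti1Image(np.zeros((4, 4, 4, 3)), np.eye(4))
        p = tmp_path / "bad.nii"
        nib.save(img, str(p))
        with pytest.raises(ValueError, match="expected 3D"):
            vq.read_volume(p)

    def test_missing_file(self, tmp_path):
        with pytest.raises(FileNotFoundError):
            vq.read_volume(tmp_path / "nope.nii")

    def test_anisotropic_spacing_rejected(self, tmp_path):
        import nibabel as nib
        img = nib.Nifti1Image(np.zeros((4, 4, 4)),
                              np.diag([0.2, 0.2, 0.5, 1.0]))
        p = tmp_path / "aniso.nii"
        nib.save(img, str(p))
        with pytest.raises(ValueError, match="anisotropic"):
            vq.read_volume(p)


# -------------------------------------------------------------- calibration
class TestHUCalibration:
    def test_anchor_points(self):
        cal = vq.HUCalibration(air_mean=10.0, water_mean=200.0)
        raw = vq.Volume(np.array([[[10.0, 200.0], [105.0, 10.0]],
                                  [[200.0, 105.0], [10.0, 200.0]]]),
                        spacing_mm=1.0)
        out = vq.calibrate_hu(raw, cal)
        assert out.data[0, 0, 0] == pytest.approx(-1000.0)
        assert out.data[0, 0, 1] == pytest.approx(0.0)
        # midpoint of the anchors maps to the midpoint of the HU range
        assert out.data[0, 1, 0] == pytest.approx(-500.0)

    @given(air=st.floats(-500, 500), scale=st.floats(0.1, 50),
           offset=st.floats(-100, 100))
    @settings(max_examples=25, deadline=None)
    def test_affine_invariance(self, air, scale, offset):
        """Calibration lands both anchors exactly for any raw scale."""
        water = air + scale * 100
        cal = vq.HUCalibration(air_mean=air, water_mean=water)
        raw = vq.Volume(np.full((2, 2, 2), air), spacing_mm=1.0)
        raw.data[0, 0, 0] = water
        out = vq.calibrate_hu(raw, cal)
        assert out.data[0, 0, 0] == pytest.approx(0.0, abs=1e-6)
        assert out.data[1, 1, 1] == pytest.approx(-1000.0, abs=1e-6)

    def test_equal_anchors_rejected(self):
        with pytest.raises(ValueError):
            vq.HUCalibration(air_mean=5.0, water_mean=5.0)

    def test_requires_ct(self):
        v = vq.Volume(np.zeros((2, 2, 2)), 1.0, modality="SPECT")
        with pytest.raises(ValueError, match="CT"):
            vq.calibrate_hu(v, vq.HUCalibration(0.0, 100.0))


# ---------------------------------------------------------------- smoothing
class TestGaussianSmooth:
    def test_sigma_zero_is_identity(self):
        rng = np.random.default_rng(2)
        v = vq.Volume(rng.normal(size=(5, 5, 5)), 1.0)
        assert np.array_equal(vq.gaussian_smooth(v, 0.0).data, v.data)

    def test_constant_preserved(self):
        v = vq.Volume(np.full((9, 9, 9), 7.0), 1.0)
        assert np.allclose(vq.gaussian_smooth(v, 0.8).data, 7.0)

    def test_impulse_center_matches_kernel_weight(self):
        # independent oracle: separable sampled-Gaussian kernel product
        sigma = 0.8
        radius = int(4.0 * sigma + 0.5)  # default truncation at 4 sigma
        x = np.arange(-radius, radius + 1)
        k1 = np.exp(-x**2 / (2 * sigma**2))
        k1 /= k1.sum()
        expected_center = k1[radius] ** 3
        data = np.zeros((9, 9, 9))
        data[4, 4, 4] = 1.0
        out = vq.gaussian_smooth(vq.Volume(data, 1.0), sigma)
        assert out.data[4, 4, 4] == pytest.approx(expected_center, rel=1e-6)

    def test_negative_sigma_rejected(self):
        with pytest.raises(ValueError):
            vq.gaussian_smooth(vq.Volume(np.zeros((2, 2, 2)), 1.0), -1.0)


# --------------------------------------------------------------- downsample
class TestDownsampleHalf:
    def test_block_mean_and_spacing(self):
        # corner 2x2x2 block holds the values 0..7: its pooled value is 3.5
        data = np.zeros((4, 4, 4))
        data[:2, :2, :2] = np.arange(8, dtype=float).reshape(2, 2, 2)
        v = vq.Volume(data, spacing_mm=0.115)
        out = vq.downsample_half(v)
        assert out.data.shape == (2, 2, 2)
        assert out.data[0, 0, 0] == pytest.approx(3.5)
        assert out.spacing_mm == pytest.approx(0.230)

    def test_constant_volume(self):
        v = vq.Volume(np.full((4, 4, 4), 2.5), 1.0)
        assert np.allclose(vq.downsample_half(v).data, 2.5)

    def test_grid_mean_conserved_exactly(self):
        rng = np.random.default_rng(3)
        v = vq.Volume(rng.normal(size=(8, 6, 4)), 1.0)
        out = vq.downsample_half(v)
        assert out.data.mean() == pytest.approx(v.data.mean(), rel=1e-12)

    def test_odd_dimension_rejected(self):
        with pytest.raises(ValueError, match="even"):
            vq.downsample_half(vq.Volume(np.zeros((3, 4, 4)), 1.0))

    def test_mask_pooling_threshold(self):
        mask = np.zeros((4, 4, 4), bool)
        mask[:2, :2, :2] = True          # one full block -> kept
        mask[2, 2, 2] = True             # 1/8 occupancy -> dropped
        lab = vq.LungLabel(mask, spacing_mm=1.0)
        out = vq.downsample_mask_half(lab)
        assert out.mask[0, 0, 0]
        assert not out.mask[1, 1, 1]


# ----------------------------------------------------------------- resample
class TestResample:
    def test_identity_on_same_grid(self):
        rng = np.random.default_rng(4)
        v = vq.Volume(rng.normal(size=(8, 8, 8)), 0.5)
        out = vq.resample(v, None, v)
        assert np.allclose(out.data[1:-1, 1:-1, 1:-1],
                           v.data[1:-1, 1:-1, 1:-1], atol=1e-10)

    def test_one_voxel_translation_is_exact_shift(self):
        rng = np.random.default_rng(5)
        v = vq.Volume(rng.normal(size=(8, 8, 8)), 0.5)
        t = vq.RigidTransform(tx=0.5)  # exactly one voxel pitch
        out = vq.resample(v, t, v)
        assert np.allclose(out.data[1:, :, :], v.data[:-1, :, :], atol=1e-10)

    def test_spect_counts_conserved_across_grids(self):
        # activity fully inside the field: totals survive a grid change
        rng = np.random.default_rng(6)
        data = np.zeros((16, 16, 16))
        data[5:11, 5:11, 5:11] = rng.uniform(1, 10, (6, 6, 6))
        v = vq.Volume(data, spacing_mm=0.472, origin_mm=(0, 0, 0),
                      modality="SPECT")
        target = Grid((30, 30, 30), 0.236, (0.1, 0.1, 0.1))
        out = vq.resample(v, None, target)
        assert out.data.sum() == pytest.approx(data.sum(), rel=5e-3)

    def test_degenerate_target_rejected(self):
        v = vq.Volume(np.zeros((4, 4, 4)), 1.0)
        with pytest.raises(ValueError, match="degenerate"):
            vq.resample(v, None, Grid((1, 4, 4), 1.0))


# --------------------------------------------------------- rigid transforms
class TestRigidTransform:
    @given(st.lists(st.floats(-2, 2), min_size=6, max_size=6))
    @settings(max_examples=30, deadline=None)
    def test_inverse_composition_is_identity(self, params):
        t = vq.RigidTransform(center_mm=(1.0, -2.0, 0.5)).with_params(params)
        dev = t.compose(t.inverse())
        assert np.allclose(dev.params, 0.0, atol=1e-9)

    def test_matrix_roundtrip(self):
        t = vq.RigidTransform(tx=0.8, ty=-0.5, tz=0.3, rx=2.0, ry=-1.0,
                              rz=1.5, center_mm=(3.0, 1.0, -2.0))
        r = vq.RigidTransform.from_matrix(t.matrix(), center_mm=t.center_mm)
        assert np.allclose(r.params, t.params, atol=1e-10)

    def test_frame_tag_mismatch_rejected(self):
        a = vq.RigidTransform(from_frame="spect", to_frame="perf_ct")
        b = vq.RigidTransform(from_frame="perf_ct", to_frame="vent_ct")
        b.compose(a)  # chains correctly
        with pytest.raises(ValueError, match="compose"):
            a.compose(b)

    def test_apply_points_matches_matrix(self):
        t = vq.RigidTransform(tx=1.0, rx=30.0, center_mm=(0.5, 0.5, 0.5))
        pts = np.array([[1.0, 2.0, 3.0], [0.0, 0.0, 0.0]])
        hom = np.hstack([pts, np.ones((2, 1))])
        expected = (t.matrix() @ hom.T).T[:, :3]
        assert np.allclose(t.apply_points(pts), expected, atol=1e-12)


def test_volume_validation():
    with pytest.raises(ValueError):
        vq.Volume(np.zeros((4, 4)), 1.0)          # not 3D
    with pytest.raises(ValueError):
        vq.Volume(np.zeros((4, 4, 4)), -1.0)      # bad spacing
    with pytest.raises(ValueError):
        vq.Volume(np.zeros((1, 4, 4)), 1.0)       # degenerate axis
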