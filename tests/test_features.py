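import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pction.features import (FeatureSpec, apply_scale, assemble, box_mean,
                             box_mean_volume, box_sd, box_sd_volume,
                             dist_features, scale)
from pction.volio import Volume


def brute_force_box(values, voxel, half_width=1):
    """27-term loop oracle for truncated box mean and population sd."""
    lo = [max(0, voxel[a] - half_width) for a in range(3)]
    hi = [min(values.shape[a], voxel[a] + half_width + 1) for a in range(3)]
    block = values[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]].ravel()
    return block.mean(), block.std()


class TestBoxFeatures:
    def test_constant_volume(self):
        vol = Volume(np.full((5, 5, 5), 4.2))
        assert box_mean(vol, (2, 2, 2)) == pytest.approx(4.2)
        assert box_sd(vol, (2, 2, 2)) == pytest.approx(0.0, abs=1e-9)

    def test_center_of_consecutive_integers(self):
        vol = Volume(np.arange(27, dtype=float).reshape(3, 3, 3))
        assert box_mean(vol, (1, 1, 1)) == pytest.approx(13.0)

    def test_corner_uses_available_eight_voxels(self):
        vol = Volume(np.arange(27, dtype=float).reshape(3, 3, 3))
        expected = vol.values[0:2, 0:2, 0:2].mean()
        assert box_mean(vol, (0, 0, 0)) == pytest.approx(expected)

    def test_box_sd_weighted_by_central_intensity(self):
        vals = np.zeros((3, 3, 3))
        vals[0, 0, 0] = 1.0
        vol = Volume(vals)
        # central voxel holds 0 -> weighted sd vanishes despite box variance
        assert box_sd(vol, (1, 1, 1)) == pytest.approx(0.0)
        assert box_sd(vol, (1, 1, 1), plain=True) > 0

    def test_alternating_box_equals_sd_times_center(self):
        idx = np.indices((3, 3, 3)).sum(axis=0)
        vals = np.where(idx % 2 == 0, 2.0, 0.0)
        vol = Volume(vals)
        _, sd = brute_force_box(vals, (1, 1, 1))
        assert box_sd(vol, (1, 1, 1)) == pytest.approx(vals[1, 1, 1] * sd)

    def test_sliding_equals_brute_force_everywhere(self, rng):
        vals = rng.normal(size=(5, 4, 6))
        vol = Volume(vals)
        bm = box_mean_volume(vol)
        bs = box_sd_volume(vol)
        for voxel in itertools.product(range(5), range(4), range(6)):
            m, s = brute_force_box(vals, voxel)
            assert bm[voxel] == pytest.approx(m, rel=1e-9, abs=1e-12)
            assert bs[voxel] == pytest.approx(s * vals[voxel], rel=1e-9, abs=1e-9)


class TestDistFeatures:
    def make_mask(self):
        vals = np.ones((9, 9, 5), dtype=np.uint8)
        return Volume(vals, spacing=(1.0, 1.0, 2.0), role="mask")

    def test_centroid_voxel_is_origin(self):
        mask = self.make_mask()
        dxyz, dc = dist_features(np.array([[4, 4, 2]]), mask)
        assert np.allclose(dxyz, 0.0)
        assert dc[0] == pytest.approx(0.0)

    def test_three_four_five_triangle(self):
        mask = self.make_mask()
        dxyz, dc = dist_features(np.array([[7, 8, 2]]), mask)  # +3 mm x, +4 mm y
        assert np.allclose(dxyz[0], (3.0, 4.0, 0.0))
        assert dc[0] == pytest.approx(5.0)

    def test_mirror_symmetric_voxels_identical(self):
        mask = self.make_mask()
        a, ca = dist_features(np.array([[2, 6, 1]]), mask)
        b, cb = dist_features(np.array([[6, 2, 3]]), mask)
        assert np.allclose(a, b) and ca[0] == pytest.approx(cb[0])

    def test_invariant_to_constant_origin_shift(self):
        mask = self.make_mask()
        shifted = Volume(mask.values, spacing=mask.spacing,
                         origin=(100.0, -50.0, 7.0), role="mask")
        a, ca = dist_features(np.array([[1, 2, 3]]), mask)
        b, cb = dist_features(np.array([[1, 2, 3]]), shifted)
        assert np.allclose(a, b) and ca[0] == pytest.approx(cb[0])

    def test_empty_mask_raises(self):
        mask = Volume(np.zeros((3, 3, 3), dtype=np.uint8), role="mask")
        with pytest.raises(ValueError, match="empty"):
            dist_features(np.array([[0, 0, 0]]), mask)


def _images(rng, shape=(6, 6, 4)):
    mk = lambda: [Volume(rng.random(shape))]
    return {
        "TSE1": mk(),
        "UTE2": [Volume(rng.random(shape)), Volume(rng.random(shape))],
        "MPRAGE": mk(),
    }


class TestAssemble:
    def test_single_contrast_no_extras_is_one_dimensional(self, rng):
        images = _images(rng)
        mask = Volume(np.ones((6, 6, 4), dtype=np.uint8), role="mask")
        obs = assemble(images, FeatureSpec(contrasts=("TSE1",)), mask)
        assert obs.p == 1 and obs.n == 6 * 6 * 4

    def test_reported_best_combination_is_seven_dimensional(self, rng):
        # TSE1 (1 echo) + UTE2 (2 echoes) with box_sd and dist_center
        images = _images(rng)
        mask = Volume(np.ones((6, 6, 4), dtype=np.uint8), role="mask")
        spec = FeatureSpec(contrasts=("TSE1", "UTE2"), box_sd=True, dist_center=True)
        assert assemble(images, spec, mask).p == 7

    @pytest.mark.parametrize(
        "box_mean_on,box_sd_on,dist_xyz_on,dist_center_on",
        list(itertools.product([False, True], repeat=4)),
    )
    def test_dimensionality_formula_over_toggle_lattice(
        self, rng, box_mean_on, box_sd_on, dist_xyz_on, dist_center_on
    ):
        images = _images(rng)
        mask = Volume(np.ones((6, 6, 4), dtype=np.uint8), role="mask")
        spec = FeatureSpec(contrasts=("TSE1", "UTE2", "MPRAGE"),
                           box_mean=box_mean_on, box_sd=box_sd_on,
                           dist_xyz=dist_xyz_on, dist_center=dist_center_on)
        n_images = 4
        expected = n_images * (1 + box_mean_on + box_sd_on) + 3 * dist_xyz_on + dist_center_on
        obs = assemble(images, spec, mask)
        assert obs.p == expected == len(obs.columns)

    def test_grid_mismatch_raises(self, rng):
        images = _images(rng)
        bad_mask = Volume(np.ones((6, 6, 4), dtype=np.uint8),
                          spacing=(2, 2, 2), role="mask")
        with pytest.raises(ValueError, match="grid"):
            assemble(images, FeatureSpec(contrasts=("TSE1",)), bad_mask)

    def test_rows_follow_mask_voxels(self, rng):
        images = _images(rng)
        vals = np.zeros((6, 6, 4), dtype=np.uint8)
        vals[1, 2, 3] = 1
        vals[4, 0, 1] = 1
        mask = Volume(vals, role="mask")
        obs = assemble(images, FeatureSpec(contrasts=("TSE1",)), mask)
        assert obs.n == 2
        assert obs.X[0, 0] == images["TSE1"][0].values[1, 2, 3]
        assert obs.X[1, 0] == images["TSE1"][0].values[4, 0, 1]


class TestScaling:
    def test_closed_form_three_point_column(self, rng):
        images = {"TSE1": [Volume(np.array([1.0, 2.0, 3.0]).reshape(3, 1, 1))]}
        mask = Volume(np.ones((3, 1, 1), dtype=np.uint8), role="mask")
        obs = assemble(images, FeatureSpec(contrasts=("TSE1",)), mask)
        scaled, params = scale(obs)
        sd = np.std([1, 2, 3])
        assert np.allclose(scaled.X.ravel(), np.array([-1.0, 0.0, 1.0]) / sd)
        assert params.mean[0] == pytest.approx(2.0)

    def test_identity_params_are_identity(self, rng):
        images = _images(rng)
        mask = Volume(np.ones((6, 6, 4), dtype=np.uint8), role="mask")
        obs = assemble(images, FeatureSpec(contrasts=("TSE1",)), mask)
        from pction.features import ScalingParams
        params = ScalingParams(mean=np.zeros(1), sd=np.ones(1), columns=obs.columns)
        assert np.allclose(apply_scale(obs, params).X, obs.X)

    def test_scale_then_apply_consistency(self, rng):
        images = _images(rng)
        mask = Volume(np.ones((6, 6, 4), dtype=np.uint8), role="mask")
        obs = assemble(images, FeatureSpec(contrasts=("TSE1", "UTE2"), box_mean=True), mask)
        scaled, params = scale(obs)
        again = apply_scale(obs, params)
        assert np.allclose(scaled.X, again.X)
        assert np.allclose(scaled.X.mean(axis=0), 0.0, atol=1e-9)
        assert np.allclose(scaled.X.std(axis=0), 1.0, atol=1e-9)

    def test_zero_variance_column_named_in_error(self):
        images = {"TSE1": [Volume(np.full((4, 1, 1), 2.0))]}
        mask = Volume(np.ones((4, 1, 1), dtype=np.uint8), role="mask")
        obs = assemble(images, FeatureSpec(contrasts=("TSE1",)), mask)
        with pytest.raises(ValueError, match="TSE1"):
            scale(obs)


@settings(max_examples=25, deadline=None, derandomize=True)
@given(st.integers(min_value=0, max_value=10**6))
def test_box_features_match_oracle_on_random_small_volumes(seed):
    rng = np.random.default_rng(seed)
    shape = tuple(rng.integers(3, 6, size=3))
    vals = rng.normal(size=shape)
    vol = Volume(vals)
    bm = box_mean_volume(vol)
    bs = box_sd_volume(vol)
    voxel = tuple(rng.integers(0, s) for s in shape)
    m, s = brute_force_box(vals, voxel)
    assert bm[voxel] == pytest.approx(m, rel=1e-9, abs=1e-12)
    assert bs[voxel] == pytest.approx(s * vals[voxel], rel=1e-9, abs=1e-9)
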