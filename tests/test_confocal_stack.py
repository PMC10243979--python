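import dataclasses

import numpy as np
import pytest
import scipy.stats
from hypothesis import given, strategies as st

from xrflabel import (
    ConfocalPhantomConfig,
    ConfocalStack,
    estimate_background,
    log_display,
    make_confocal_phantom,
    particle_features,
    shift_correct,
    threshold_map,
)
from xrflabel.errors import GeometryError, MaskError


def rod_stack(n_planes=4, shape=(40, 40), depth_step=15.0, pixel=5.0,
              angle=45.0, value=100.0):
    """A vertical rod drawn WITH the geometric skew applied."""
    shift = depth_step * np.tan(np.radians(angle)) / pixel
    planes = np.zeros((n_planes, *shape))
    r0, c0 = 10, 20
    for k in range(n_planes):
        row = r0 + shift * k
        low, frac = int(np.floor(row)), row - np.floor(row)
        planes[k, low, c0] = value * (1 - frac)  # anti-aliased sub-pixel rod
        if frac:
            planes[k, low + 1, c0] = value * frac
    return ConfocalStack(planes=planes, depth_step_um=depth_step,
                         geometry_angle_deg=angle, pixel_size_um=pixel)


def rod_centroids(stack):
    out = []
    for plane in stack.planes:
        filled = np.nan_to_num(plane, nan=0.0)
        total = filled.sum()
        rows = np.arange(plane.shape[0], dtype=float)
        out.append((filled.sum(axis=1) * rows).sum() / total)
    return np.array(out)


class TestStackValidation:
    def test_needs_three_dims(self):
        with pytest.raises(ValueError):
            ConfocalStack(planes=np.zeros((4, 4)), depth_step_um=15.0)

    def test_angle_range(self):
        with pytest.raises(ValueError):
            ConfocalStack(planes=np.zeros((2, 4, 4)), depth_step_um=15.0,
                          geometry_angle_deg=90.0)

    def test_45_degree_shift_equals_depth_step(self):
        stack = ConfocalStack(planes=np.zeros((2, 8, 8)), depth_step_um=15.0,
                              geometry_angle_deg=45.0, pixel_size_um=5.0)
        assert stack.shift_px_per_plane() == pytest.approx(3.0)


class TestShiftCorrect:
    def test_zero_step_identity(self):
        planes = np.random.default_rng(0).random((3, 8, 8))
        stack = ConfocalStack(planes=planes, depth_step_um=0.0)
        assert np.array_equal(shift_correct(stack).planes, planes)

    def test_rod_realigned(self):
        corrected = shift_correct(rod_stack())
        centroids = rod_centroids(corrected)
        assert np.abs(centroids - centroids[0]).max() < 0.5

    def test_fractional_shift_realigned(self):
        # 10 um step at 45 deg over 4 um pixels -> 2.5 px per plane
        corrected = shift_correct(rod_stack(depth_step=10.0, pixel=4.0))
        centroids = rod_centroids(corrected)
        assert np.abs(centroids - centroids[0]).max() < 0.5

    def test_inverse_property(self):
        rng = np.random.default_rng(1)
        planes = rng.random((3, 30, 30))
        stack = ConfocalStack(planes=planes, depth_step_um=15.0,
                              pixel_size_um=5.0)
        forth = shift_correct(stack)
        back = shift_correct(dataclasses.replace(forth, shift_sign=-1))
        valid = np.isfinite(back.planes)
        assert np.allclose(back.planes[valid], planes[valid], atol=1e-10)
        # interior is preserved: at most the shifted margin is invalid
        assert valid[1:].mean() > 0.5

    def test_intensity_conserved_in_valid_region(self):
        stack = rod_stack(value=100.0)
        corrected = shift_correct(stack)
        total_in = np.nansum(stack.planes)
        total_out = np.nansum(corrected.planes)
        assert total_out == pytest.approx(total_in, rel=1e-3)

    def test_vacated_margin_invalid_not_zero(self):
        corrected = shift_correct(rod_stack())
        # plane k was pulled back by 3k px: the trailing rows are vacated
        assert np.isnan(corrected.planes[1, -1]).all()
        assert not np.isnan(corrected.planes[0]).any()

    def test_excessive_shift_rejected(self):
        stack = ConfocalStack(planes=np.zeros((10, 8, 8)), depth_step_um=15.0,
                              pixel_size_um=5.0)  # 27 px total shift on 8 rows
        with pytest.raises(GeometryError, match="extent"):
            shift_correct(stack)


class TestEstimateBackground:
    def test_constant_map(self):
        assert estimate_background(np.full((10, 10), 7.5)) == 7.5

    def test_zeros_with_bright_outliers(self):
        image = np.zeros((10, 10))
        image[0, 0] = image[3, 3] = image[7, 7] = 1e4
        assert estimate_background(image) == 0.0

    def test_masked_median_of_off_tissue(self):
        image = np.full((10, 10), 100.0)
        mask = np.zeros((10, 10), dtype=bool)
        mask[:, :5] = True  # tissue on the left
        image[~mask] = 3.0
        assert estimate_background(image, tissue_mask=mask) == 3.0

    def test_empty_off_tissue_rejected(self):
        with pytest.raises(MaskError):
            estimate_background(np.ones((4, 4)),
                                tissue_mask=np.ones((4, 4), dtype=bool))

    def test_phantom_recovery_within_ten_percent(self):
        # high-count phantom: the lowest-quartile median converges on the
        # true baseline (at low counts the Poisson spread biases it down)
        config = ConfocalPhantomConfig(seed=9, background_mean=1000.0)
        stack, truth = make_confocal_phantom(config)
        level = estimate_background(stack.planes[0])
        assert abs(level - truth.background_mean) / truth.background_mean < 0.10


class TestThresholdMap:
    def test_uniform_at_background_nothing_survives(self):
        image = np.full((5, 5), 2.0)
        assert not threshold_map(image, background=2.0, factor=10).any()

    def test_factor_one_everything_survives(self):
        image = np.array([[1.0, 2.0], [3.0, 4.0]])
        out = threshold_map(image, background=1.0, factor=1.0)
        assert np.array_equal(out, image)

    def test_idempotent(self):
        rng = np.random.default_rng(2)
        image = rng.exponential(10.0, (20, 20))
        once = threshold_map(image, background=5.0)
        twice = threshold_map(once, background=5.0)
        assert np.array_equal(once, twice)

    def test_negative_background_rejected(self):
        with pytest.raises(ValueError):
            threshold_map(np.ones((2, 2)), background=-1.0)

    def test_invalid_pixels_stay_invalid(self):
        image = np.array([[np.nan, 100.0], [1.0, 50.0]])
        out = threshold_map(image, background=1.0, factor=10)
        assert np.isnan(out[0, 0]) and out[1, 0] == 0.0 and out[0, 1] == 100.0

    def test_phantom_particles_survive_background_does_not(self):
        config = ConfocalPhantomConfig(seed=4, intensity_multiple=50.0,
                                       background_mean=10.0)
        stack, truth = make_confocal_phantom(config)
        level = truth.background_mean
        survived = [threshold_map(p, level) for p in stack.planes]
        particle_mask = _true_particle_mask(stack, truth)
        survived = np.stack(survived) > 0
        assert survived[particle_mask].all()
        assert survived[~particle_mask].mean() < 0.01


def _true_particle_mask(stack, truth):
    mask = np.zeros(stack.planes.shape, dtype=bool)
    rr, cc = np.ogrid[: stack.planes.shape[1], : stack.planes.shape[2]]
    for particle in truth.particles:
        r0, c0 = particle["center"]
        radius = particle["radius_px"]
        for k in range(particle["start_plane"],
                       particle["start_plane"] + particle["depth_span"]):
            skewed_r = r0 + truth.shift_px_per_plane * k
            mask[k] |= (rr - skewed_r) ** 2 + (cc - c0) ** 2 <= radius ** 2
    return mask


class TestLogDisplay:
    def test_zero_maps_to_zero(self):
        assert log_display(np.zeros((2, 2)))[0, 0] == 0.0

    def test_closed_form(self):
        assert log_display(np.array([999.0]))[0] == pytest.approx(3.0)

    @given(st.floats(0, 1e6), st.floats(0, 1e6))
    def test_order_preserving(self, a, b):
        la, lb = log_display(np.array([a, b]))
        if a < b:
            assert la <= lb
        elif a > b:
            assert la >= lb
        else:
            assert la == lb

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            log_display(np.array([-1.0]))

    def test_nan_stays_nan(self):
        assert np.isnan(log_display(np.array([np.nan, 1.0]))[0])


class TestParticleFeatures:
    @staticmethod
    def make_stack(planes):
        return ConfocalStack(planes=planes, depth_step_um=0.0,
                             pixel_size_um=2.0)

    def test_single_voxel(self):
        planes = np.zeros((3, 5, 5))
        planes[1, 2, 2] = 50.0
        features = particle_features(self.make_stack(planes))
        assert len(features) == 1
        f = features[0]
        assert f.volume_voxels == 1 and f.depth_span_planes == 1
        assert f.extent_um == 2.0  # one voxel at 2 um pixels

    def test_diagonal_voxels_merge_under_26_connectivity(self):
        planes = np.zeros((2, 4, 4))
        planes[0, 0, 0] = planes[1, 1, 1] = 1.0
        features = particle_features(self.make_stack(planes))
        assert len(features) == 1
        assert features[0].depth_span_planes == 2

    def test_separated_particles_counted(self):
        planes = np.zeros((2, 12, 12))
        planes[0, 1:3, 1:3] = 1.0     # volume 4
        planes[:, 8:10, 8:11] = 1.0   # volume 12 across both planes
        features = particle_features(self.make_stack(planes))
        assert sorted(f.volume_voxels for f in features) == [4, 12]

    def test_phantom_feature_count_matches_truth(self):
        config = ConfocalPhantomConfig(seed=6, noise=False)
        stack, truth = make_confocal_phantom(config)
        corrected = shift_correct(stack)
        thresholded = dataclasses.replace(corrected, planes=np.stack([
            threshold_map(p, truth.background_mean)
            for p in corrected.planes]))
        features = particle_features(thresholded)
        assert len(features) == len(truth.particles)
        assert (sorted(f.depth_span_planes for f in features)
                == sorted(p["depth_span"] for p in truth.particles))

    def test_depth_persistence_positive_association(self):
        config = ConfocalPhantomConfig(seed=13, n_particles=20, n_planes=6,
                                       shape=(160, 160), noise=False)
        stack, truth = make_confocal_phantom(config)
        corrected = shift_correct(stack)
        thresholded = dataclasses.replace(corrected, planes=np.stack([
            threshold_map(p, truth.background_mean)
            for p in corrected.planes]))
        features = particle_features(thresholded)
        extents = [f.extent_um for f in features]
        spans = [f.depth_span_planes for f in features]
        rho, _ = scipy.stats.spearmanr(extents, spans)
        assert rho > 0

    def test_plane_reversal_preserves_feature_count(self):
        config = ConfocalPhantomConfig(seed=6, noise=False, depth_step_um=0.0)
        stack, truth = make_confocal_phantom(config)
        thresholded = dataclasses.replace(stack, planes=np.stack([
            threshold_map(p, truth.background_mean) for p in stack.planes]))
        reversed_stack = dataclasses.replace(
            thresholded, planes=thresholded.planes[::-1].copy())
        assert (len(particle_features(thresholded))
                == len(particle_features(reversed_stack)))

    def test_empty_stack_empty_list(self):
        assert particle_features(self.make_stack(np.zeros((2, 4, 4)))) == []
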