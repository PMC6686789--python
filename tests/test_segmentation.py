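import numpy as np
import pytest
from numpy.lib.stride_tricks import sliding_window_view
from skimage.draw import polygon2mask
from skimage.morphology import ball

from ivdquant import (BinaryMask, ContourKeyframe, ContourSet, Volume3D,
                      blended_median_filter, exclude_bone,
                      interpolate_contours, rasterize_to_mask, smooth_mask,
                      suggest_bone_threshold)
from ivdquant.segmentation import read_contours, write_contours

# ---------------------------------------------------------------------------
# independent brute-force oracles


def naive_blended_median(vox, weight, radius):
    """Per-voxel cubic-neighborhood median with replicate borders."""
    p = np.pad(vox, radius, mode="edge")
    w = sliding_window_view(p, (2 * radius + 1,) * 3)
    med = np.median(w.reshape(vox.shape + (-1,)), axis=-1)
    return weight * med + (1.0 - weight) * vox.astype(np.float64)


def naive_erode(m, elem):
    r = elem.shape[0] // 2
    p = np.pad(m, r, constant_values=False)
    w = sliding_window_view(p, elem.shape)
    return (w | ~elem).all(axis=(-3, -2, -1))


def naive_dilate(m, elem):
    r = elem.shape[0] // 2
    p = np.pad(m, r, constant_values=False)
    w = sliding_window_view(p, elem.shape)
    return (w & elem).any(axis=(-3, -2, -1))


def naive_open_close(m, radius):
    elem = ball(radius).astype(bool)
    opened = naive_dilate(naive_erode(m, elem), elem)
    return naive_erode(naive_dilate(opened, elem), elem)


def star_polygon(rng, center, r_lo=3.0, r_hi=12.0, n=8):
    """Random star-shaped (hence simple) polygon around a center.

    Angular gaps are kept below pi (bounded gap ratios), which guarantees
    every edge stays inside its angular wedge and the polygon is simple.
    """
    gaps = rng.uniform(0.6, 1.0, n)
    angles = 2 * np.pi * np.cumsum(gaps) / gaps.sum()
    radii = rng.uniform(r_lo, r_hi, n)
    y = center[0] + radii * np.sin(angles)
    x = center[1] + radii * np.cos(angles)
    return np.stack([y, x], axis=1)


# ---------------------------------------------------------------------------
# blended median filter


class TestBlendedMedianFilter:
    def test_constant_volume_unchanged(self):
        vol = Volume3D(np.full((10, 10, 10), 7, dtype=np.uint16), 10.0)
        out = blended_median_filter(vol, weight=0.8, radius=2)
        assert np.all(out.voxels == 7.0)

    def test_weight_zero_is_identity(self, rng):
        vox = rng.integers(0, 65536, size=(10, 10, 10)).astype(np.uint16)
        out = blended_median_filter(Volume3D(vox, 10.0), weight=0.0, radius=3)
        assert np.array_equal(out.voxels, vox.astype(np.float64))

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        vox = rng.integers(0, 65536, size=(12, 12, 12)).astype(np.uint16)
        out = blended_median_filter(Volume3D(vox, 10.0), weight=0.8, radius=2)
        assert np.array_equal(out.voxels, naive_blended_median(vox, 0.8, 2))

    def test_weight_one_is_pure_median(self, rng):
        vox = rng.integers(0, 65536, size=(9, 9, 9)).astype(np.uint16)
        out = blended_median_filter(Volume3D(vox, 10.0), weight=1.0, radius=1)
        assert np.array_equal(out.voxels, naive_blended_median(vox, 1.0, 1))

    def test_float_volume_fallback_matches_oracle(self, rng):
        vox = rng.normal(3000, 100, size=(8, 8, 8))
        out = blended_median_filter(Volume3D(vox, 10.0), weight=0.5, radius=1)
        np.testing.assert_allclose(out.voxels,
                                   naive_blended_median(vox, 0.5, 1),
                                   rtol=1e-12)

    def test_invalid_parameters_rejected(self, rng):
        vol = Volume3D(np.zeros((5, 5, 5), dtype=np.uint16), 10.0)
        with pytest.raises(ValueError):
            blended_median_filter(vol, weight=1.2, radius=2)
        with pytest.raises(ValueError):
            blended_median_filter(vol, weight=0.5, radius=0)


# ---------------------------------------------------------------------------
# contour interpolation


class TestInterpolateContours:
    SHAPE = (48, 48)

    def test_identical_keyframes_propagate_unchanged(self, rng):
        poly = star_polygon(rng, (24, 24))
        cs = ContourSet([ContourKeyframe(0, poly), ContourKeyframe(10, poly)])
        regions = interpolate_contours(cs, (0, 10), self.SHAPE)
        ref = polygon2mask(self.SHAPE, poly)
        for z in range(11):
            assert np.array_equal(regions[z], ref)

    def test_keyframes_reproduced_exactly(self, rng):
        for _ in range(10):
            p1 = star_polygon(rng, (20, 20))
            p2 = star_polygon(rng, (28, 28))
            cs = ContourSet([ContourKeyframe(2, p1), ContourKeyframe(9, p2)])
            regions = interpolate_contours(cs, (2, 9), self.SHAPE)
            assert np.array_equal(regions[2], polygon2mask(self.SHAPE, p1))
            assert np.array_equal(regions[9], polygon2mask(self.SHAPE, p2))

    def test_concentric_circles_interpolate_radius(self):
        theta = np.linspace(0, 2 * np.pi, 128, endpoint=False)

        def circle(r):
            return np.stack([24 + r * np.sin(theta), 24 + r * np.cos(theta)], 1)

        cs = ContourSet([ContourKeyframe(0, circle(10.0)),
                         ContourKeyframe(10, circle(20.0))])
        mid = interpolate_contours(cs, (5, 5), self.SHAPE)[5]
        r_eq = np.sqrt(mid.sum() / np.pi)
        assert r_eq == pytest.approx(15.0, abs=1.0)

    def test_no_extrapolation(self, rng):
        poly = star_polygon(rng, (24, 24))
        cs = ContourSet([ContourKeyframe(5, poly), ContourKeyframe(10, poly)])
        with pytest.raises(ValueError, match="extrapolat"):
            interpolate_contours(cs, (0, 10), self.SHAPE)

    def test_contour_file_round_trip(self, rng, tmp_path):
        cs = ContourSet([ContourKeyframe(0, star_polygon(rng, (24, 24))),
                         ContourKeyframe(7, star_polygon(rng, (24, 24)))])
        write_contours(cs, tmp_path / "c.json")
        back = read_contours(tmp_path / "c.json")
        assert back.slice_indices == cs.slice_indices
        for a, b in zip(back.keyframes, cs.keyframes):
            np.testing.assert_allclose(a.polygon, b.polygon)

    def test_degenerate_polygons_rejected(self):
        with pytest.raises(ValueError):
            ContourKeyframe(0, [[0, 0], [1, 1]])  # too few vertices
        bowtie = [[0, 0], [10, 10], [0, 10], [10, 0]]
        with pytest.raises(ValueError, match="simple"):
            ContourKeyframe(0, bowtie)
        with pytest.raises(ValueError, match="increase"):
            ContourSet([ContourKeyframe(5, [[0, 0], [0, 5], [5, 0]]),
                        ContourKeyframe(5, [[0, 0], [0, 5], [5, 0]])])


class TestRasterizeToMask:
    def test_popcount_of_square_region(self):
        region = np.zeros((20, 20), dtype=bool)
        region[5:15, 5:15] = True
        mask = rasterize_to_mask({3: region}, (6, 20, 20), 10.0)
        assert mask.count == 100
        assert mask.voxels[3].sum() == 100
        assert mask.voxels[[0, 1, 2, 4, 5]].sum() == 0

    def test_empty_region_set_gives_empty_mask(self):
        assert rasterize_to_mask({}, (4, 4, 4), 10.0).count == 0

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            rasterize_to_mask({0: np.ones((3, 3), bool)}, (4, 4, 4), 10.0)
        with pytest.raises(ValueError):
            rasterize_to_mask({9: np.ones((4, 4), bool)}, (4, 4, 4), 10.0)


# ---------------------------------------------------------------------------
# bone exclusion


class TestExcludeBone:
    def test_threshold_above_max_keeps_roi(self, small_phantom):
        vol, truth = small_phantom
        roi = BinaryMask(truth.disc_mask.voxels | truth.bone_mask.voxels,
                         vol.voxel_size)
        out = exclude_bone(vol, roi, bone_threshold=70000.0)
        assert np.array_equal(out.voxels, roi.voxels)

    def test_midpoint_threshold_separates_constants(self, small_phantom,
                                                    small_spec):
        vol, truth = small_phantom
        roi = BinaryMask(truth.disc_mask.voxels | truth.bone_mask.voxels,
                         vol.voxel_size)
        thr = (small_spec.mu_bone + small_spec.mu_disc_pre) / 2
        out = exclude_bone(vol, roi, thr)
        assert np.array_equal(out.voxels, truth.disc_mask.voxels)

    def test_threshold_below_min_is_error(self, small_phantom):
        vol, truth = small_phantom
        roi = BinaryMask(truth.disc_mask.voxels | truth.bone_mask.voxels,
                         vol.voxel_size)
        with pytest.raises(ValueError, match="removed every"):
            exclude_bone(vol, roi, bone_threshold=0.0)


class TestSuggestBoneThreshold:
    def test_two_constant_modes_separated(self, small_phantom, small_spec):
        vol, truth = small_phantom
        roi = BinaryMask(truth.disc_mask.voxels | truth.bone_mask.voxels,
                         vol.voxel_size)
        thr = suggest_bone_threshold(vol, roi)
        assert small_spec.mu_disc_pre < thr < small_spec.mu_bone

    def test_gaussian_mixture_misclassification_below_1pct(self, rng):
        labels = rng.random((20, 20, 20)) < 0.5
        vox = np.where(labels, rng.normal(8000, 200, labels.shape),
                       rng.normal(3000, 200, labels.shape))
        vol = Volume3D(np.clip(np.rint(vox), 0, 65535).astype(np.uint16), 10.0)
        roi = BinaryMask(np.ones_like(labels), 10.0)
        thr = suggest_bone_threshold(vol, roi)
        misclass = ((vol.voxels >= thr) != labels).mean()
        assert misclass < 0.01

    def test_constant_roi_is_error(self):
        vol = Volume3D(np.full((5, 5, 5), 42, dtype=np.uint16), 10.0)
        roi = BinaryMask(np.ones((5, 5, 5), bool), 10.0)
        with pytest.raises(ValueError, match="constant"):
            suggest_bone_threshold(vol, roi)


# ---------------------------------------------------------------------------
# morphological smoothing


class TestSmoothMask:
    def test_solid_ball_nearly_unchanged(self):
        solid = np.zeros((26, 26, 26), dtype=bool)
        zz, yy, xx = np.mgrid[0:26, 0:26, 0:26]
        solid[(zz - 13) ** 2 + (yy - 13) ** 2 + (xx - 13) ** 2 <= 100] = True
        out = smooth_mask(BinaryMask(solid, 10.0), radius=2)
        # differences confined to the one-voxel discretization shell
        diff = out.voxels ^ solid
        inner = (zz - 13) ** 2 + (yy - 13) ** 2 + (xx - 13) ** 2 <= 81
        assert not (diff & inner).any()

    def test_isolated_speck_removed(self):
        m = np.zeros((11, 11, 11), dtype=bool)
        m[5, 5, 5] = True
        out = smooth_mask(BinaryMask(m, 10.0), radius=2)
        assert out.count == 0

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        m = rng.random((20, 20, 20)) < 0.5
        out = smooth_mask(BinaryMask(m, 10.0), radius=2)
        assert np.array_equal(out.voxels, naive_open_close(m, 2))

    def test_opening_closing_sandwich(self, rng):
        from scipy import ndimage as ndi

        m = rng.random((15, 15, 15)) < 0.6
        elem = ball(2)
        opened = ndi.binary_opening(m, elem)
        closed = ndi.binary_closing(m, elem)
        # anti-extensivity / extensivity of opening and closing (closing
        # checked away from the array border, where the zero boundary
        # condition truncates the dilation)
        assert (opened <= m).all()
        inner = (slice(2, -2),) * 3
        assert (m[inner] <= closed[inner]).all()
        smoothed = smooth_mask(BinaryMask(m, 10.0), radius=2)
        # closing is extensive, so open-then-close contains the opening
        assert (opened <= smoothed.voxels).all()
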