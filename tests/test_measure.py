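import numpy as np
import pytest
from skimage import measure as skmeasure
from skimage.morphology import skeletonize

from internode.io_formats import BACKGROUND, CalibrationProfile, LabeledMask
from internode.measure import (
    MeasureParams,
    SkeletonPath,
    SkeletonTopologyError,
    arc_length_px,
    denoise_mask,
    distort_points,
    extract_internode_mask,
    length_mm,
    measure_seedling,
    order_skeleton,
    undistort,
    undistort_points,
    zhang_suen_thin,
)
from internode.synthetic import make_seedling


def _mask_with(cls_pixels: dict) -> LabeledMask:
    arr = np.full((40, 40), BACKGROUND, dtype=np.uint8)
    for cls, slices in cls_pixels.items():
        arr[slices] = cls
    return LabeledMask(arr)


class TestUndistort:
    def test_zero_coefficients_identity(self, rng):
        calib = CalibrationProfile(fx=100, fy=100, cx=32, cy=32, k=1.0)
        img = rng.integers(0, 256, size=(64, 64), dtype=np.uint8)
        np.testing.assert_array_equal(undistort(img, calib), img)

    def test_size_preserved_and_rgb_supported(self, rng):
        calib = CalibrationProfile(fx=100, fy=100, cx=32, cy=32,
                                   dist_coeffs=(0.05, 0, 0, 0, 0), k=1.0)
        img = rng.integers(0, 256, size=(48, 64, 3), dtype=np.uint8)
        out = undistort(img, calib)
        assert out.shape == img.shape and out.dtype == img.dtype

    def test_point_roundtrip(self):
        calib = CalibrationProfile(fx=120, fy=115, cx=100, cy=90,
                                   dist_coeffs=(0.08, -0.02, 0.001, -0.001, 0.0), k=1.0)
        pts = np.array([[30.0, 40.0], [100.0, 90.0], [160.0, 150.0], [50.0, 140.0]])
        back = undistort_points(distort_points(pts, calib), calib)
        np.testing.assert_allclose(back, pts, atol=1e-6)

    def test_radial_distortion_restores_straight_lines(self):
        # dots rendered at the distorted positions of collinear ideal points
        # become collinear again (within 0.5 px) after undistortion
        calib = CalibrationProfile(fx=100, fy=100, cx=100, cy=100,
                                   dist_coeffs=(0.1, 0, 0, 0, 0), k=1.0)
        ideal = np.array([[x, 40.0] for x in range(30, 180, 15)])
        distorted = distort_points(ideal, calib)
        img = np.zeros((200, 200))
        yy, xx = np.mgrid[0:200, 0:200]
        for dx, dy in distorted:
            img += np.exp(-((xx - dx) ** 2 + (yy - dy) ** 2) / (2 * 2.0**2))
        out = undistort(img, calib)
        # centroid per dot in a window around the ideal location
        ys = []
        for x, y in ideal:
            win = out[int(y) - 6 : int(y) + 7, int(x) - 6 : int(x) + 7]
            wy = np.mgrid[int(y) - 6 : int(y) + 7, 0:13][0]
            ys.append(float((win * wy).sum() / win.sum()))
        assert max(ys) - min(ys) < 0.5  # restored to one horizontal line

    def test_missing_calibration_rejected(self, rng):
        with pytest.raises(ValueError):
            undistort(rng.integers(0, 2, size=(8, 8), dtype=np.uint8), None)


class TestExtractInternodeMask:
    def test_counts_class_one_only(self):
        mask = _mask_with({1: (slice(5, 15), slice(5, 15)), 0: (slice(20, 30), slice(5, 15)),
                           2: (slice(32, 35), slice(5, 8))})
        binary = extract_internode_mask(mask)
        assert int(binary.sum()) == 100
        assert not binary[20:30, 5:15].any()
        assert not binary[32:35, 5:8].any()

    def test_all_background_gives_empty(self):
        binary = extract_internode_mask(_mask_with({}))
        assert not binary.any()


class TestDenoiseMask:
    def test_specks_removed_blob_survives(self, rng):
        binary = np.zeros((80, 80), dtype=bool)
        binary[10:50, 20:45] = True  # 1000 px blob
        speck_rc = [(5, 5), (70, 70), (5, 70), (70, 5), (60, 10)]
        for r, c in speck_rc:
            binary[r : r + 2, c : c + 2] = True
        out = denoise_mask(binary, min_component_px=50, opening_radius=1)
        assert out[30, 30]
        for r, c in speck_rc:
            assert not out[r : r + 2, c : c + 2].any()

    def test_everything_below_min_size_gives_empty(self):
        binary = np.zeros((20, 20), dtype=bool)
        binary[5:8, 5:8] = True
        assert not denoise_mask(binary, min_component_px=50).any()

    @pytest.mark.filterwarnings("ignore:.*components survive.*")
    def test_idempotent(self, rng):
        binary = rng.random((60, 60)) > 0.4
        once = denoise_mask(binary)
        np.testing.assert_array_equal(denoise_mask(once), once)

    def test_keeps_largest_of_multiple_components(self):
        binary = np.zeros((60, 120), dtype=bool)
        binary[10:30, 10:30] = True   # 400 px
        binary[10:40, 60:90] = True   # 900 px
        with pytest.warns(UserWarning, match="largest"):
            out = denoise_mask(binary, min_component_px=50)
        assert out[20, 70] and not out[20, 20]


class TestZhangSuen:
    def test_bar_thins_to_single_pixel_line(self):
        binary = np.zeros((9, 26), dtype=bool)
        binary[3:6, 3:23] = True  # 3 px x 20 px bar
        skel = zhang_suen_thin(binary)
        rows = np.flatnonzero(skel.any(axis=1))
        assert len(rows) == 1  # all skeleton pixels on one row
        # end caps erode by about half the bar width on each side
        n = int(skel.sum())
        assert 16 <= n <= 20

    def test_single_pixel_unchanged(self):
        binary = np.zeros((5, 5), dtype=bool)
        binary[2, 2] = True
        np.testing.assert_array_equal(zhang_suen_thin(binary), binary)

    def test_empty_in_empty_out(self):
        assert not zhang_suen_thin(np.zeros((4, 4), dtype=bool)).any()

    @pytest.mark.parametrize("shape", ["bar", "Y", "ring"])
    def test_connectivity_preserved_and_single_width(self, shape):
        binary = np.zeros((60, 60), dtype=bool)
        if shape == "bar":
            binary[10:14, 5:55] = True
        elif shape == "Y":
            binary[30:55, 28:32] = True  # stem
            for i in range(22):
                binary[30 - i, 28 - i : 32 - i] = True  # up-left arm
                binary[30 - i, 28 + i : 32 + i] = True  # up-right arm
        else:  # ring
            yy, xx = np.mgrid[0:60, 0:60]
            r = np.hypot(yy - 30, xx - 30)
            binary = (r > 14) & (r < 20)
        skel = zhang_suen_thin(binary)
        n_before = skmeasure.label(binary, connectivity=2).max()
        n_after = skmeasure.label(skel, connectivity=2).max()
        assert n_before == n_after == 1
        # single-pixel-wide: no 2x2 block fully set
        two_by_two = skel[:-1, :-1] & skel[1:, :-1] & skel[:-1, 1:] & skel[1:, 1:]
        assert not two_by_two.any()

    def test_agrees_with_skimage_zhang_on_synthetic_stem(self):
        s = make_seedling(length_mm=100.0, curvature=0.05, rng_seed=8)
        binary = s.mask.class_pixels(1)
        ours = zhang_suen_thin(binary)
        reference = skeletonize(binary, method="zhang")
        # same algorithm family: skeletons overlap almost everywhere
        agree = np.sum(ours & reference) / max(np.sum(ours | reference), 1)
        assert agree > 0.8


class TestOrderSkeleton:
    def test_straight_line_path(self):
        skel = np.zeros((40, 40), dtype=bool)
        skel[5:35, 20] = True
        path = order_skeleton(skel)
        assert len(path) == 30
        assert path.pixels[0][0] == 34  # basal end first (largest row)
        assert path.pixels[-1][0] == 5

    def test_branched_skeleton_takes_two_longest_arms(self):
        # arms of 50, 40 and 10 px meeting at one junction: the longest
        # endpoint-to-endpoint geodesic covers 90 pixels, the spur is pruned
        skel = np.zeros((100, 100), dtype=bool)
        skel[40:90, 40] = True                   # 50 px arm (holds the junction)
        skel[0:40, 40] = True                    # 40 px arm, collinear
        spur = [(30 - i, 40 + i) for i in range(1, 11)]  # 10 px diagonal spur
        for r, c in spur:
            skel[r, c] = True
        path = order_skeleton(skel)
        got = set(map(tuple, path.pixels))
        assert got.isdisjoint(spur)
        assert (89, 40) in got and (0, 40) in got
        assert len(path) == 90
        assert tuple(path.pixels[0]) == (89, 40)  # basal end leads

    def test_closed_loop_raises_topology_error(self):
        yy, xx = np.mgrid[0:40, 0:40]
        ring = np.abs(np.hypot(yy - 20, xx - 20) - 12) < 0.6
        with pytest.raises(SkeletonTopologyError):
            order_skeleton(zhang_suen_thin(ring))

    def test_two_components_largest_used_with_warning(self):
        skel = np.zeros((50, 50), dtype=bool)
        skel[5:10, 2] = True   # 5 px
        skel[20:45, 30] = True  # 25 px
        with pytest.warns(UserWarning, match="largest"):
            path = order_skeleton(skel)
        assert len(path) == 25


class TestArcLength:
    def test_horizontal_path_of_11(self):
        path = SkeletonPath(np.array([(5, c) for c in range(10, 21)]))
        assert arc_length_px(path) == pytest.approx(10.0)

    def test_diagonal_path_of_11(self):
        path = SkeletonPath(np.array([(i, i) for i in range(11)]))
        assert arc_length_px(path) == pytest.approx(10 * np.sqrt(2))

    def test_single_pixel_zero(self):
        assert arc_length_px(SkeletonPath(np.array([(3, 3)]))) == 0.0

    def test_matches_pairwise_distance_oracle(self, rng):
        # random monotone 8-connected staircase path
        steps = rng.integers(0, 2, size=(50, 2))
        steps[steps.sum(axis=1) == 0] = (1, 0)
        pix = np.cumsum(np.vstack([[0, 0], steps]), axis=0)
        path = SkeletonPath(pix)
        oracle = sum(
            float(np.linalg.norm(pix[i + 1] - pix[i])) for i in range(len(pix) - 1)
        )
        assert arc_length_px(path) == pytest.approx(oracle, abs=1e-9)


class TestLengthMm:
    def test_eq10_arithmetic(self):
        calib = CalibrationProfile.identity(k=0.5)
        assert length_mm(240.0, calib) == pytest.approx(120.0)
        assert length_mm(0.0, calib) == 0.0

    def test_homogeneous_in_k(self):
        l1 = length_mm(137.0, CalibrationProfile.identity(k=0.3))
        l2 = length_mm(137.0, CalibrationProfile.identity(k=0.6))
        assert l2 == pytest.approx(2 * l1)


class TestMeasureSeedling:
    def test_straight_seedling_recovers_truth_within_3_percent(self, unit_calib):
        s = make_seedling(length_mm=120.0, curvature=0.0, occlusion_fraction=0.0,
                          k_synth=0.5, rng_seed=1)
        res = measure_seedling(s.mask, unit_calib)
        assert res.length_mm == pytest.approx(120.0, abs=3.6)
        assert res.grade == "I"
        assert res.n_skeleton_px > 0

    def test_fully_occluded_gives_flagged_empty_result(self, unit_calib):
        arr = np.full((50, 50), BACKGROUND, dtype=np.uint8)
        arr[10:40, 20:30] = 0  # only leaves, no visible internode
        res = measure_seedling(LabeledMask(arr), unit_calib)
        assert res.length_mm == 0.0
        assert res.grade == "OUT"
        assert "empty_mask" in res.flags

    def test_monotone_non_increasing_under_occlusion(self, unit_calib):
        lengths = []
        for f in (0.0, 0.05, 0.1, 0.2, 0.3):
            s = make_seedling(length_mm=140.0, curvature=0.05,
                              occlusion_fraction=f, rng_seed=17)
            lengths.append(measure_seedling(s.mask, unit_calib).length_mm)
        assert all(a >= b for a, b in zip(lengths, lengths[1:]))

    def test_median_recovery_error_under_3_percent_batch(self, unit_calib):
        # seeded batch spanning the full length range, unoccluded
        rng = np.random.default_rng(99)
        errs = []
        for _ in range(50):
            target = float(rng.uniform(80, 180))
            s = make_seedling(length_mm=target,
                              curvature=float(rng.uniform(0.01, 0.08)),
                              k_synth=0.5, rng_seed=int(rng.integers(2**31)))
            res = measure_seedling(s.mask, unit_calib)
            errs.append(abs(res.length_mm - s.true_length_mm) / s.true_length_mm)
        assert float(np.median(errs)) <= 0.03
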