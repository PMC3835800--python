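"""Thinning and cross-point-number junction detection."""

import numpy as np
import pytest

from gridstereo import preprocess
from gridstereo.errors import ConfigError
from gridstereo.features import (
    MCN_RING,
    SCN_RING,
    IntersectionSet,
    cpn_mcn,
    cpn_scn,
    detect_intersections,
    score_detection,
    thin,
)


def brute_force_transitions(ring_vals):
    """Independent oracle: walk the closed ring, count 0/1 changes, halve."""
    total = 0
    n = len(ring_vals)
    for i in range(n):
        total += abs(int(ring_vals[i]) - int(ring_vals[(i + 1) % n]))
    return total / 2.0


def _skeleton_with_ring(ring, ring_vals, center=True):
    pad = max(abs(d) for off in ring for d in off)
    size = 2 * pad + 3
    img = np.zeros((size, size), dtype=bool)
    c = size // 2
    img[c, c] = center
    for (dy, dx), v in zip(ring, ring_vals):
        img[c + dy, c + dx] = bool(v)
    return img, (c, c)


class TestThin:
    def test_thick_bar_becomes_unit_width_line(self):
        img = np.zeros((20, 30), dtype=bool)
        img[8:13, 2:28] = True
        skel = thin(img)
        # one pixel per column over the bar's interior
        assert all(skel[:, x].sum() == 1 for x in range(4, 26))

    def test_no_interior_3x3_block_survives(self, noise_free_render):
        left, _, _ = noise_free_render
        binary = preprocess.to_gray_inverted(left) > 150
        skel = thin(binary)
        from scipy.ndimage import minimum_filter

        solid = minimum_filter(skel.astype(np.uint8), size=3, mode="constant") == 1
        assert not solid.any()

    def test_plus_cross_has_single_4_degree_junction(self):
        img = np.zeros((31, 31), dtype=bool)
        img[13:18, :] = True
        img[:, 13:18] = True
        skel = thin(img)
        from scipy.ndimage import convolve

        deg = convolve(skel.astype(int), np.ones((3, 3), dtype=int), mode="constant")
        deg = (deg - 1) * skel
        assert (deg >= 4).sum() >= 1  # a junction pixel region exists
        # and it is unique up to 8-connectivity
        from scipy.ndimage import label

        assert label(deg >= 4, structure=np.ones((3, 3)))[1] == 1

    def test_unit_width_line_unchanged(self):
        img = np.zeros((10, 20), dtype=bool)
        img[5, 2:18] = True
        assert np.array_equal(thin(img), img)

    def test_preserves_component_count(self, noise_free_render):
        from scipy.ndimage import label

        left, _, _ = noise_free_render
        binary = preprocess.to_gray_inverted(left) > 150
        eight = np.ones((3, 3), dtype=int)
        assert label(thin(binary), eight)[1] == label(binary, eight)[1]


class TestCpnOperators:
    def test_ideal_cross_scores_four(self):
        ring_vals = [1, 0, 1, 0, 1, 0, 1, 0]  # 4-connected cross neighborhood
        img, px = _skeleton_with_ring(SCN_RING, ring_vals)
        assert cpn_scn(img, px) == 4.0

    def test_straight_line_scores_two(self):
        ring_vals = [1, 0, 0, 0, 1, 0, 0, 0]  # two opposite ring pixels
        img, px = _skeleton_with_ring(SCN_RING, ring_vals)
        assert cpn_scn(img, px) == 2.0

    def test_empty_ring_scores_zero(self):
        img, px = _skeleton_with_ring(SCN_RING, [0] * 8)
        assert cpn_scn(img, px) == 0.0

    def test_mcn_cross_scores_four(self):
        # four isolated foreground runs on the 5x5 perimeter
        vals = [0] * 16
        for i in (0, 4, 8, 12):
            vals[i] = 1
        img, px = _skeleton_with_ring(MCN_RING, vals)
        assert cpn_mcn(img, px) == 4.0

    def test_mcn_straight_line_scores_two(self):
        vals = [0] * 16
        vals[0] = vals[8] = 1
        img, px = _skeleton_with_ring(MCN_RING, vals)
        assert cpn_mcn(img, px) == 2.0

    def test_scn_matches_brute_force_for_all_256_rings(self):
        # exhaustive oracle over every possible 3x3 ring configuration
        for code in range(256):
            vals = [(code >> i) & 1 for i in range(8)]
            img, px = _skeleton_with_ring(SCN_RING, vals)
            assert cpn_scn(img, px) == brute_force_transitions(vals)

    def test_mcn_matches_brute_force_for_random_perimeters(self, rng):
        for _ in range(5000):
            vals = rng.integers(0, 2, size=16)
            img, px = _skeleton_with_ring(MCN_RING, vals)
            assert cpn_mcn(img, px) == brute_force_transitions(vals)

    def test_cpn_invariant_to_ring_start(self, rng):
        # the transition count is a cyclic invariant: any rotation of the
        # ring ordering gives the same value
        for _ in range(100):
            vals = list(rng.integers(0, 2, size=8))
            base = brute_force_transitions(vals)
            for shift in range(1, 8):
                rotated = vals[shift:] + vals[:shift]
                assert brute_force_transitions(rotated) == base

    def test_border_pixel_raises(self):
        img = np.zeros((7, 7), dtype=bool)
        with pytest.raises(ConfigError):
            cpn_scn(img, (0, 3))
        with pytest.raises(ConfigError):
            cpn_mcn(img, (1, 3))


class TestDetectIntersections:
    def test_clean_grid_yields_77_centroids_near_truth(self, noise_free_render):
        left, _, truth = noise_free_render
        corrected = preprocess.intensity_correct(preprocess.to_gray_inverted(left))
        roi = preprocess.detect_roi(corrected, threshold_method="background")
        binary = preprocess.binarize(corrected, "background", mask=roi.mask)
        skel = thin(preprocess.clean_binary(binary, 1, min_size=25, max_hole=100))
        det = detect_intersections(skel, threshold=3.0, image=corrected)
        assert len(det) == 77
        d = np.linalg.norm(
            det.points[:, None, :] - truth.left2d[None, :, :], axis=-1
        ).min(axis=1)
        assert d.max() < 1.5

    def test_single_line_yields_no_junctions(self):
        img = np.zeros((20, 40), dtype=bool)
        img[10, 2:38] = True
        assert len(detect_intersections(img, 3.0)) == 0

    def test_detection_monotone_in_threshold(self, noisy_render):
        left, _, _ = noisy_render
        corrected = preprocess.intensity_correct(preprocess.to_gray_inverted(left))
        roi = preprocess.detect_roi(corrected, threshold_method="background")
        binary = preprocess.binarize(corrected, "background", mask=roi.mask)
        skel = thin(preprocess.clean_binary(binary, 1, min_size=25, max_hole=100))
        counts = [len(detect_intersections(skel, t, refine=False))
                  for t in (3.0, 3.5, 4.0)]
        assert counts[0] >= counts[1] >= counts[2]

    def test_threshold_outside_range_raises(self):
        with pytest.raises(ConfigError):
            detect_intersections(np.zeros((10, 10), dtype=bool), threshold=2.5)

    def test_serialization_round_trip(self, tmp_path):
        det = IntersectionSet(
            points=np.array([[1.25, 2.5], [10.0, 20.0]]),
            scn=np.array([3.0, 4.0]),
            mcn=np.array([3.5, 4.0]),
        )
        path = tmp_path / "pts.txt"
        det.save(path)
        back = IntersectionSet.load(path)
        assert np.allclose(back.points, det.points)
        assert np.allclose(back.scn, det.scn)


class TestScoreDetection:
    def test_perfect_detection(self):
        truth = np.array([[5.0, 5.0], [20.0, 5.0]])
        s = score_detection(truth.copy(), truth, 3.0)
        assert s.sensitivity == 1.0 and s.fpp == 0 and s.fnp == 0

    def test_partial_detection_matches_expected_counts(self, rng):
        # 73 of 77 found, none spurious: sensitivity 73/77, FNP 4
        truth = rng.uniform(0, 400, size=(77, 2))
        detected = truth[:73] + rng.normal(0, 0.3, size=(73, 2))
        s = score_detection(detected, truth, 3.0)
        assert s.n_correct == 73
        assert s.fpp == 0 and s.fnp == 4
        assert abs(s.sensitivity - 0.9481) < 5e-4

    def test_empty_detection(self):
        truth = np.array([[5.0, 5.0], [20.0, 5.0]])
        s = score_detection(np.zeros((0, 2)), truth, 3.0)
        assert s.sensitivity == 0.0 and s.fnp == 2

    def test_one_to_one_matching(self):
        # two detections near one truth: only one may match
        truth = np.array([[10.0, 10.0]])
        det = np.array([[10.2, 10.0], [9.8, 10.0]])
        s = score_detection(det, truth, 3.0)
        assert s.n_correct == 1 and s.fpp == 1
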