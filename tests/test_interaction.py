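"""Interaction-map machinery: fits, crops, circular statistics, region ratios."""

import numpy as np
import pytest

from sdpc import gabor_patch
from sdpc.interaction import (InteractionMap, circular_average,
                              cocircular_reference, cocircularity_deviation,
                              colinearity_deviation, extract_top_neighborhoods,
                              feedback_ratios, fit_gabor, marginal_activity,
                              normalized_activity, region_masks)


class TestFitGabor:
    def test_planted_orientation_recovered(self):
        patch = gabor_patch(11, np.radians(30), 0.18, sigma=2.5)
        theta, quality = fit_gabor(patch)
        assert np.degrees(abs(np.angle(np.exp(2j * (theta - np.radians(30)))))) / 2 <= 3
        assert quality >= 0.9

    def test_isotropic_blob_scores_below_threshold(self):
        xs = np.arange(11) - 5
        X, Y = np.meshgrid(xs, xs, indexing="ij")
        blob = np.exp(-(X ** 2 + Y ** 2) / 8.0)
        _, quality = fit_gabor(blob)
        assert quality < 0.5

    def test_90_degree_rotation_equivariance(self):
        base = gabor_patch(11, np.radians(20), 0.18, sigma=2.5)
        rotated = np.rot90(base)
        t0, _ = fit_gabor(base)
        t1, _ = fit_gabor(rotated)
        shift = np.degrees(abs(np.angle(np.exp(2j * (t1 - t0 - np.pi / 2))))) / 2
        assert shift <= 3


class TestExtractTopNeighborhoods:
    def test_single_nonzero_entry_centered(self):
        act = np.zeros((2, 11, 11))
        act[1, 5, 6] = 3.0
        crops, centers = extract_top_neighborhoods(act, 1, k=1, window=5)
        assert centers == [(5, 6)]
        assert crops[0].shape == (2, 5, 5)
        assert crops[0][1, 2, 2] == 3.0

    def test_equal_maxima_tie_break_by_scan_order(self):
        act = np.zeros((1, 11, 11))
        act[0, 3, 7] = 1.0
        act[0, 3, 4] = 1.0
        _, centers = extract_top_neighborhoods(act, 0, k=2, window=3)
        assert centers == [(3, 4), (3, 7)]

    def test_matches_full_sort_oracle(self, rng):
        act = rng.random((3, 15, 15))
        _, centers = extract_top_neighborhoods(act, 2, k=10, window=5)
        plane = act[2]
        order = np.argsort(plane, axis=None)[::-1]
        expected = []
        for flat in order:
            x, y = np.unravel_index(flat, plane.shape)
            if 2 <= x < 13 and 2 <= y < 13:
                expected.append((int(x), int(y)))
            if len(expected) == 10:
                break
        assert centers == expected

    def test_border_peaks_skipped_and_replaced(self):
        act = np.zeros((1, 9, 9))
        act[0, 0, 0] = 5.0  # too close to the border for a 5-window
        act[0, 4, 4] = 1.0
        _, centers = extract_top_neighborhoods(act, 0, k=1, window=5)
        assert centers == [(4, 4)]


class TestMarginalActivity:
    def test_uniform_plane_returns_value(self):
        act = np.full((1, 11, 11), 0.7)
        assert marginal_activity(act, 0, (5, 5), 5) == pytest.approx(0.7)

    def test_activity_only_inside_window_gives_zero(self):
        act = np.zeros((1, 11, 11))
        act[0, 5, 5] = 9.0
        assert marginal_activity(act, 0, (5, 5), 5) == 0.0

    def test_matches_mask_and_mean_oracle(self, rng):
        act = rng.random((2, 12, 12))
        got = marginal_activity(act, 1, (6, 5), 5)
        mask = np.ones((12, 12), dtype=bool)
        mask[4:9, 3:8] = False
        assert got == pytest.approx(act[1][mask].mean())

    def test_window_covering_map_rejected(self):
        with pytest.raises(ValueError):
            marginal_activity(np.ones((1, 5, 5)), 0, (2, 2), 11)


class TestNormalizedActivity:
    def test_crop_equal_to_marginal_is_zero(self):
        crop = np.full((2, 3, 3), 0.4)
        out = normalized_activity(crop, np.array([0.4, 0.4]))
        assert np.allclose(out, 0.0)

    def test_double_the_marginal_is_one(self):
        crop = np.full((2, 3, 3), 0.8)
        out = normalized_activity(crop, np.array([0.4, 0.4]))
        assert np.allclose(out, 1.0)

    def test_matches_direct_formula(self, rng):
        crop = rng.random((3, 5, 5))
        marg = rng.random(3) + 0.1
        out = normalized_activity(crop, marg)
        want = (crop - marg[:, None, None]) / marg[:, None, None]
        assert np.allclose(out, want)

    def test_zero_marginal_without_floor_raises(self):
        with pytest.raises(ZeroDivisionError):
            normalized_activity(np.ones((1, 3, 3)), np.array([0.0]), floor=0)


class TestCircularAverage:
    def test_single_term(self):
        crop = np.zeros((2, 3, 3))
        crop[0, 1, 1] = 1.0
        field = circular_average([crop], np.radians([30.0, 120.0]))
        assert np.angle(field[1, 1]) == pytest.approx(np.radians(30))
        assert abs(field[1, 1]) == pytest.approx(0.5)  # 1/n with n = 2

    def test_opposite_angles_cancel_to_real_axis(self):
        crop = np.ones((2, 1, 1))
        field = circular_average([crop], np.array([0.4, -0.4]))
        assert np.angle(field[0, 0]) == pytest.approx(0.0, abs=1e-12)

    def test_two_orthogonal_terms(self):
        a = 0.8
        crop = np.full((2, 1, 1), a)
        field = circular_average([crop], np.radians([0.0, 90.0]))
        assert np.angle(field[0, 0]) == pytest.approx(np.radians(45))
        assert abs(field[0, 0]) == pytest.approx(a * np.sqrt(2) / 2)

    def test_matches_bruteforce_complex_sum(self, rng):
        crops = rng.standard_normal((4, 5, 3, 3))
        thetas = rng.uniform(0, np.pi, 5)
        field = circular_average(crops, thetas)
        want = np.zeros((3, 3), dtype=complex)
        for c in crops:
            acc = np.zeros((3, 3), dtype=complex)
            for f, th in enumerate(thetas):
                acc += c[f] * np.exp(1j * th)
            want += acc / len(thetas)
        want /= len(crops)
        assert np.allclose(field, want, atol=1e-9)

    def test_permutation_invariance(self, rng):
        crops = rng.standard_normal((6, 4, 3, 3))
        thetas = rng.uniform(0, np.pi, 4)
        perm = rng.permutation(6)
        a = circular_average(crops, thetas)
        b = circular_average(crops[perm], thetas)
        assert np.allclose(a, b, atol=1e-12)

    def test_empty_feature_set_rejected(self):
        with pytest.raises(ValueError):
            circular_average(np.zeros((1, 0, 3, 3)), np.array([]))


class TestDeviations:
    def test_colinear_map_has_zero_deviation(self):
        theta_c = np.radians(30)
        field = np.full((5, 5), theta_c)
        assert np.allclose(colinearity_deviation(field, theta_c), 0.0)

    def test_orthogonal_map_deviates_by_half_pi(self):
        theta_c = np.radians(30)
        field = np.full((5, 5), theta_c + np.pi / 2)
        assert np.allclose(colinearity_deviation(field, theta_c), np.pi / 2)

    def test_period_pi_wrap(self):
        theta_c = 0.3
        field = np.full((3, 3), theta_c + np.pi)
        assert np.allclose(colinearity_deviation(field, theta_c), 0.0, atol=1e-9)

    def test_on_axis_cocircular_reference_is_colinear(self):
        ref = cocircular_reference(9, 0.0)
        # theta_c = 0 axis: the x-axis row through the centre (Y = 0)
        assert np.allclose(ref[:, 4], 0.0, atol=1e-9)

    def test_reference_map_deviates_zero_from_itself(self):
        ref = cocircular_reference(9, np.radians(40))
        assert np.allclose(cocircularity_deviation(ref, np.radians(40)), 0.0,
                           atol=1e-9)

    def test_reference_matches_independent_geometry(self):
        """Circle through centre tangent to theta_c: tangent angles at each cell."""
        theta_c = 0.0
        ref = cocircular_reference(9, theta_c)
        for x in range(9):
            for y in range(9):
                X, Y = x - 4, y - 4
                if Y == 0:  # on the axis: co-linear limit
                    want = 0.0
                else:
                    # centre on the normal at t*(-sin, cos) = (0, t);
                    # equidistance gives t = (X^2+Y^2)/(2Y)
                    t = (X ** 2 + Y ** 2) / (2.0 * Y)
                    radius = np.array([X - 0.0, Y - t])
                    tangent = np.arctan2(radius[0], -radius[1])  # perpendicular
                    want = np.mod(tangent, np.pi)
                d = abs(np.angle(np.exp(2j * (ref[x, y] - want)))) / 2
                assert d <= 1e-9


class TestRegionMasks:
    def test_theta_zero_end_zone_symmetric_under_flip(self):
        masks = region_masks(9, 0.0)
        assert np.array_equal(masks["end"], masks["end"][::-1, :])
        assert np.array_equal(masks["end"], masks["end"][:, ::-1])

    def test_rotating_by_90_swaps_end_and_side(self):
        a = region_masks(9, 0.0)
        b = region_masks(9, np.pi / 2)
        assert np.array_equal(a["end"], b["side"])
        assert np.array_equal(a["side"], b["end"])

    def test_masks_disjoint_and_exclude_center(self):
        for theta in np.radians([0, 22.5, 45, 80]):
            masks = region_masks(9, theta, center_block=3)
            total = (masks["end"].astype(int) + masks["side"].astype(int)
                     + masks["center"].astype(int))
            assert total.max() <= 1
            assert masks["center"].sum() == 9


class TestFeedbackRatios:
    @staticmethod
    def _map_from(field, theta_c, k_fb):
        return InteractionMap(complex_field=field, theta_c=theta_c,
                              feedback_strength=k_fb)

    def test_identical_maps_give_unit_ratios(self, rng):
        field = rng.standard_normal((9, 9)) + 1j * rng.standard_normal((9, 9))
        m0 = self._map_from(field, 0.5, 0.0)
        m1 = self._map_from(field.copy(), 0.5, 1.0)
        r = feedback_ratios(m1, m0)
        for d in (r.r_colin, r.r_cocir, r.r_a):
            for v in d.values():
                assert v == pytest.approx(1.0)

    def test_doubled_magnitude_doubles_activity_ratio(self, rng):
        field = rng.standard_normal((9, 9)) + 1j * rng.standard_normal((9, 9))
        m0 = self._map_from(field, 0.5, 0.0)
        m1 = self._map_from(2.0 * field, 0.5, 1.0)
        r = feedback_ratios(m1, m0)
        for v in r.r_a.values():
            assert v == pytest.approx(2.0)

    def test_planted_end_zone_boost_detected(self, rng):
        field = np.full((9, 9), 1.0 + 0.0j)
        boosted = field.copy()
        masks = region_masks(9, 0.0)
        boosted[masks["end"]] *= 3.0
        m0 = self._map_from(field, 0.0, 0.0)
        m1 = self._map_from(boosted, 0.0, 1.0)
        r = feedback_ratios(m1, m0)
        assert r.r_a["end"] == pytest.approx(3.0)
        assert r.r_a["side"] == pytest.approx(1.0)
        assert r.r_a["center"] == pytest.approx(1.0)

    def test_mismatched_maps_rejected(self, rng):
        f = rng.standard_normal((9, 9)) + 0j
        with pytest.raises(ValueError):
            feedback_ratios(self._map_from(f, 0.1, 1.0),
                            self._map_from(f, 0.9, 0.0))
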