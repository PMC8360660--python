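"""Bouton counting near dendrites and effective-range estimation."""

import numpy as np
import pytest

from ngfc.errors import ConfigurationError, GeometryError, StatisticsError
from ngfc.morphology import AxonMorphology
from ngfc.transmission_range import (
    BoutonCountCurve,
    correlation_vs_radius,
    count_boutons_near_dendrite,
    estimate_range,
    point_polyline_distance,
)


def morph_with_boutons(xyz):
    xyz = np.asarray(xyz, dtype=float).reshape(-1, 3)
    return AxonMorphology(soma=[0, 0, 0], nodes=[[0, 0, 0]], parents=[-1],
                          bouton_xyz=xyz)


STRAIGHT = [np.array([[0.0, 0.0, 0.0], [10.0, 0.0, 0.0]])]


class TestCountBoutons:
    def test_boundary_is_inclusive(self):
        m = morph_with_boutons([[5.0, 1.0, 0.0]])  # exactly 1.0 µm away
        c = count_boutons_near_dendrite(m, STRAIGHT, radii=[0.9, 1.0, 1.5])
        assert list(c.counts) == [0, 1, 1]

    def test_curve_is_nondecreasing(self, rng):
        m = morph_with_boutons(rng.normal(scale=2.0, size=(30, 3)) + [5, 0, 0])
        c = count_boutons_near_dendrite(m, STRAIGHT, radii=np.arange(0.25, 5.0, 0.25))
        assert np.all(np.diff(c.counts) >= 0)

    def test_distances_match_dense_sampling_oracle(self, rng):
        pts = rng.normal(scale=3.0, size=(20, 3)) + [5, 0, 0]
        d = point_polyline_distance(pts, STRAIGHT)
        # oracle: minimal distance over densely sampled polyline points
        t = np.linspace(0, 1, 20001)
        dense = STRAIGHT[0][0] + t[:, None] * (STRAIGHT[0][1] - STRAIGHT[0][0])
        d_o = np.min(np.linalg.norm(pts[:, None, :] - dense[None], axis=2), axis=1)
        assert np.allclose(d, d_o, atol=1e-5)

    def test_counts_match_brute_force(self, rng):
        pts = rng.normal(scale=2.0, size=(20, 3)) + [5, 0, 0]
        m = morph_with_boutons(pts)
        radii = np.arange(0.5, 4.01, 0.5)
        c = count_boutons_near_dendrite(m, STRAIGHT, radii=radii)
        d = point_polyline_distance(pts, STRAIGHT)
        expected = [(d <= r).sum() for r in radii]
        assert list(c.counts) == expected

    def test_empty_dendrite_rejected(self):
        with pytest.raises(GeometryError):
            count_boutons_near_dendrite(morph_with_boutons([[0, 0, 0]]), [])

    def test_dendrite_radius_shifts_distances(self):
        m = morph_with_boutons([[5.0, 1.0, 0.0]])
        c = count_boutons_near_dendrite(m, STRAIGHT, radii=[0.4, 0.5, 1.0],
                                        dendrite_radius=0.5)
        assert list(c.counts) == [0, 1, 1]


class TestEstimateRange:
    def linear_curve(self, slope=10.0):
        r = np.arange(0.1, 2.01, 0.1)
        return BoutonCountCurve(radii=r, counts=slope * r)

    def test_exact_inversion_of_linear_curve(self):
        est = estimate_range(5.0, 0.0, [self.linear_curve()])
        assert est.lower == pytest.approx(0.5, abs=1e-9)
        assert est.upper == pytest.approx(0.5, abs=1e-9)

    def test_below_minimum_collapses_and_flags(self):
        est = estimate_range(0.5, 0.0, [self.linear_curve()])
        assert est.lower == pytest.approx(0.1)
        assert est.flags[0][0] == "below_min"

    def test_above_maximum_flags_open_bound(self):
        est = estimate_range(100.0, 0.0, [self.linear_curve()])
        assert est.flags[0][1] == "above_max"
        assert est.upper == pytest.approx(2.0)

    def test_wider_nfrs_sd_gives_nested_wider_interval(self):
        narrow = estimate_range(10.0, 1.0, [self.linear_curve()])
        wide = estimate_range(10.0, 5.0, [self.linear_curve()])
        assert wide.lower <= narrow.lower
        assert wide.upper >= narrow.upper

    def test_generative_self_consistency(self, rng):
        # boutons inside a known radius r* equal the functional site count:
        # the inverted interval must contain r*
        r_star = 1.2
        curves = []
        for _ in range(4):
            pts = rng.normal(scale=1.5, size=(60, 3)) + [5, 0, 0]
            m = morph_with_boutons(pts)
            c = count_boutons_near_dendrite(m, STRAIGHT,
                                            radii=np.arange(0.25, 3.01, 0.25))
            curves.append(c)
        nfrs = [float(np.interp(r_star, c.radii, c.counts)) for c in curves]
        est = estimate_range(float(np.mean(nfrs)), float(np.std(nfrs)), curves)
        assert est.lower - 0.25 <= r_star <= est.upper + 0.25


class TestCorrelationVsRadius:
    def test_proportional_counts_give_perfect_correlation(self):
        nfrs = np.array([3.0, 7.0, 11.0, 15.0])
        counts = np.column_stack([
            np.ones(4),            # constant -> skipped
            2.0 * nfrs,            # perfectly correlated
            np.array([5.0, 2.0, 8.0, 1.0]),
        ])
        with pytest.warns(UserWarning):
            r, p, best = correlation_vs_radius(nfrs, counts, radii=[0.5, 1.0, 1.5])
        assert np.isnan(r[0])
        assert r[1] == pytest.approx(1.0)
        assert best == 1.0

    def test_permutation_null_gives_small_correlations(self, rng):
        n = 200
        nfrs = rng.normal(10, 3, n)
        counts = rng.normal(20, 5, size=(n, 4))
        r, _, _ = correlation_vs_radius(nfrs, counts)
        assert np.all(np.abs(r) < 0.2)

    def test_three_pair_hand_case(self):
        nfrs = np.array([1.0, 2.0, 4.0])
        col = np.array([2.0, 3.0, 7.0])
        r, _, _ = correlation_vs_radius(nfrs, col[:, None])
        expected = np.corrcoef(nfrs, col)[0, 1]
        assert r[0] == pytest.approx(expected)

    def test_too_few_pairs_rejected(self):
        with pytest.raises(StatisticsError):
            correlation_vs_radius([1.0, 2.0], np.ones((2, 3)))
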