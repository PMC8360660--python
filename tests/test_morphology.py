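"""Sholl analysis, axon growth, bouton placement, K-S calibration."""

import math

import numpy as np
import pytest

from ngfc.errors import CalibrationError, StatisticsError
from ngfc.morphology import (
    AxonMorphology,
    GrowthParams,
    ShollProfile,
    calibrate_growth,
    grow_axon,
    ks_two_sample,
    place_boutons,
    sholl_analysis,
)

SMALL = GrowthParams(total_length_mean=1500.0, total_length_sd=300.0,
                     n_branch_mean=15.0, n_branch_sd=4.0)


def straight_segment(length):
    return AxonMorphology(soma=[0, 0, 0], nodes=[[0, 0, 0], [length, 0, 0]],
                          parents=[-1, 0])


class TestSholl:
    def test_straight_segment_partitions_exactly(self):
        prof = sholl_analysis(straight_segment(25.0), shell_step=10.0)
        assert np.allclose(prof.lengths, [10.0, 10.0, 5.0], atol=0.3)

    def test_empty_morphology_gives_zero_profile(self):
        m = AxonMorphology(soma=[0, 0, 0], nodes=[[0, 0, 0]], parents=[-1])
        prof = sholl_analysis(m)
        assert prof.total_length == 0.0

    def test_partition_conserves_total_cable_length(self):
        m = grow_axon(SMALL, seed=5)
        prof = sholl_analysis(m, shell_step=10.0)
        assert prof.total_length == pytest.approx(m.total_length(), rel=0.005)

    def test_profile_sampling_respects_support(self, rng):
        prof = ShollProfile(shell_step=10.0, lengths=[0.0, 5.0, 0.0])
        s = prof.sample(500, rng)
        assert np.all((s >= 10.0) & (s < 20.0))


class TestGrowAxon:
    def test_unbranched_growth_is_a_single_path(self):
        p = GrowthParams(total_length_mean=100.0, total_length_sd=0.0,
                         n_branch_mean=0.0, n_branch_sd=0.0,
                         polar_mean_deg=0.0, polar_sd_deg=0.0)
        m = grow_axon(p, seed=0)
        assert m.total_length() == pytest.approx(100.0, abs=1.0)
        assert m.n_branch_points() == 0
        # straight line: extent equals cable length
        ext = np.linalg.norm(m.nodes - m.soma, axis=1).max()
        assert ext == pytest.approx(100.0, abs=1.0)

    def test_seed_determinism(self):
        a = grow_axon(SMALL, seed=11)
        b = grow_axon(SMALL, seed=11)
        assert np.array_equal(a.nodes, b.nodes)

    def test_realized_total_length_distribution(self):
        total = [grow_axon(SMALL, seed=s).total_length() for s in range(200)]
        se = SMALL.total_length_sd / math.sqrt(len(total))
        assert abs(np.mean(total) - SMALL.total_length_mean) < 3.5 * se

    def test_branch_count_tracks_configuration(self):
        p = GrowthParams(total_length_mean=2000.0, total_length_sd=0.0,
                         n_branch_mean=10.0, n_branch_sd=0.0)
        m = grow_axon(p, seed=3)
        assert m.n_branch_points() == 10


class TestPlaceBoutons:
    def test_fixed_spacing_count(self):
        m = straight_segment(50.0)
        mb = place_boutons(m, spacing_mean=5.0, spacing_sd=0.0, seed=0)
        assert mb.bouton_xyz.shape[0] == 10
        assert np.allclose(np.diff(mb.bouton_path_dist), 5.0)

    def test_axon_shorter_than_spacing_has_no_boutons(self):
        m = straight_segment(2.0)
        mb = place_boutons(m, spacing_mean=5.0, spacing_sd=0.0, seed=0)
        assert mb.bouton_xyz.shape[0] == 0

    def test_mean_interbouton_spacing_matches_default(self):
        spacings = []
        for s in range(4):
            mb = place_boutons(grow_axon(SMALL, seed=100 + s), seed=s)
            d = np.diff(mb.bouton_path_dist)
            spacings.extend(d[d > 0])
        spacings = np.asarray(spacings)
        assert spacings.size >= 1000
        se = spacings.std() / math.sqrt(spacings.size)
        assert abs(spacings.mean() - 3.36) < 3 * se

    def test_boutons_deterministic_given_seed(self):
        m = grow_axon(SMALL, seed=4)
        a = place_boutons(m, seed=9)
        b = place_boutons(m, seed=9)
        assert np.array_equal(a.bouton_xyz, b.bouton_xyz)


class TestKsTwoSample:
    def test_identical_samples(self):
        d, p = ks_two_sample([1, 2, 3, 4], [1, 2, 3, 4])
        assert d == 0.0
        assert p == pytest.approx(1.0)

    def test_disjoint_supports(self):
        d, _ = ks_two_sample(np.arange(100), np.arange(1000, 1100))
        assert d == 1.0

    def test_hand_computed_statistic(self):
        d, _ = ks_two_sample([1, 2, 3], [2, 3, 4])
        assert d == pytest.approx(1.0 / 3.0)

    def test_empty_sample_rejected(self):
        with pytest.raises(StatisticsError):
            ks_two_sample([], [1.0])


class TestCalibrateGrowth:
    def test_zero_threshold_returns_init(self):
        target = ShollProfile(shell_step=10.0, lengths=[1.0, 2.0, 1.0])
        res = calibrate_growth(target, SMALL, p_threshold=0.0, seed=0)
        assert res.params is SMALL
        assert res.passed

    def test_self_recovery_from_generating_parameters(self):
        # target = profile of a population generated with known parameters;
        # starting at those parameters the K-S test must pass quickly
        profs = [sholl_analysis(grow_axon(SMALL, seed=s)) for s in range(16)]
        n_shell = max(p.lengths.size for p in profs)
        pooled = np.zeros(n_shell)
        for p in profs:
            pooled[: p.lengths.size] += p.lengths
        target = ShollProfile(shell_step=10.0, lengths=pooled)
        passes = 0
        n_runs = 10
        for run in range(n_runs):
            try:
                res = calibrate_growth(target, SMALL, p_threshold=0.05,
                                       max_iter=15, n_sample=250,
                                       seed=1000 + run)
                passes += res.passed
            except CalibrationError:
                pass
        assert passes >= 0.9 * n_runs

    def test_degenerate_target_rejected(self):
        target = ShollProfile(shell_step=10.0, lengths=[0.0, 0.0])
        with pytest.raises(StatisticsError):
            calibrate_growth(target, SMALL, seed=0)
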