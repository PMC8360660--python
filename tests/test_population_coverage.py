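"""Soma placement, nearest-neighbor distances, coverage maps, multiplicity."""

import numpy as np
import pytest
from scipy import stats

from ngfc.errors import ConfigurationError, StatisticsError
from ngfc.morphology import AxonMorphology, GrowthParams
from ngfc.population_coverage import (
    DEFAULT_DIMS,
    DEFAULT_N_SOMATA,
    CoverageMap,
    DepthDensityProfile,
    PopulationLayout,
    build_coverage,
    build_population,
    nn_distances,
    sample_somata,
    source_multiplicity,
)


def toy_layout(bouton_sets, dims=(10.0, 10.0, 10.0)):
    """Layout with explicit bouton positions, one morphology per cell."""
    morphs = []
    somata = []
    for xyz in bouton_sets:
        xyz = np.asarray(xyz, dtype=float).reshape(-1, 3)
        soma = np.clip(xyz.mean(axis=0), 0, np.asarray(dims))
        somata.append(soma)
        morphs.append(AxonMorphology(soma=soma, nodes=soma[None, :],
                                     parents=np.array([-1]), bouton_xyz=xyz))
    return PopulationLayout(dims=dims, somata=np.array(somata), morphologies=morphs)


class TestSampleSomata:
    def test_zero_count_gives_empty_set(self):
        prof = DepthDensityProfile.default()
        assert sample_somata(prof, n=0, seed=0).shape == (0, 3)

    def test_default_population_size_and_bounds(self):
        prof = DepthDensityProfile.default()
        pos = sample_somata(prof, seed=1)
        assert pos.shape == (DEFAULT_N_SOMATA, 3)
        assert np.all(pos >= 0)
        assert np.all(pos <= np.asarray(DEFAULT_DIMS))

    def test_uniform_profile_passes_chi_square(self):
        prof = DepthDensityProfile.uniform()
        pos = sample_somata(prof, n=10_000, seed=2)
        counts, _ = np.histogram(pos[:, 2], bins=prof.bin_edges)
        _, p = stats.chisquare(counts)
        assert p > 0.01

    def test_all_zero_profile_rejected(self):
        with pytest.raises(ConfigurationError):
            DepthDensityProfile(bin_edges=[0, 10, 20], density=[0.0, 0.0])


class TestNnDistances:
    def test_two_points(self):
        d = nn_distances([[0, 0, 0], [3, 4, 0]])
        assert np.allclose(d, [5.0, 5.0])

    def test_cubic_lattice_spacing(self):
        g = np.stack(np.meshgrid(*[np.arange(3) * 2.0] * 3,
                                 indexing="ij"), axis=-1).reshape(-1, 3)
        assert np.allclose(nn_distances(g), 2.0)

    def test_matches_brute_force(self, rng):
        pts = rng.random((50, 3)) * 100
        d = nn_distances(pts)
        diff = pts[:, None, :] - pts[None, :, :]
        full = np.linalg.norm(diff, axis=2)
        np.fill_diagonal(full, np.inf)
        assert np.allclose(d, full.min(axis=1))

    def test_single_point_rejected(self):
        with pytest.raises(StatisticsError):
            nn_distances([[0, 0, 0]])


def brute_force_coverage(layout, radius, voxel_size):
    """Exhaustive per-voxel scan used as the oracle."""
    dims = np.asarray(layout.dims)
    shape = tuple(int(np.ceil(d / voxel_size)) for d in dims)
    xyz, cell = layout.boutons()
    bouton = np.zeros(shape, dtype=int)
    source = np.zeros(shape, dtype=int)
    for i in range(shape[0]):
        for j in range(shape[1]):
            for k in range(shape[2]):
                c = (np.array([i, j, k]) + 0.5) * voxel_size
                if xyz.shape[0]:
                    d = np.linalg.norm(xyz - c, axis=1)
                    hit = d <= radius
                    bouton[i, j, k] = hit.sum()
                    source[i, j, k] = np.unique(cell[hit]).size
    return bouton.ravel(), source.ravel()


class TestBuildCoverage:
    def test_single_bouton_covers_exactly_inradius_voxels(self):
        layout = toy_layout([[[5.0, 5.0, 5.0]]])
        cov = build_coverage(layout, radius=1.5, voxel_size=1.0)
        b_o, s_o = brute_force_coverage(layout, 1.5, 1.0)
        assert np.array_equal(cov.bouton_count, b_o)
        assert np.array_equal(cov.source_count, s_o)
        assert cov.bouton_count.max() == 1

    def test_same_cell_boutons_count_one_source(self):
        layout = toy_layout([[[5.0, 5.0, 5.0], [5.4, 5.0, 5.0]]])
        cov = build_coverage(layout, radius=1.5, voxel_size=1.0)
        center = np.ravel_multi_index((5, 5, 5), cov.shape)
        assert cov.bouton_count[center] == 2
        assert cov.source_count[center] == 1

    def test_five_cell_toy_matches_brute_force(self, rng):
        sets = [rng.random((4, 3)) * 10 for _ in range(5)]
        layout = toy_layout(sets)
        cov = build_coverage(layout, radius=1.5, voxel_size=1.0)
        b_o, s_o = brute_force_coverage(layout, 1.5, 1.0)
        assert np.array_equal(cov.bouton_count, b_o)
        assert np.array_equal(cov.source_count, s_o)

    def test_counts_monotone_in_radius(self, rng):
        sets = [rng.random((5, 3)) * 10 for _ in range(3)]
        layout = toy_layout(sets)
        prev = None
        for r in (0.5, 1.0, 1.5, 2.0):
            cov = build_coverage(layout, radius=r, voxel_size=1.0)
            if prev is not None:
                assert np.all(cov.bouton_count >= prev)
            prev = cov.bouton_count

    def test_invalid_voxel_size_rejected(self):
        layout = toy_layout([[[5, 5, 5]]])
        with pytest.raises(ConfigurationError):
            build_coverage(layout, radius=1.5, voxel_size=0.0)


class TestSourceMultiplicity:
    def test_single_cell_population_is_all_single_source(self):
        layout = toy_layout([[[5.0, 5.0, 5.0], [6.0, 5.0, 5.0]]])
        cov = build_coverage(layout, radius=1.5, voxel_size=1.0)
        mult = source_multiplicity(cov, active_fraction=1.0, seed=0)
        assert mult[1] == pytest.approx(100.0)
        assert mult[2] == mult[3] == mult["4+"] == 0.0

    def test_percentages_sum_to_hundred(self, rng):
        sets = [rng.random((6, 3)) * 8 + 1 for _ in range(5)]
        cov = build_coverage(toy_layout(sets), radius=1.5, voxel_size=1.0)
        mult = source_multiplicity(cov, seed=0)
        assert sum(mult.values()) == pytest.approx(100.0, abs=1e-6)

    def test_matches_exhaustive_enumeration(self, rng):
        sets = [rng.random((4, 3)) * 8 + 1 for _ in range(5)]
        layout = toy_layout(sets)
        cov = build_coverage(layout, radius=1.5, voxel_size=1.0)
        mult = source_multiplicity(cov, active_fraction=1.0, seed=0,
                                   include_edge=True)
        _, s_o = brute_force_coverage(layout, 1.5, 1.0)
        covered = s_o[s_o > 0]
        assert mult[1] == pytest.approx(100.0 * (covered == 1).sum() / covered.size)
        assert mult[2] == pytest.approx(100.0 * (covered == 2).sum() / covered.size)

    def test_lower_active_fraction_shifts_mass_to_single_source(self, rng):
        sets = [rng.random((25, 3)) * 8 + 1 for _ in range(8)]
        cov = build_coverage(toy_layout(sets), radius=2.0, voxel_size=1.0)
        full = source_multiplicity(cov, active_fraction=1.0, seed=0)
        partial = np.mean([
            source_multiplicity(cov, active_fraction=0.4, seed=s)[1]
            for s in range(10)
        ])
        assert partial > full[1]

    def test_invalid_fraction_rejected(self):
        cov = build_coverage(toy_layout([[[5, 5, 5]]]), radius=1.5, voxel_size=1.0)
        with pytest.raises(ConfigurationError):
            source_multiplicity(cov, active_fraction=0.0, seed=0)


class TestBuildPopulation:
    def test_small_population_structure(self):
        growth = GrowthParams(total_length_mean=300.0, total_length_sd=50.0,
                              n_branch_mean=3.0, n_branch_sd=1.0)
        layout = build_population(growth=growth, n=5, dims=(50.0, 50.0, 30.0),
                                  seed=3)
        assert layout.n_cells == 5
        xyz, cell = layout.boutons()
        assert xyz.shape[0] > 0
        assert set(np.unique(cell)) <= set(range(5))
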