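"""Layer-1 population model and volume-transmission coverage maps.

Somata are placed in a bounded cortical volume according to a radial
depth-density profile (uniform horizontally), one model arbor is grown
per soma, and the neuropil is voxelized to count, at every voxel center,
the boutons lying within the transmitter interaction radius and the
number of distinct source cells among them.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .errors import ConfigurationError, StatisticsError
from .morphology import AxonMorphology, GrowthParams, grow_axon, place_boutons

__all__ = [
    "DepthDensityProfile",
    "PopulationLayout",
    "CoverageMap",
    "sample_somata",
    "nn_distances",
    "build_population",
    "build_coverage",
    "source_multiplicity",
    "DEFAULT_DIMS",
    "DEFAULT_N_SOMATA",
]

#: bounded model volume, µm (x, y, z-depth)
DEFAULT_DIMS = (354.0, 354.0, 140.0)
#: number of interneuron somata placed in the default volume
DEFAULT_N_SOMATA = 374


@dataclass
class DepthDensityProfile:
    """Relative soma density as a function of depth below the pia."""

    bin_edges: np.ndarray
    density: np.ndarray

    def __post_init__(self):
        self.bin_edges = np.asarray(self.bin_edges, dtype=float)
        self.density = np.asarray(self.density, dtype=float)
        if self.density.size != self.bin_edges.size - 1:
            raise ConfigurationError("need one density per bin")
        if np.any(self.density < 0) or not np.any(self.density > 0):
            raise ConfigurationError("densities must be >= 0 with at least one positive bin")

    @classmethod
    def default(cls, max_depth: float = 140.0, peak: float = 100.0,
                width: float = 45.0, n_bins: int = 14) -> "DepthDensityProfile":
        """Parametric stand-in: Gaussian bump peaking in the 50-150 µm band.

        The published depth histogram is not printed as numbers, so a
        Gaussian profile (peak depth ``peak`` µm, SD ``width``) is used and
        can be overridden with measured bin values.
        """
        edges = np.linspace(0.0, max_depth, n_bins + 1)
        centers = 0.5 * (edges[:-1] + edges[1:])
        dens = np.exp(-0.5 * ((centers - peak) / width) ** 2)
        return cls(bin_edges=edges, density=dens)

    @classmethod
    def uniform(cls, max_depth: float = 140.0, n_bins: int = 14) -> "DepthDensityProfile":
        edges = np.linspace(0.0, max_depth, n_bins + 1)
        return cls(bin_edges=edges, density=np.ones(n_bins))

    def sample(self, n: int, rng) -> np.ndarray:
        probs = self.density / self.density.sum()
        bins = rng.choice(self.density.size, size=n, p=probs)
        lo = self.bin_edges[bins]
        hi = self.bin_edges[bins + 1]
        return lo + rng.random(n) * (hi - lo)


def sample_somata(
    profile: DepthDensityProfile,
    dims=DEFAULT_DIMS,
    n: int = DEFAULT_N_SOMATA,
    seed: int = 0,
) -> np.ndarray:
    """Place ``n`` somata: x, y uniform; z (depth) from the profile."""
    if n < 0:
        raise ConfigurationError("n must be >= 0")
    rng = np.random.default_rng(seed)
    dims = np.asarray(dims, dtype=float)
    xy = rng.random((n, 2)) * dims[:2]
    z = np.clip(profile.sample(n, rng), 0.0, dims[2])
    return np.column_stack([xy, z])


def nn_distances(positions: np.ndarray) -> np.ndarray:
    """3D nearest-neighbor Euclidean distance of every point."""
    positions = np.asarray(positions, dtype=float).reshape(-1, 3)
    if positions.shape[0] < 2:
        raise StatisticsError("nearest-neighbor distances need >= 2 points")
    tree = cKDTree(positions)
    d, _ = tree.query(positions, k=2)
    return d[:, 1]


@dataclass
class PopulationLayout:
    """Somata plus one bouton-decorated arbor per soma in a bounded volume."""

    dims: tuple
    somata: np.ndarray
    morphologies: list

    def __post_init__(self):
        self.somata = np.asarray(self.somata, dtype=float).reshape(-1, 3)
        dims = np.asarray(self.dims, dtype=float)
        if np.any(self.somata < -1e-9) or np.any(self.somata > dims + 1e-9):
            raise ConfigurationError("all somata must lie inside the volume")
        if len(self.morphologies) != self.somata.shape[0]:
            raise ConfigurationError("one morphology per soma required")

    @property
    def n_cells(self) -> int:
        return self.somata.shape[0]

    def boutons(self):
        """All bouton positions with their source-cell index."""
        xyz, cell = [], []
        for ci, m in enumerate(self.morphologies):
            if m.bouton_xyz.size:
                xyz.append(m.bouton_xyz)
                cell.append(np.full(m.bouton_xyz.shape[0], ci, dtype=int))
        if not xyz:
            return np.empty((0, 3)), np.empty(0, dtype=int)
        return np.vstack(xyz), np.concatenate(cell)


def build_population(
    profile: DepthDensityProfile = None,
    growth: GrowthParams = None,
    dims=DEFAULT_DIMS,
    n: int = DEFAULT_N_SOMATA,
    spacing_mean: float = 3.36,
    spacing_sd: float = 2.54,
    seed: int = 0,
) -> PopulationLayout:
    """Grow the full population: somata, arbors, boutons."""
    profile = profile or DepthDensityProfile.default(max_depth=float(dims[2]))
    growth = growth or GrowthParams()
    rng = np.random.default_rng(seed)
    somata = sample_somata(profile, dims=dims, n=n, seed=int(rng.integers(2**31 - 1)))
    morphs = []
    for soma in somata:
        m = grow_axon(growth, seed=int(rng.integers(2**31 - 1)), soma=soma)
        m = place_boutons(m, spacing_mean, spacing_sd, seed=int(rng.integers(2**31 - 1)))
        morphs.append(m)
    return PopulationLayout(dims=tuple(float(d) for d in dims), somata=somata,
                            morphologies=morphs)


@dataclass
class CoverageMap:
    """Voxelized bouton coverage of the model volume.

    ``bouton_count[v]`` is the number of boutons within the interaction
    radius of voxel center v; ``source_count[v]`` the number of distinct
    source cells among them. ``pairs`` stores the unique (voxel, cell)
    incidences so multiplicity can be recomputed for any active subset of
    cells. Voxels whose center lies within the radius of a volume face
    are flagged ``edge`` and excluded from multiplicity percentages.
    """

    voxel_size: float
    radius: float
    shape: tuple
    dims: tuple
    bouton_count: np.ndarray         # flat, len = prod(shape)
    source_count: np.ndarray
    edge_mask: np.ndarray
    pair_voxel: np.ndarray           # unique (voxel, cell) incidence pairs
    pair_cell: np.ndarray
    n_cells: int

    def voxel_centers(self) -> np.ndarray:
        axes = [
            (np.arange(s) + 0.5) * self.voxel_size for s in self.shape
        ]
        grid = np.meshgrid(*axes, indexing="ij")
        return np.stack([g.ravel() for g in grid], axis=1)


def build_coverage(
    layout: PopulationLayout,
    radius: float = 1.5,
    voxel_size: float = 1.0,
) -> CoverageMap:
    """Count boutons (and distinct source cells) near every voxel center."""
    if radius <= 0:
        raise ConfigurationError("radius must be positive")
    if voxel_size <= 0:
        raise ConfigurationError("voxel_size must be positive")
    dims = np.asarray(layout.dims, dtype=float)
    shape = tuple(int(np.ceil(d / voxel_size)) for d in dims)
    n_vox = int(np.prod(shape))

    xyz, cell = layout.boutons()
    pair_voxel = np.empty(0, dtype=np.int64)
    pair_cell = np.empty(0, dtype=np.int64)
    bouton_count = np.zeros(n_vox, dtype=np.int64)

    if xyz.shape[0]:
        centers_ax = [(np.arange(s) + 0.5) * voxel_size for s in shape]
        pv, pc = [], []
        # per-bouton stencil: voxels whose center can be within `radius`
        for b in range(xyz.shape[0]):
            p = xyz[b]
            rngs = []
            for ax in range(3):
                lo = int(np.floor((p[ax] - radius) / voxel_size - 0.5))
                hi = int(np.ceil((p[ax] + radius) / voxel_size - 0.5))
                rngs.append(np.arange(max(lo, 0), min(hi, shape[ax] - 1) + 1))
            if any(r.size == 0 for r in rngs):
                continue
            gi, gj, gk = np.meshgrid(*rngs, indexing="ij")
            cx = (gi + 0.5) * voxel_size
            cy = (gj + 0.5) * voxel_size
            cz = (gk + 0.5) * voxel_size
            d2 = (cx - p[0]) ** 2 + (cy - p[1]) ** 2 + (cz - p[2]) ** 2
            hit = d2 <= radius**2
            if not hit.any():
                continue
            vox = (gi[hit] * shape[1] + gj[hit]) * shape[2] + gk[hit]
            pv.append(vox)
            pc.append(np.full(vox.size, cell[b], dtype=np.int64))
        if pv:
            all_vox = np.concatenate(pv)
            all_cell = np.concatenate(pc)
            bouton_count = np.bincount(all_vox, minlength=n_vox)
            uniq = np.unique(np.stack([all_vox, all_cell], axis=1), axis=0)
            pair_voxel, pair_cell = uniq[:, 0], uniq[:, 1]

    source_count = np.bincount(pair_voxel, minlength=n_vox)

    # edge voxels: center closer than `radius` to any face of the volume
    axes = [(np.arange(s) + 0.5) * voxel_size for s in shape]
    edge_1d = [
        (a < radius) | (a > d - radius) for a, d in zip(axes, dims)
    ]
    ei, ej, ek = np.meshgrid(*edge_1d, indexing="ij")
    edge_mask = (ei | ej | ek).ravel()

    return CoverageMap(
        voxel_size=voxel_size,
        radius=radius,
        shape=shape,
        dims=tuple(dims),
        bouton_count=bouton_count,
        source_count=source_count,
        edge_mask=edge_mask,
        pair_voxel=pair_voxel,
        pair_cell=pair_cell,
        n_cells=layout.n_cells,
    )


def source_multiplicity(
    coverage: CoverageMap,
    active_fraction: float = 1.0,
    seed: int = 0,
    include_edge: bool = False,
) -> dict:
    """Distribution of distinct-source counts over covered voxels.

    Cells are subsampled Bernoulli(``active_fraction``); the returned dict
    maps ``1, 2, 3`` and ``"4+"`` to the percentage of covered (non-edge)
    voxels reached by exactly that many distinct active cells. The
    percentages sum to 100.
    """
    if not (0.0 < active_fraction <= 1.0):
        raise ConfigurationError("active_fraction must be in (0, 1]")
    rng = np.random.default_rng(seed)
    if active_fraction < 1.0:
        active = rng.random(coverage.n_cells) < active_fraction
    else:
        active = np.ones(coverage.n_cells, dtype=bool)

    keep = active[coverage.pair_cell]
    vox = coverage.pair_voxel[keep]
    if not include_edge:
        vox = vox[~coverage.edge_mask[vox]]
    if vox.size == 0:
        raise StatisticsError("no covered voxel for the active subset")
    counts = np.bincount(vox)
    counts = counts[counts > 0]
    n_cov = counts.size
    out = {
        1: 100.0 * np.sum(counts == 1) / n_cov,
        2: 100.0 * np.sum(counts == 2) / n_cov,
        3: 100.0 * np.sum(counts == 3) / n_cov,
        "4+": 100.0 * np.sum(counts >= 4) / n_cov,
    }
    return out
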