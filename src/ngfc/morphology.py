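"""Axonal morphology: Sholl analysis, stochastic arbor growth, boutons.

Model interneuron axons are grown as rooted 3D trees by expanding fixed
elementary segments from the soma, with branch events and orientation
deviations drawn from configurable distributions. The growth parameters
are calibrated so that the Sholl profile of a generated population is
statistically indistinguishable (two-sample K-S test) from a target
profile, mirroring how a model arbor is matched to reconstructed cells.

Units are µm throughout; coordinates are right-handed with z the depth
below the pia (0 at the pia, increasing downward).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import stats

from .errors import CalibrationError, ConfigurationError, StatisticsError

__all__ = [
    "AxonMorphology",
    "ShollProfile",
    "GrowthParams",
    "sholl_analysis",
    "grow_axon",
    "place_boutons",
    "ks_two_sample",
    "calibrate_growth",
    "CalibrationResult",
]


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass
class AxonMorphology:
    """Rooted 3D axonal tree with optional bouton decorations.

    ``nodes[0]`` is the soma; ``parents[i]`` indexes the parent of node i
    (-1 for the soma). Boutons are stored with their 3D position, the
    index of the edge (child-node index) they lie on, and their path
    distance from the soma along the tree.
    """

    soma: np.ndarray
    nodes: np.ndarray                      # (N, 3)
    parents: np.ndarray                    # (N,)
    bouton_xyz: np.ndarray = field(default_factory=lambda: np.empty((0, 3)))
    bouton_edge: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=int))
    bouton_path_dist: np.ndarray = field(default_factory=lambda: np.empty(0))

    def __post_init__(self):
        self.soma = np.asarray(self.soma, dtype=float)
        self.nodes = np.asarray(self.nodes, dtype=float).reshape(-1, 3)
        self.parents = np.asarray(self.parents, dtype=int)
        if self.nodes.shape[0] != self.parents.shape[0]:
            raise ConfigurationError("nodes and parents length mismatch")
        if self.nodes.shape[0] and self.parents[0] != -1:
            raise ConfigurationError("node 0 must be the root (parent -1)")

    @property
    def n_nodes(self) -> int:
        return self.nodes.shape[0]

    @property
    def edges(self) -> np.ndarray:
        """Child-node indices of all edges (node i with parent >= 0)."""
        return np.flatnonzero(self.parents >= 0)

    def edge_lengths(self) -> np.ndarray:
        e = self.edges
        return np.linalg.norm(self.nodes[e] - self.nodes[self.parents[e]], axis=1)

    def total_length(self) -> float:
        return float(self.edge_lengths().sum())

    def path_distances(self) -> np.ndarray:
        """Along-tree distance of every node from the soma."""
        dist = np.zeros(self.n_nodes)
        for i in range(1, self.n_nodes):
            p = self.parents[i]
            dist[i] = dist[p] + np.linalg.norm(self.nodes[i] - self.nodes[p])
        return dist

    def n_branch_points(self) -> int:
        if self.n_nodes < 2:
            return 0
        counts = np.bincount(self.parents[self.parents >= 0], minlength=self.n_nodes)
        return int(np.sum(counts[1:] > 1))  # soma multifurcation is not a branch point

    def translated(self, offset) -> "AxonMorphology":
        offset = np.asarray(offset, dtype=float)
        return replace(
            self,
            soma=self.soma + offset,
            nodes=self.nodes + offset,
            bouton_xyz=self.bouton_xyz + offset if self.bouton_xyz.size else self.bouton_xyz,
        )

    def resample_points(self, step: float = 1.0):
        """Dense points along the cable with per-point weights (lengths).

        Returns (points (M,3), weights (M,), radial distances (M,)): each
        edge is split into sub-segments of at most ``step`` µm, represented
        by midpoints weighted by sub-segment length.
        """
        pts, wts = [], []
        for i in self.edges:
            a, b = self.nodes[self.parents[i]], self.nodes[i]
            length = np.linalg.norm(b - a)
            if length == 0:
                continue
            k = max(1, int(math.ceil(length / step)))
            frac = (np.arange(k) + 0.5) / k
            pts.append(a + frac[:, None] * (b - a))
            wts.append(np.full(k, length / k))
        if not pts:
            return np.empty((0, 3)), np.empty(0), np.empty(0)
        pts = np.vstack(pts)
        wts = np.concatenate(wts)
        radii = np.linalg.norm(pts - self.soma, axis=1)
        return pts, wts, radii


@dataclass
class ShollProfile:
    """Axonal cable length in concentric spherical shells around the soma."""

    shell_step: float
    lengths: np.ndarray

    def __post_init__(self):
        if self.shell_step <= 0:
            raise ConfigurationError("shell_step must be positive")
        self.lengths = np.asarray(self.lengths, dtype=float)
        if np.any(self.lengths < 0):
            raise ConfigurationError("shell lengths must be >= 0")

    @property
    def total_length(self) -> float:
        return float(self.lengths.sum())

    def radii(self) -> np.ndarray:
        """Inner radius of each shell."""
        return self.shell_step * np.arange(self.lengths.size)

    def sample(self, n: int, rng) -> np.ndarray:
        """Length-weighted radial sample (uniform within each shell).

        Used to compare profiles with a two-sample K-S test.
        """
        if self.total_length <= 0:
            raise StatisticsError("cannot sample from an all-zero profile")
        probs = self.lengths / self.total_length
        shells = rng.choice(self.lengths.size, size=n, p=probs)
        return (shells + rng.random(n)) * self.shell_step


@dataclass
class GrowthParams:
    """Parameters of the stochastic axon-growth model.

    Total cable length and branch-point count are drawn per cell from
    truncated normals; the arbor is grown in elementary segments of
    ``segment_step`` µm whose direction deviates from the parent segment
    by a polar angle ~ N(polar_mean_deg, polar_sd_deg) with the azimuth
    uniform around the parent axis.
    """

    total_length_mean: float = 10000.0
    total_length_sd: float = 2000.0
    n_branch_mean: float = 120.0
    n_branch_sd: float = 30.0
    segment_step: float = 10.0
    polar_mean_deg: float = 40.0
    polar_sd_deg: float = 25.0

    def __post_init__(self):
        if self.total_length_mean <= 0 or self.n_branch_mean < 0:
            raise ConfigurationError("means must be positive (branch count >= 0)")
        if self.total_length_sd < 0 or self.n_branch_sd < 0:
            raise ConfigurationError("SDs must be >= 0")
        if self.segment_step <= 0:
            raise ConfigurationError("segment_step must be positive")


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def sholl_analysis(morph: AxonMorphology, shell_step: float = 10.0,
                   resample_step: float = 0.25) -> ShollProfile:
    """Partition cable length into concentric shells around the soma.

    Shells are half-open ``[k*step, (k+1)*step)``. The cable is resampled
    at ``resample_step`` so the partition conserves total length to within
    0.5%.
    """
    if shell_step <= 0:
        raise ConfigurationError("shell_step must be positive")
    _, wts, radii = morph.resample_points(step=resample_step)
    if wts.size == 0:
        return ShollProfile(shell_step=shell_step, lengths=np.zeros(1))
    n_shells = int(radii.max() // shell_step) + 1
    idx = np.minimum((radii // shell_step).astype(int), n_shells - 1)
    lengths = np.bincount(idx, weights=wts, minlength=n_shells)
    return ShollProfile(shell_step=shell_step, lengths=lengths)


def _truncnorm_pos(mean, sd, rng):
    """Positive draw from N(mean, sd) by rejection (mean must be > 0)."""
    if sd == 0:
        return mean
    for _ in range(1000):
        x = rng.normal(mean, sd)
        if x > 0:
            return x
    raise ConfigurationError("truncated-normal rejection failed; check mean/sd")


def _deviate(direction, polar_deg, azimuth, out=None):
    """Rotate a unit vector by a polar angle about a random azimuth."""
    d = direction / np.linalg.norm(direction)
    # orthonormal frame around d
    a = np.array([1.0, 0.0, 0.0]) if abs(d[0]) < 0.9 else np.array([0.0, 1.0, 0.0])
    u = np.cross(d, a)
    u /= np.linalg.norm(u)
    v = np.cross(d, u)
    th = math.radians(polar_deg)
    return (math.cos(th) * d
            + math.sin(th) * (math.cos(azimuth) * u + math.sin(azimuth) * v))


def grow_axon(params: GrowthParams, seed: int, soma=(0.0, 0.0, 0.0)) -> AxonMorphology:
    """Grow one model axonal arbor from the soma.

    The realized total length is drawn from a positive-truncated normal;
    the branch-event count from a rounded truncated normal. Branch events
    are scheduled uniformly over the elementary segments; at a branch the
    tip splits into two daughters, each deviating independently.
    """
    rng = np.random.default_rng(seed)
    total = _truncnorm_pos(params.total_length_mean, params.total_length_sd, rng)
    if params.n_branch_sd == 0:
        n_branch = int(round(params.n_branch_mean))
    else:
        n_branch = max(0, int(round(rng.normal(params.n_branch_mean, params.n_branch_sd))))

    step = params.segment_step
    n_seg = max(1, int(round(total / step)))
    seg_len = total / n_seg
    # schedule branch events on segment indices (without replacement)
    branch_at = set(rng.choice(n_seg, size=min(n_branch, n_seg), replace=False).tolist()) if n_branch else set()

    soma = np.asarray(soma, dtype=float)
    nodes = [soma.copy()]
    parents = [-1]
    # initial direction: uniform on the sphere
    d0 = rng.normal(size=3)
    d0 /= np.linalg.norm(d0)
    tips = [(0, d0)]  # (node index, direction)

    for s in range(n_seg):
        ti = rng.integers(len(tips))
        node_idx, direction = tips.pop(ti)
        if params.polar_sd_deg == 0 and params.polar_mean_deg == 0:
            new_dir = direction
        else:
            polar = rng.normal(params.polar_mean_deg, params.polar_sd_deg)
            new_dir = _deviate(direction, polar, rng.uniform(0, 2 * math.pi))
        new_pos = nodes[node_idx] + seg_len * new_dir
        nodes.append(new_pos)
        parents.append(node_idx)
        new_idx = len(nodes) - 1
        if s in branch_at:
            tips.append((new_idx, new_dir))
            tips.append((new_idx, new_dir))
        else:
            tips.append((new_idx, new_dir))

    return AxonMorphology(soma=soma, nodes=np.array(nodes), parents=np.array(parents))


def _tree_paths(morph: AxonMorphology):
    """Maximal unbranched paths as lists of node indices (root/branch to
    branch/leaf), each starting at a branch point or the soma."""
    children = [[] for _ in range(morph.n_nodes)]
    for i in morph.edges:
        children[morph.parents[i]].append(int(i))
    paths = []
    # path starts: children of soma and of every multi-child node
    stack = [(0, c) for c in children[0]]
    while stack:
        start_parent, node = stack.pop()
        path = [start_parent, node]
        while len(children[node]) == 1:
            node = children[node][0]
            path.append(node)
        paths.append(path)
        for c in children[node]:
            stack.append((node, c))
    return paths


def place_boutons(
    morph: AxonMorphology,
    spacing_mean: float = 3.36,
    spacing_sd: float = 2.54,
    seed: int = 0,
) -> AxonMorphology:
    """Decorate an arbor with boutons at gamma-distributed spacings.

    Consecutive along-path spacings are drawn from a gamma distribution
    with the configured mean and SD (a gamma keeps spacings positive with
    the realized mean equal to the configured mean in expectation, which a
    zero-truncated normal would not). Spacings restart on every maximal
    unbranched path. SD 0 degenerates to fixed spacing.
    """
    if spacing_mean <= 0:
        raise ConfigurationError("spacing_mean must be positive")
    if spacing_sd < 0:
        raise ConfigurationError("spacing_sd must be >= 0")
    rng = np.random.default_rng(seed)
    path_dist = morph.path_distances()

    b_xyz, b_edge, b_dist = [], [], []
    for path in _tree_paths(morph):
        # cumulative arc length along the path polyline
        pts = morph.nodes[path]
        seg_len = np.linalg.norm(np.diff(pts, axis=0), axis=1)
        cum = np.concatenate([[0.0], np.cumsum(seg_len)])
        path_len = cum[-1]
        if path_len <= 0:
            continue
        pos = 0.0
        while True:
            if spacing_sd == 0:
                gap = spacing_mean
            else:
                shape = (spacing_mean / spacing_sd) ** 2
                scale = spacing_sd**2 / spacing_mean
                gap = rng.gamma(shape, scale)
            pos += gap
            if pos > path_len * (1 + 1e-12):
                break
            j = int(np.searchsorted(cum, pos, side="right") - 1)
            j = min(j, len(seg_len) - 1)
            frac = (pos - cum[j]) / seg_len[j] if seg_len[j] > 0 else 0.0
            xyz = pts[j] + frac * (pts[j + 1] - pts[j])
            b_xyz.append(xyz)
            b_edge.append(path[j + 1])
            b_dist.append(path_dist[path[j]] + (pos - cum[j]))

    return replace(
        morph,
        bouton_xyz=np.array(b_xyz).reshape(-1, 3),
        bouton_edge=np.array(b_edge, dtype=int),
        bouton_path_dist=np.array(b_dist, dtype=float),
    )


def ks_two_sample(a, b):
    """Two-sample Kolmogorov-Smirnov test (two-sided, asymptotic p).

    Returns ``(D, p)`` with D the supremum ECDF distance.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise StatisticsError("K-S test requires non-empty samples")
    res = stats.ks_2samp(a, b, alternative="two-sided", method="asymp")
    return float(res.statistic), float(res.pvalue)


@dataclass
class CalibrationResult:
    params: GrowthParams
    p_value: float
    d_statistic: float
    n_iter: int
    passed: bool


def _population_sholl_sample(params, n_cells, n_sample, rng):
    radii_all = []
    wts_all = []
    for _ in range(n_cells):
        cell_seed = int(rng.integers(2**31 - 1))
        morph = grow_axon(params, seed=cell_seed)
        _, wts, radii = morph.resample_points(step=2.0)
        radii_all.append(radii)
        wts_all.append(wts)
    radii = np.concatenate(radii_all)
    wts = np.concatenate(wts_all)
    probs = wts / wts.sum()
    return rng.choice(radii, size=n_sample, p=probs)


def calibrate_growth(
    target: ShollProfile,
    init: GrowthParams,
    p_threshold: float = 0.05,
    max_iter: int = 40,
    n_cells: int = 6,
    n_sample: int = 400,
    seed: int = 0,
    t0: float = 0.3,
    cooling: float = 0.93,
) -> CalibrationResult:
    """Anneal growth parameters until generated arbors match a Sholl target.

    A simulated-annealing loop perturbs the orientation parameters (and
    segment step) of ``init``; the energy is the K-S D statistic between a
    length-weighted radial sample pooled over ``n_cells`` generated arbors
    and a sample from the target profile. Calibration passes as soon as
    the K-S p-value reaches ``p_threshold``.

    Raises :class:`CalibrationError` (carrying the best parameters) if
    ``max_iter`` is exhausted without passing.
    """
    if target.total_length <= 0:
        raise StatisticsError("target profile is degenerate (zero length)")
    if p_threshold <= 0:
        return CalibrationResult(params=init, p_value=1.0, d_statistic=0.0,
                                 n_iter=0, passed=True)
    rng = np.random.default_rng(seed)
    target_sample = target.sample(n_sample, rng)

    def energy(params):
        sample = _population_sholl_sample(params, n_cells, n_sample, rng)
        d, p = ks_two_sample(sample, target_sample)
        return d, p

    current = init
    d_cur, p_cur = energy(current)
    best = CalibrationResult(current, p_cur, d_cur, 0, p_cur >= p_threshold)
    temp = t0
    for it in range(1, max_iter + 1):
        if best.passed:
            break
        cand = replace(
            current,
            polar_mean_deg=max(1.0, current.polar_mean_deg * rng.lognormal(0, 0.15)),
            polar_sd_deg=max(1.0, current.polar_sd_deg * rng.lognormal(0, 0.15)),
            segment_step=float(np.clip(current.segment_step * rng.lognormal(0, 0.1), 2.0, 25.0)),
        )
        d_new, p_new = energy(cand)
        if d_new < d_cur or rng.random() < math.exp(-(d_new - d_cur) / max(temp, 1e-9)):
            current, d_cur, p_cur = cand, d_new, p_new
        if d_cur < best.d_statistic or p_cur >= p_threshold:
            best = CalibrationResult(current, p_cur, d_cur, it, p_cur >= p_threshold)
        temp *= cooling
    if not best.passed:
        raise CalibrationError(
            f"Sholl calibration did not reach p >= {p_threshold} in {max_iter} "
            f"iterations (best p = {best.p_value:.3g})",
            best=best,
        )
    return best
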