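"""Receptor/channel cluster placement by a two-stage seed cascade.

Primary seed particles land on the membrane and subdivide into secondary
seeds; secondaries destined to become GIRK channel clusters nucleate in
place (GIRK clusters are immobile), while secondaries destined to become
GABA_B receptor clusters first diffuse laterally for a stochastic time
(a fixed delay plus an exponential conversion time set by the forward
rate) before nucleating. The delay and forward rate therefore control
the distribution of receptor-to-channel cluster distances, and are
calibrated by simulated annealing against a target distance
distribution on a flat test surface.

Cluster sizes: 1-8 receptors per GABA_B cluster, 1-4 channels per GIRK
cluster.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from ..errors import CalibrationError, ConfigurationError, GeometryError

__all__ = [
    "CascadeParams",
    "ClusterLayout",
    "place_surface_molecules",
    "simulate_flat_cascade",
    "calibrate_cluster_placement",
    "PlacementCalibration",
    "GABAB_CLUSTER_RANGE",
    "GIRK_CLUSTER_RANGE",
]

GABAB_CLUSTER_RANGE = (1, 8)
GIRK_CLUSTER_RANGE = (1, 4)


@dataclass
class CascadeParams:
    """Two-stage cascade parameters.

    ``delay_ms`` + Exp(``forward_rate``) is the lateral-diffusion time of
    a receptor-destined secondary seed before cluster nucleation;
    ``d_seed`` its diffusion coefficient (µm²/ms);
    ``secondaries_per_primary`` controls how many secondary seeds each
    primary spawns.
    """

    delay_ms: float = 5.0
    forward_rate: float = 0.2        # 1/ms
    d_seed: float = 1e-3             # µm²/ms
    secondaries_per_primary: int = 4

    def __post_init__(self):
        if self.delay_ms < 0 or self.forward_rate <= 0 or self.d_seed < 0:
            raise ConfigurationError("invalid cascade parameters")
        if self.secondaries_per_primary < 1:
            raise ConfigurationError("secondaries_per_primary must be >= 1")

    def displacement_sd(self, rng, n):
        """Per-axis SD of the lateral displacement for n seeds."""
        t = self.delay_ms + rng.exponential(1.0 / self.forward_rate, size=n)
        return np.sqrt(2.0 * self.d_seed * t)


@dataclass
class ClusterLayout:
    """Surface clusters of receptors and channels."""

    positions: np.ndarray            # (n, 3) on the membrane, µm
    types: np.ndarray                # "gabab" | "girk"
    sizes: np.ndarray                # receptors / channels per cluster
    compartments: np.ndarray         # "shaft" | "spine"
    mobile: np.ndarray               # bool; GIRK clusters always immobile

    def __post_init__(self):
        self.positions = np.asarray(self.positions, dtype=float).reshape(-1, 3)
        n = self.positions.shape[0]
        self.types = np.asarray(self.types, dtype=object)
        self.sizes = np.asarray(self.sizes, dtype=int)
        self.compartments = np.asarray(self.compartments, dtype=object)
        self.mobile = np.asarray(self.mobile, dtype=bool)
        for arr, name in ((self.types, "types"), (self.sizes, "sizes"),
                          (self.compartments, "compartments"), (self.mobile, "mobile")):
            if arr.shape[0] != n:
                raise ConfigurationError(f"{name} length mismatch")
        gb = self.types == "gabab"
        gk = self.types == "girk"
        if np.any(~(gb | gk)):
            raise ConfigurationError("cluster types must be 'gabab' or 'girk'")
        if gb.any() and (self.sizes[gb].min() < GABAB_CLUSTER_RANGE[0]
                         or self.sizes[gb].max() > GABAB_CLUSTER_RANGE[1]):
            raise ConfigurationError("GABA_B cluster sizes must be in [1, 8]")
        if gk.any() and (self.sizes[gk].min() < GIRK_CLUSTER_RANGE[0]
                         or self.sizes[gk].max() > GIRK_CLUSTER_RANGE[1]):
            raise ConfigurationError("GIRK cluster sizes must be in [1, 4]")
        if np.any(self.mobile[gk]):
            raise ConfigurationError("GIRK clusters must be immobile")

    @property
    def n_clusters(self) -> int:
        return self.positions.shape[0]

    def total(self, type_: str, compartment: str = None) -> int:
        mask = self.types == type_
        if compartment is not None:
            mask &= self.compartments == compartment
        return int(self.sizes[mask].sum())

    @classmethod
    def concatenate(cls, layouts):
        return cls(
            positions=np.vstack([l.positions for l in layouts]),
            types=np.concatenate([l.types for l in layouts]),
            sizes=np.concatenate([l.sizes for l in layouts]),
            compartments=np.concatenate([l.compartments for l in layouts]),
            mobile=np.concatenate([l.mobile for l in layouts]),
        )


def _draw_cluster_sizes(total: int, size_range, rng) -> np.ndarray:
    """Uniform cluster sizes whose sum equals ``total`` (last one trimmed)."""
    lo, hi = size_range
    sizes = []
    remaining = total
    while remaining > 0:
        s = int(rng.integers(lo, hi + 1))
        s = min(s, remaining)
        sizes.append(s)
        remaining -= s
    return np.asarray(sizes, dtype=int)


def place_surface_molecules(
    geometry,
    densities: dict,
    cascade: CascadeParams = None,
    seed: int = 0,
) -> ClusterLayout:
    """Populate a membrane with receptor and channel clusters.

    ``densities`` maps compartment -> {"gabab": per µm², "girk": per µm²}.
    Realized molecule counts per compartment are within 10% of
    density x area (exact up to integer rounding). Receptor-destined
    seeds diffuse laterally (tangent-plane displacement, reprojected to
    the surface) before nucleating; channel clusters nucleate in place.
    """
    cascade = cascade or CascadeParams()
    rng = np.random.default_rng(seed)
    parts = []
    for compartment, spec_d in densities.items():
        area = geometry.area(compartment)
        for type_, dens in spec_d.items():
            if dens < 0:
                raise ConfigurationError("densities must be >= 0")
            if dens == 0:
                continue
            if area <= 0:
                raise GeometryError(
                    f"compartment {compartment!r} has zero area but positive density"
                )
            total = int(round(dens * area))
            if total == 0:
                continue
            size_range = GABAB_CLUSTER_RANGE if type_ == "gabab" else GIRK_CLUSTER_RANGE
            sizes = _draw_cluster_sizes(total, size_range, rng)
            n_sec = sizes.size
            n_prim = max(1, math.ceil(n_sec / cascade.secondaries_per_primary))
            primaries = geometry.sample_surface(n_prim, compartment, rng)
            sec_origin = primaries[rng.integers(0, n_prim, size=n_sec)]
            if type_ == "gabab":
                sd = cascade.displacement_sd(rng, n_sec)
                disp = rng.normal(size=(n_sec, 3)) * sd[:, None]
                # project the 3D kick onto the local tangent plane
                _, faces = geometry.nearest_face(sec_origin)
                normals = geometry.mesh.face_normals[faces]
                disp -= (np.einsum("ij,ij->i", disp, normals))[:, None] * normals
                pos, _ = geometry.nearest_face(sec_origin + disp)
                mobile = np.ones(n_sec, dtype=bool)
            else:
                pos = sec_origin
                mobile = np.zeros(n_sec, dtype=bool)
            comp_final = geometry.label_at(pos)
            parts.append(ClusterLayout(
                positions=pos,
                types=np.full(n_sec, type_, dtype=object),
                sizes=sizes,
                compartments=comp_final,
                mobile=mobile,
            ))
    if not parts:
        return ClusterLayout(
            positions=np.empty((0, 3)), types=np.empty(0, dtype=object),
            sizes=np.empty(0, dtype=int), compartments=np.empty(0, dtype=object),
            mobile=np.empty(0, dtype=bool),
        )
    return ClusterLayout.concatenate(parts)


# ---------------------------------------------------------------------------
# flat-surface calibration
# ---------------------------------------------------------------------------

def simulate_flat_cascade(
    cascade: CascadeParams,
    n_primaries: int = 60,
    extent: float = 10.0,
    seed: int = 0,
) -> np.ndarray:
    """Receptor-to-nearest-channel cluster distances on a flat test plane.

    Each primary seed spawns secondaries that become either a GIRK
    cluster (in place) or a GABA_B cluster (after lateral diffusion);
    returns the distance from every GABA_B cluster center to its nearest
    GIRK cluster center.
    """
    rng = np.random.default_rng(seed)
    prim = rng.random((n_primaries, 2)) * extent
    girk_pos, gabab_pos = [], []
    for p in prim:
        n_sec = cascade.secondaries_per_primary
        kinds = rng.random(n_sec) < 0.5
        for is_gabab in kinds:
            if is_gabab:
                sd = cascade.displacement_sd(rng, 1)[0]
                gabab_pos.append(p + rng.normal(scale=sd, size=2))
            else:
                girk_pos.append(p.copy())
    if not girk_pos or not gabab_pos:
        return np.empty(0)
    tree = cKDTree(np.asarray(girk_pos))
    d, _ = tree.query(np.asarray(gabab_pos))
    return np.asarray(d)


@dataclass
class PlacementCalibration:
    delay_ms: float
    forward_rate: float
    energy: float          # final K-S distance to the target
    energy_history: list   # best-so-far energy per epoch (nonincreasing)
    passed: bool


def calibrate_cluster_placement(
    target_distances,
    init: CascadeParams = None,
    max_epochs: int = 80,
    n_primaries: int = 100,
    n_eval: int = 3,
    seed: int = 0,
    t0: float = 0.2,
    cooling: float = 0.93,
    energy_tol: float = None,
) -> PlacementCalibration:
    """Anneal (delay, forward rate) to match a cluster-distance target.

    The energy is the two-sample K-S statistic between realized and
    target receptor-to-channel distance distributions on a flat test
    surface, averaged over ``n_eval`` independent cascade simulations so
    the annealer does not overfit sampling noise. Raises
    :class:`CalibrationError` with the best-so-far parameters if the
    energy never reaches ``energy_tol`` (default: the K-S critical D at
    alpha = 0.05 for the two sample sizes).
    """
    target = np.asarray(target_distances, dtype=float)
    if target.size == 0:
        raise ConfigurationError("target distance distribution is empty")
    from ..morphology import ks_two_sample

    init = init or CascadeParams()
    rng = np.random.default_rng(seed)

    def energy(params, ep):
        ds = []
        for _ in range(n_eval):
            d = simulate_flat_cascade(params, n_primaries=n_primaries,
                                      seed=int(rng.integers(2**31 - 1)))
            ds.append(ks_two_sample(d, target)[0] if d.size else 1.0)
        return float(np.mean(ds))

    current = init
    e_cur = energy(current, 0)
    best = (current, e_cur)
    history = [e_cur]
    temp = t0
    if energy_tol is None:
        # asymptotic two-sample K-S critical value at alpha = 0.05
        n_eff = target.size / 2.0
        energy_tol = 1.358 * math.sqrt(2.0 / n_eff)
    for ep in range(1, max_epochs + 1):
        if best[1] <= energy_tol:
            break
        cand = CascadeParams(
            delay_ms=max(1e-3, current.delay_ms * rng.lognormal(0, 0.4)),
            forward_rate=float(np.clip(current.forward_rate * rng.lognormal(0, 0.4),
                                       1e-4, 1e3)),
            d_seed=current.d_seed,
            secondaries_per_primary=current.secondaries_per_primary,
        )
        e_new = energy(cand, ep)
        if e_new < e_cur or rng.random() < math.exp(-(e_new - e_cur) / max(temp, 1e-9)):
            current, e_cur = cand, e_new
        if e_cur < best[1]:
            best = (current, e_cur)
        history.append(best[1])
        temp *= cooling
    passed = best[1] <= energy_tol
    result = PlacementCalibration(
        delay_ms=best[0].delay_ms,
        forward_rate=best[0].forward_rate,
        energy=best[1],
        energy_history=history,
        passed=passed,
    )
    if not passed:
        raise CalibrationError(
            f"placement calibration stalled at K-S D = {best[1]:.3g} "
            f"(tolerance {energy_tol:.3g})",
            best=result,
        )
    return result
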