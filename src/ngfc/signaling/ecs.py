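"""Extracellular-space (ECS) lattice: volume fraction and tortuosity.

The ECS is modeled as a periodic array of solid cuboid cells separated by
a thin fluid gap; each cuboid carries a dead-end cavity opening on one
face. The gaps form the connected extracellular pathway; the cavities
act as dead-space microdomains that retard diffusion, raising tortuosity
well above that of gap-only geometries.

Defaults (µm): cuboid edge 0.8, cavity 0.4 x 0.4 opening with depth
0.34, gap 0.032 — the analytic extracellular volume fraction of this
geometry is ~0.205 and random-walk tortuosity ~1.6, matching cortical
tissue. Cavity opening orientations alternate deterministically from
cell to cell so the medium is isotropic on average.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

import numpy as np

from ..errors import ConfigurationError, GeometryError

__all__ = ["EcsLattice", "TortuosityResult", "estimate_tortuosity"]


@dataclass
class EcsLattice:
    """Periodic cuboid-with-cavity lattice (all lengths µm)."""

    cuboid_edge: float = 0.8
    cavity_width: float = 0.4
    cavity_depth: float = 0.34
    gap: float = 0.032
    bounding_box: tuple = (13.28, 13.28, 6.592)

    def __post_init__(self):
        if self.cuboid_edge <= 0 or self.gap < 0:
            raise GeometryError("cuboid edge must be positive and gap >= 0")
        if self.cavity_width < 0 or self.cavity_depth < 0:
            raise GeometryError("cavity dimensions must be >= 0")
        if self.cavity_width > self.cuboid_edge or self.cavity_depth > self.cuboid_edge:
            raise GeometryError("cavity must fit inside the cuboid")

    @property
    def period(self) -> float:
        """Lattice period: one cuboid plus one gap."""
        return self.cuboid_edge + self.gap

    @property
    def cavity_volume(self) -> float:
        return self.cavity_width**2 * self.cavity_depth

    @property
    def volume_fraction(self) -> float:
        """Analytic extracellular volume fraction alpha.

        Extracellular = gap volume + cavity volume per unit cell, divided
        by the unit-cell volume.
        """
        cell = self.period**3
        solid = self.cuboid_edge**3 - self.cavity_volume
        return (cell - solid) / cell

    @property
    def domain_volume(self) -> float:
        """Total simulation-domain volume from the bounding box, µm³."""
        return float(np.prod(self.bounding_box))

    # -- geometry queries ----------------------------------------------------

    def _cavity_axis_sign(self, ci, cj, ck):
        """Deterministic pseudo-random cavity orientation per cell."""
        s = ci + cj + ck
        axis = s % 3
        sign = np.where((ci * 3 + cj * 5 + ck * 7) % 2 == 0, 1, -1)
        return axis, sign

    def inside_solid(self, points: np.ndarray) -> np.ndarray:
        """True where a point lies inside solid (cuboid minus its cavity)."""
        points = np.atleast_2d(np.asarray(points, dtype=float))
        L = self.period
        cell_idx = np.floor(points / L).astype(np.int64)
        local = points - cell_idx * L  # in [0, L)
        g2 = self.gap / 2.0
        in_cuboid = np.all((local >= g2) & (local < g2 + self.cuboid_edge), axis=1)

        axis, sign = self._cavity_axis_sign(cell_idx[:, 0], cell_idx[:, 1], cell_idx[:, 2])
        half_w = self.cavity_width / 2.0
        center = g2 + self.cuboid_edge / 2.0
        in_cavity = np.ones(points.shape[0], dtype=bool)
        for ax in range(3):
            coord = local[:, ax]
            is_depth_axis = axis == ax
            # transverse extent: centered square of cavity_width
            trans_ok = np.abs(coord - center) <= half_w
            # depth extent: from the opening face inward by cavity_depth
            hi_face = g2 + self.cuboid_edge
            depth_pos = np.where(sign > 0, hi_face - coord, coord - g2)
            depth_ok = (depth_pos >= 0) & (depth_pos <= self.cavity_depth)
            in_cavity &= np.where(is_depth_axis, depth_ok, trans_ok)
        return in_cuboid & ~in_cavity

    def sample_extracellular(self, n: int, rng) -> np.ndarray:
        """Uniform random points in the extracellular space of one period."""
        out = np.empty((n, 3))
        filled = 0
        while filled < n:
            cand = rng.random((2 * (n - filled) + 16, 3)) * self.period
            ok = ~self.inside_solid(cand)
            take = cand[ok][: n - filled]
            out[filled : filled + take.shape[0]] = take
            filled += take.shape[0]
        return out


class TortuosityResult(NamedTuple):
    tortuosity: float        # lambda = sqrt(D_free / D_eff)
    d_eff: float
    d_free: float
    msd_times: np.ndarray    # in step units
    msd: np.ndarray
    converged: bool


def estimate_tortuosity(
    lattice: EcsLattice,
    n_walkers: int = 4000,
    n_steps: int = 100000,
    step_size: float = 0.009,
    seed: int = 0,
    n_checkpoints: int = 60,
) -> TortuosityResult:
    """Random-walk estimate of the lattice tortuosity.

    Point walkers start uniformly in the extracellular space and take
    fixed-length steps in uniformly random directions; steps that would
    end inside solid are rejected (the walker waits), which reproduces
    obstructed diffusion in the long-time limit. The effective diffusion
    coefficient comes from a linear fit to the mean-squared displacement
    over the second half of the walk, and

        lambda = sqrt(D_free / D_eff).

    ``step_size`` must resolve the narrowest fluid feature (the default
    0.009 µm is well below the 0.032 µm gap; the residual step-size bias
    inflates the estimate slightly and shrinks as the step is refined). Times are reported in step
    units with D_free = step_size² / 6 per step.
    """
    if step_size <= 0 or step_size > lattice.gap:
        raise ConfigurationError("step_size must be positive and below the gap width")
    rng = np.random.default_rng(seed)
    pos = lattice.sample_extracellular(n_walkers, rng)
    start = pos.copy()

    check_every = max(1, n_steps // n_checkpoints)
    msd_t, msd = [], []
    for s in range(1, n_steps + 1):
        d = rng.normal(size=(n_walkers, 3))
        d *= step_size / np.linalg.norm(d, axis=1)[:, None]
        trial = pos + d
        blocked = lattice.inside_solid(trial)
        pos[~blocked] = trial[~blocked]
        if s % check_every == 0:
            disp = pos - start
            msd_t.append(s)
            msd.append(float(np.mean(np.einsum("ij,ij->i", disp, disp))))
    msd_t = np.asarray(msd_t, dtype=float)
    msd = np.asarray(msd, dtype=float)

    half = msd_t >= msd_t[-1] / 2.0
    slope = np.polyfit(msd_t[half], msd[half], 1)[0]
    d_eff = slope / 6.0
    d_free = step_size**2 / 6.0
    lam = float(np.sqrt(d_free / max(d_eff, 1e-300)))

    # convergence: the walk must have explored several lattice periods
    converged = bool(np.sqrt(msd[-1]) > 2.0 * lattice.period)
    if not converged:
        import warnings

        warnings.warn("MSD has not reached several lattice periods; "
                      "tortuosity estimate may be biased", stacklevel=2)
    return TortuosityResult(tortuosity=lam, d_eff=d_eff, d_free=d_free,
                            msd_times=msd_t, msd=msd, converged=converged)
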