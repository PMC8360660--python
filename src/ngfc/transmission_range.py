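"""Effective range of volume transmission from anatomy + quantal estimates.

Boutons of a presynaptic arbor are counted within increasing radial
distances from the postsynaptic dendrite; projecting the quantal estimate
of the number of functional release sites onto these cumulative count
curves inverts them into a radius interval — the putative reach of
nonsynaptic GABA action. A correlation-vs-radius scan identifies the
distance at which anatomical bouton counts best predict the functional
site counts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .errors import ConfigurationError, GeometryError, StatisticsError
from .morphology import AxonMorphology

__all__ = [
    "BoutonCountCurve",
    "count_boutons_near_dendrite",
    "RangeEstimate",
    "estimate_range",
    "correlation_vs_radius",
    "point_polyline_distance",
    "DEFAULT_RADII",
]

#: default radial grid, µm
DEFAULT_RADII = np.arange(0.25, 3.01, 0.25)


def point_polyline_distance(points: np.ndarray, polylines) -> np.ndarray:
    """Minimal Euclidean distance from each point to a set of polylines.

    ``polylines`` is a list of (k, 3) vertex arrays; distance is measured
    to the segment chain (not only to vertices).
    """
    points = np.asarray(points, dtype=float).reshape(-1, 3)
    segs_a, segs_b = [], []
    for pl in polylines:
        pl = np.asarray(pl, dtype=float).reshape(-1, 3)
        if pl.shape[0] == 1:
            segs_a.append(pl)
            segs_b.append(pl)
        elif pl.shape[0] > 1:
            segs_a.append(pl[:-1])
            segs_b.append(pl[1:])
    if not segs_a:
        raise GeometryError("empty dendrite: no polyline vertices")
    a = np.vstack(segs_a)                     # (S, 3)
    b = np.vstack(segs_b)
    ab = b - a
    denom = np.einsum("ij,ij->i", ab, ab)     # (S,)
    out = np.empty(points.shape[0])
    for chunk in np.array_split(np.arange(points.shape[0]),
                                max(1, points.shape[0] // 2048 + 1)):
        p = points[chunk]                     # (M, 3)
        ap = p[:, None, :] - a[None, :, :]    # (M, S, 3)
        t = np.einsum("msj,sj->ms", ap, ab)
        with np.errstate(invalid="ignore", divide="ignore"):
            t = np.where(denom > 0, t / denom, 0.0)
        t = np.clip(t, 0.0, 1.0)
        proj = a[None, :, :] + t[:, :, None] * ab[None, :, :]
        d = np.linalg.norm(p[:, None, :] - proj, axis=2)
        out[chunk] = d.min(axis=1)
    return out


@dataclass
class BoutonCountCurve:
    """Cumulative bouton count within increasing radii of one connection."""

    radii: np.ndarray
    counts: np.ndarray
    pair_id: str = ""

    def __post_init__(self):
        self.radii = np.asarray(self.radii, dtype=float)
        self.counts = np.asarray(self.counts, dtype=float)
        if self.radii.size != self.counts.size:
            raise ConfigurationError("radii and counts must align")
        if np.any(np.diff(self.radii) <= 0):
            raise ConfigurationError("radii must be strictly increasing")
        if np.any(self.counts < 0) or np.any(np.diff(self.counts) < 0):
            raise ConfigurationError("counts must be nonnegative and nondecreasing")


def count_boutons_near_dendrite(
    pre: AxonMorphology,
    post_dendrite,
    radii=DEFAULT_RADII,
    dendrite_radius: float = 0.0,
    pair_id: str = "",
) -> BoutonCountCurve:
    """Count presynaptic boutons within each radial distance of a dendrite.

    ``post_dendrite`` is a list of polyline vertex arrays (µm). A bouton
    at distance exactly r counts at radius r (inclusive boundary). If
    ``dendrite_radius`` is given, distances are measured to the dendritic
    surface (centerline distance minus radius, floored at 0).
    """
    radii = np.asarray(radii, dtype=float)
    if np.any(np.diff(radii) <= 0):
        raise ConfigurationError("radii must be sorted ascending")
    if pre.bouton_xyz.shape[0] == 0:
        return BoutonCountCurve(radii=radii, counts=np.zeros_like(radii), pair_id=pair_id)
    d = point_polyline_distance(pre.bouton_xyz, post_dendrite)
    if dendrite_radius > 0:
        d = np.maximum(d - dendrite_radius, 0.0)
    counts = np.array([(d <= r + 1e-12).sum() for r in radii], dtype=float)
    return BoutonCountCurve(radii=radii, counts=counts, pair_id=pair_id)


def _invert_curve(curve: BoutonCountCurve, n_target: float):
    """Smallest radius at which the cumulative count reaches ``n_target``.

    Linear interpolation between the bracketing radii; returns
    ``(radius, flag)`` with flag ``"below_min"`` when the count at the
    smallest radius already exceeds the target, ``"above_max"`` when the
    curve never reaches it (open-ended upper bound).
    """
    r, c = curve.radii, curve.counts
    if n_target <= c[0]:
        return float(r[0]), "below_min"
    if n_target > c[-1]:
        return float(r[-1]), "above_max"
    j = int(np.searchsorted(c, n_target, side="left"))
    if c[j] == c[j - 1]:
        return float(r[j]), ""
    frac = (n_target - c[j - 1]) / (c[j] - c[j - 1])
    return float(r[j - 1] + frac * (r[j] - r[j - 1])), ""


@dataclass
class RangeEstimate:
    """Aggregated effective-range interval across connections (µm)."""

    lower: float
    upper: float
    per_pair: list      # (pair_id, lower, upper)
    flags: list         # per-pair tuple of boundary flags


def estimate_range(nfrs_mean: float, nfrs_sd: float, curves) -> RangeEstimate:
    """Invert bouton-count curves at Nfrs mean ± SD into a radius interval.

    Per connection, the monotone cumulative curve is inverted at
    ``nfrs_mean - nfrs_sd`` and ``nfrs_mean + nfrs_sd`` (clipped at 0);
    intervals are aggregated across connections as the mean of the
    endpoints.
    """
    if not curves:
        raise ConfigurationError("need at least one count curve")
    if nfrs_sd < 0:
        raise ConfigurationError("nfrs_sd must be >= 0")
    per_pair, flags = [], []
    for cv in curves:
        lo_t = max(nfrs_mean - nfrs_sd, 0.0)
        hi_t = nfrs_mean + nfrs_sd
        r_lo, f_lo = _invert_curve(cv, lo_t)
        r_hi, f_hi = _invert_curve(cv, hi_t)
        per_pair.append((cv.pair_id, r_lo, r_hi))
        flags.append((f_lo, f_hi))
    lower = float(np.mean([p[1] for p in per_pair]))
    upper = float(np.mean([p[2] for p in per_pair]))
    return RangeEstimate(lower=lower, upper=upper, per_pair=per_pair, flags=flags)


def correlation_vs_radius(nfrs_per_pair, counts_per_pair_per_radius, radii=None):
    """Pearson r between Nfrs and bouton counts at each radius.

    ``counts_per_pair_per_radius`` is (n_pairs, n_radii). Radii at which
    counts are constant across pairs are skipped (r undefined there) with
    a warning. Returns ``(r_by_radius, p_by_radius, best_radius)`` where
    best is the radius of maximal r (NaN-aware).
    """
    nfrs = np.asarray(nfrs_per_pair, dtype=float)
    counts = np.asarray(counts_per_pair_per_radius, dtype=float)
    if counts.ndim != 2 or counts.shape[0] != nfrs.size:
        raise ConfigurationError("counts must be (n_pairs, n_radii)")
    if nfrs.size < 3:
        raise StatisticsError("need >= 3 pairs for correlation")
    n_radii = counts.shape[1]
    radii = np.asarray(radii, dtype=float) if radii is not None else np.arange(n_radii, dtype=float)
    r_out = np.full(n_radii, np.nan)
    p_out = np.full(n_radii, np.nan)
    for j in range(n_radii):
        col = counts[:, j]
        if np.std(col) == 0:
            warnings.warn(f"constant counts at radius {radii[j]}; correlation undefined",
                          stacklevel=2)
            continue
        r_out[j], p_out[j] = stats.pearsonr(nfrs, col)
    if np.all(np.isnan(r_out)):
        raise StatisticsError("correlation undefined at every radius")
    best_radius = float(radii[np.nanargmax(r_out)])
    return r_out, p_out, best_radius
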