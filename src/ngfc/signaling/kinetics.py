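"""Reaction scheme, release schedule and the GABA distance profile.

The signaling cascade on the dendritic membrane:

* GABA (3D, extracellular) + R -> R*           (receptor activation)
* R* -> R                                       (deactivation)
* R* + G -> R* + Gbg                            (catalytic Gbg production)
* Gbg + GIRK site -> bound                      (cooperative gating; a
  channel opens when all four of its sites are occupied)
* bound -> Gbg                                  (unbinding)
* Gbg -> G                                      (reassociation with Ga)
* GABA -> (cleared)                             (first-order sink)

Rate constants are configuration entries with literature-scale defaults;
none is a measured quantity of this package.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from ..errors import ConfigurationError

__all__ = [
    "ReactionScheme",
    "ReleaseSchedule",
    "release_profile",
    "DEFAULT_ANCHORS",
    "GABA_DECAY_TAU_MS",
]

#: peak-concentration anchors of the distance-dependent release profile:
#: (distance µm, concentration µM)
DEFAULT_ANCHORS = ((0.0, 1000.0), (0.5, 60.0), (2.0, 1.0))

#: free-GABA decay time constant the clearance sink is calibrated to, ms
GABA_DECAY_TAU_MS = 11.52


def release_profile(distance, anchors=DEFAULT_ANCHORS):
    """Peak GABA concentration (µM) at a radial distance from a release site.

    Piecewise log-linear (exponential-segment) interpolation through the
    anchor points; beyond the last anchor the final exponential slope
    continues. Scalar or array input.
    """
    d = np.asarray(distance, dtype=float)
    if np.any(d < 0):
        raise ConfigurationError("distance must be >= 0")
    xs = np.array([a[0] for a in anchors], dtype=float)
    cs = np.array([a[1] for a in anchors], dtype=float)
    if np.any(np.diff(xs) <= 0) or np.any(np.diff(cs) >= 0):
        raise ConfigurationError("anchors must be strictly decreasing with distance")
    logc = np.log(cs)
    # extend the last segment's slope beyond the final anchor
    slope_last = (logc[-1] - logc[-2]) / (xs[-1] - xs[-2])
    out = np.where(
        d <= xs[-1],
        np.interp(d, xs, logc),
        logc[-1] + slope_last * (d - xs[-1]),
    )
    result = np.exp(out)
    return float(result) if np.isscalar(distance) else result


@dataclass
class ReactionScheme:
    """Rate constants and diffusion coefficients of the cascade.

    Units: bimolecular rates µm³/ms (3D) or µm²/ms (2D surface),
    unimolecular rates 1/ms, diffusion µm²/ms.
    """

    k_on: float = 0.02             # GABA + R, µm³/ms
    k_off: float = 0.02            # R* -> R, 1/ms
    k_cat: float = 0.3             # R* + G -> R* + Gbg, µm²/ms
    k_girk_on: float = 0.3         # Gbg + site, µm²/ms
    k_girk_off: float = 0.02       # 1/ms
    k_reassoc: float = 0.01        # Gbg -> G, 1/ms
    d_gaba: float = 0.5            # free GABA diffusion, µm²/ms
    d_gbg: float = 1e-4            # Gbg lateral diffusion, µm²/ms (0.1 µm²/s)
    d_cluster: float = 5e-5        # mobile receptor-cluster diffusion, µm²/ms
    gaba_sink: float = field(default=None)   # 1/ms; default from decay tau
    reaction_radius: float = 0.1   # encounter radius, µm
    tortuosity: float = 1.6        # scales D_gaba to its effective value

    def __post_init__(self):
        rates = (self.k_on, self.k_off, self.k_cat, self.k_girk_on,
                 self.k_girk_off, self.k_reassoc)
        if any(r < 0 for r in rates):
            raise ConfigurationError("rate constants must be >= 0")
        if self.reaction_radius <= 0:
            raise ConfigurationError("reaction_radius must be positive")
        if self.gaba_sink is None:
            self.gaba_sink = 1.0 / GABA_DECAY_TAU_MS

    @property
    def d_gaba_eff(self) -> float:
        """Effective GABA diffusion in tortuous tissue, D/lambda²."""
        return self.d_gaba / self.tortuosity**2

    @property
    def encounter_volume(self) -> float:
        return 4.0 / 3.0 * math.pi * self.reaction_radius**3

    @property
    def encounter_area(self) -> float:
        return math.pi * self.reaction_radius**2


@dataclass
class ReleaseSchedule:
    """Release-site positions and action-potential times.

    Default: 4 boutons at distances ~N(1.2, 0.7) µm from the dendrite
    surface, spikes at 100 Hz (10 ms apart).
    """

    site_positions: np.ndarray = None     # (n_sites, 3), µm
    ap_times: tuple = (0.0,)              # ms
    gaba_per_release: int = 2000          # particles per site per release
    anchors: tuple = DEFAULT_ANCHORS

    n_sites: int = 4
    distance_mean: float = 1.2
    distance_sd: float = 0.7

    def __post_init__(self):
        if self.site_positions is not None:
            self.site_positions = np.asarray(self.site_positions, dtype=float).reshape(-1, 3)
        if self.gaba_per_release < 0:
            raise ConfigurationError("gaba_per_release must be >= 0")
        if len(self.ap_times) and np.any(np.diff(self.ap_times) <= 0):
            raise ConfigurationError("ap_times must be strictly increasing")

    @classmethod
    def burst(cls, k: int, interval_ms: float = 10.0, **kwargs) -> "ReleaseSchedule":
        """k action potentials at the given interval (default 100 Hz)."""
        if k < 1:
            raise ConfigurationError("need at least one AP")
        return cls(ap_times=tuple(interval_ms * i for i in range(k)), **kwargs)

    def realize_sites(self, geometry, rng) -> np.ndarray:
        """Draw release-site positions around a dendrite.

        Sites are placed at random surface points displaced outward along
        the surface normal by a positive truncated-normal distance.
        """
        if self.site_positions is not None:
            return self.site_positions
        pts = geometry.sample_surface(self.n_sites, "shaft", rng)
        _, faces = geometry.nearest_face(pts)
        normals = geometry.mesh.face_normals[faces]
        dist = np.abs(rng.normal(self.distance_mean, self.distance_sd, self.n_sites))
        return pts + normals * dist[:, None]
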