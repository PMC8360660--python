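"""Ready-made simulator configurations.

The default problem sizes here are reduced relative to a full-scale
reconstruction-based run: a short dendrite stand-in, a few thousand GABA
particles per release and tens of clusters. They preserve the structure
of the cascade (distance-dependent release, tortuosity-scaled diffusion,
cluster stoichiometry, compartment labeling) at a cost of minutes per
run, and are the configurations exercised by the test-suite and the
reproduction script.

Receptor/channel densities and the GABA particle budget are calibrated
choices, not measured quantities: they are set so that a single release
activates a handful of receptors on the stand-in dendrite.
"""

from __future__ import annotations

import numpy as np

from ..errors import ConfigurationError
from ..synthetic_data import synth_dendrite
from .kinetics import ReactionScheme, ReleaseSchedule
from .placement import ClusterLayout

__all__ = ["scaled_demo", "paired_cluster_layout", "linearity_experiment"]


def paired_cluster_layout(
    geometry,
    n_pairs_per_compartment: int = 8,
    colocalized_offset: float = 0.05,
    segregated_offset: float = 0.6,
    gabab_size: int = 4,
    girk_size: int = 2,
    seed: int = 0,
) -> ClusterLayout:
    """Receptor/channel cluster pairs: colocalized on spines, segregated on
    the shaft.

    Mirrors the ultrastructural arrangement in which receptor-channel
    complexes colocalize on spines while being separated on dendritic
    shafts: each spine pair sits ``colocalized_offset`` µm apart, each
    shaft pair ``segregated_offset`` µm apart (along the surface).
    """
    rng = np.random.default_rng(seed)
    pos, types, sizes, comps, mobile = [], [], [], [], []
    for compartment, offset in (("spine", colocalized_offset),
                                ("shaft", segregated_offset)):
        anchors = geometry.sample_surface(n_pairs_per_compartment, compartment, rng)
        _, faces = geometry.nearest_face(anchors)
        normals = geometry.mesh.face_normals[faces]
        for a, n in zip(anchors, normals):
            # random tangent direction for the channel offset
            t = np.cross(n, rng.normal(size=3))
            t /= max(np.linalg.norm(t), 1e-12)
            girk_pos, _ = geometry.nearest_face((a + offset * t)[None, :])
            pos.extend([a, girk_pos[0]])
            types.extend(["gabab", "girk"])
            sizes.extend([gabab_size, girk_size])
            comps.extend([compartment, compartment])
            mobile.extend([True, False])
    return ClusterLayout(
        positions=np.asarray(pos),
        types=np.asarray(types, dtype=object),
        sizes=np.asarray(sizes, dtype=int),
        compartments=np.asarray(comps, dtype=object),
        mobile=np.asarray(mobile, dtype=bool),
    )


def linearity_experiment(n_seeds: int = 30, seed: int = 0, max_aps: int = 2):
    """Burst-summation linearity of GIRK recruitment at reduced scale.

    For each seed, the cascade is run once per AP count (1..``max_aps``,
    100 Hz spacing, matched post-release tail) on a fixed dendrite,
    cluster layout and release-site geometry; the deviation from the
    arithmetic sum is computed on the across-seed mean counts,

        dev_k = 100 * (mean opened_k - k * mean opened_1) / (k * mean opened_1).

    The configuration runs in the sparse-activation regime (per-receptor
    and per-channel hit probabilities well below one), which is the
    regime in which summation of volume-transmitted inhibition is
    near-linear. Returns ``(deviation_percent_by_k, counts_by_k)``.
    """
    from .simulate import run_simulation

    rng = np.random.default_rng(seed)
    geo = synth_dendrite(length=8.0, radius=0.5, n_spines=6, seed=seed)
    layout = paired_cluster_layout(
        geo, n_pairs_per_compartment=80, gabab_size=2, girk_size=4,
        colocalized_offset=0.2, segregated_offset=0.6, seed=seed + 1,
    )
    pts = geo.sample_surface(4, "shaft", rng)
    _, faces = geo.nearest_face(pts)
    sites = pts + geo.mesh.face_normals[faces] * np.abs(
        rng.normal(1.2, 0.7, 4))[:, None]
    scheme = ReactionScheme(k_on=0.0005, k_reassoc=0.05)
    counts = {k: [] for k in range(1, max_aps + 1)}
    base = int(rng.integers(2**31 - 1 - n_seeds))
    for s in range(n_seeds):
        for k in counts:
            sched = ReleaseSchedule(
                site_positions=sites,
                ap_times=tuple(10.0 * i for i in range(k)),
                gaba_per_release=400,
            )
            res = run_simulation(geo, layout, scheme, sched, dt=0.02,
                                 t_end=25.0 + 10.0 * (k - 1), seed=base + s,
                                 g_density=600.0, record_interval=1.0)
            counts[k].append(res.channels_opened["total"])
    m1 = float(np.mean(counts[1]))
    dev = {
        k: 100.0 * (float(np.mean(counts[k])) - k * m1) / (k * m1)
        for k in counts if k > 1
    }
    return dev, counts


def scaled_demo(
    n_aps: int = 1,
    seed: int = 0,
    dt: float = 0.02,
    t_end: float = 40.0,
    gaba_per_release: int = 800,
    n_pairs_per_compartment: int = 8,
):
    """Reduced-scale simulator configuration.

    Returns ``(geometry, layout, scheme, schedule, run_kwargs)`` ready
    for :func:`ngfc.signaling.run_simulation`. The dendrite is the
    synthetic spiny cylinder; release sites sit around it at the
    configured bouton distances; cluster pairs follow the
    colocalized-on-spine / segregated-on-shaft arrangement.
    """
    if n_aps < 1:
        raise ConfigurationError("n_aps must be >= 1")
    geometry = synth_dendrite(length=8.0, radius=0.5, n_spines=6, seed=seed)
    layout = paired_cluster_layout(
        geometry, n_pairs_per_compartment=n_pairs_per_compartment, seed=seed + 1
    )
    scheme = ReactionScheme()
    schedule = ReleaseSchedule.burst(n_aps, gaba_per_release=gaba_per_release)
    run_kwargs = dict(dt=dt, t_end=t_end, g_density=300.0, record_interval=0.2)
    return geometry, layout, scheme, schedule, run_kwargs
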