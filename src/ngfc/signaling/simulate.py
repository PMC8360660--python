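"""Particle-based stochastic simulation of the GABA_B -> Gbg -> GIRK cascade.

GABA is released as 3D Brownian particles around the dendrite, diffuses
with the tortuosity-corrected effective coefficient, and is cleared by a
first-order sink calibrated to the free-GABA decay time constant.
Receptor clusters (laterally mobile) and GIRK channel clusters
(immobile) live on the membrane together with a pool of immobile
G-protein heterotrimers; produced Gbg subunits diffuse laterally and
gate channels by sequential occupation of four binding sites per
channel.

Bimolecular events are resolved by reaction-radius sampling: a pair
within the encounter radius R reacts in a time step with probability
``k * dt / V_R`` (3D) or ``k * dt / A_R`` (surface), which reproduces
mass action in the well-mixed limit. Per-step event probabilities above
0.2 raise a stability error.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from ..errors import ConfigurationError, StabilityError
from .kinetics import ReactionScheme, ReleaseSchedule
from .placement import ClusterLayout

__all__ = [
    "SimResult",
    "SimSummary",
    "run_simulation",
    "summarize",
    "girk_summation_linearity",
]

COMPARTMENTS = ("shaft", "spine")
#: Gbg sites per channel; a channel opens when all four are occupied
SITES_PER_CHANNEL = 4


@dataclass
class SimResult:
    """Per-species time series and end-of-run activation totals."""

    times: np.ndarray                  # ms
    series: dict                       # name -> array aligned with times
    receptors_activated: dict          # compartment -> distinct count
    channels_opened: dict              # compartment -> distinct count
    totals: dict                       # conserved totals for invariant checks
    dt: float
    seed: int

    def check_conservation(self) -> bool:
        """Receptor/channel totals constant; G-pool partition conserved."""
        s = self.series
        g_sum = s["g_trimer"] + s["gbg_free"] + s["gbg_bound"]
        ok = np.all(g_sum == self.totals["g_total"])
        ok &= np.all(s["gabab_active_total"] <= self.totals["receptors"])
        ok &= np.all(s["girk_open_total"] <= self.totals["channels"])
        ok &= np.all(s["gbg_free"] + s["gbg_bound"] <= self.totals["g_total"])
        return bool(ok)


def _check_stability(scheme: ReactionScheme, dt: float):
    probs = {
        "k_on": scheme.k_on * dt / scheme.encounter_volume,
        "k_cat": scheme.k_cat * dt / scheme.encounter_area,
        "k_girk_on": scheme.k_girk_on * dt / scheme.encounter_area,
        "k_off": scheme.k_off * dt,
        "k_girk_off": scheme.k_girk_off * dt,
        "k_reassoc": scheme.k_reassoc * dt,
        "gaba_sink": scheme.gaba_sink * dt,
    }
    worst = max(probs, key=probs.get)
    if probs[worst] > 0.2:
        raise StabilityError(
            f"per-step event probability for {worst} is {probs[worst]:.3g} > 0.2; "
            "reduce dt or the rate constant"
        )


def _reflect(pos: np.ndarray, lo: np.ndarray, hi: np.ndarray):
    """Reflect positions into the box [lo, hi] (single bounce per axis)."""
    for ax in range(3):
        below = pos[:, ax] < lo[ax]
        pos[below, ax] = 2 * lo[ax] - pos[below, ax]
        above = pos[:, ax] > hi[ax]
        pos[above, ax] = 2 * hi[ax] - pos[above, ax]
        np.clip(pos[:, ax], lo[ax], hi[ax], out=pos[:, ax])
    return pos


def run_simulation(
    geometry,
    layout: ClusterLayout,
    scheme: ReactionScheme,
    schedule: ReleaseSchedule,
    dt: float = 1e-3,
    t_end: float = 50.0,
    seed: int = 0,
    g_density: float = 300.0,
    record_interval: float = 0.1,
    box: tuple = None,
    lattice=None,
    reproject_every: int = 100,
) -> SimResult:
    """Run the stochastic cascade simulation.

    Parameters
    ----------
    geometry : MembraneGeometry or None
        Dendritic surface; ``None`` selects planar mode (membrane =
        z = 0 plane spanned by the box, all clusters taken as given).
    layout : ClusterLayout
        Receptor and channel clusters on the membrane.
    scheme, schedule
        Rate constants / release sites and AP times.
    dt, t_end : float
        Time step and duration, ms.
    g_density : float
        G-protein heterotrimer surface density, 1/µm² (planar mode:
        trimers scattered over the box footprint at z = 0).
    box : (3, 2) or None
        Reflecting bounds for GABA; defaults to the lattice bounding box
        when given, else the geometry bounds with a 3 µm margin.
    lattice : EcsLattice, optional
        Used only for its bounding box; tortuosity enters through
        ``scheme.tortuosity``.
    """
    _check_stability(scheme, dt)
    rng = np.random.default_rng(seed)

    if box is not None:
        lo = np.asarray([b[0] for b in box], dtype=float)
        hi = np.asarray([b[1] for b in box], dtype=float)
    elif lattice is not None:
        lo = np.zeros(3)
        hi = np.asarray(lattice.bounding_box, dtype=float)
    elif geometry is not None:
        b = geometry.mesh.bounds
        lo, hi = b[0] - 3.0, b[1] + 3.0
    else:
        raise ConfigurationError("need a box in planar mode")

    # --- membrane species state ------------------------------------------
    n_cl = layout.n_clusters
    cl_pos = layout.positions.copy()
    is_gabab = layout.types == "gabab"
    is_girk = layout.types == "girk"
    size = layout.sizes.copy()
    comp = layout.compartments
    n_active = np.zeros(n_cl, dtype=int)        # gabab: active receptors
    n_virgin = size.copy()                      # gabab: never-activated receptors
    bound = np.zeros(n_cl, dtype=int)           # girk: occupied Gbg sites
    ever_open = np.zeros(n_cl, dtype=int)       # girk: distinct channels opened
    ever_act = np.zeros(n_cl, dtype=int)        # gabab: distinct receptors activated

    # --- G-protein pool ---------------------------------------------------
    if geometry is not None:
        areas = {c: geometry.area(c) for c in COMPARTMENTS}
        g_parts = []
        for c in COMPARTMENTS:
            n_g = int(round(g_density * areas[c]))
            if n_g:
                g_parts.append(geometry.sample_surface(n_g, c, rng))
        g_pos = np.vstack(g_parts) if g_parts else np.empty((0, 3))
    else:
        foot = (hi[0] - lo[0]) * (hi[1] - lo[1])
        n_g = int(round(g_density * foot))
        g_pos = np.column_stack([
            lo[0] + rng.random(n_g) * (hi[0] - lo[0]),
            lo[1] + rng.random(n_g) * (hi[1] - lo[1]),
            np.zeros(n_g),
        ])
    n_g_total = g_pos.shape[0]
    G_TRIMER, G_FREE, G_BOUND = 0, 1, 2
    g_state = np.zeros(n_g_total, dtype=np.int8)
    g_cluster = np.full(n_g_total, -1, dtype=int)   # girk cluster while bound

    # --- GABA -------------------------------------------------------------
    sites = schedule.realize_sites(geometry, rng) if geometry is not None else schedule.site_positions
    if sites is None:
        sites = np.empty((0, 3))
    gaba_pos = np.empty((0, 3))
    ap_queue = list(schedule.ap_times)

    # --- bookkeeping ------------------------------------------------------
    R = scheme.reaction_radius
    v_r = scheme.encounter_volume
    a_r = scheme.encounter_area
    p_off = -math.expm1(-scheme.k_off * dt)
    p_goff = -math.expm1(-scheme.k_girk_off * dt)
    p_reas = -math.expm1(-scheme.k_reassoc * dt)
    p_sink = -math.expm1(-scheme.gaba_sink * dt)
    p_on_pair = scheme.k_on * dt / v_r
    p_cat_pair = scheme.k_cat * dt / a_r
    p_gon_pair = scheme.k_girk_on * dt / a_r
    sigma_gaba = math.sqrt(2.0 * scheme.d_gaba_eff * dt)
    sigma_gbg = math.sqrt(2.0 * scheme.d_gbg * dt)
    sigma_cl = math.sqrt(2.0 * scheme.d_cluster * dt)

    girk_idx = np.flatnonzero(is_girk)
    girk_tree = cKDTree(cl_pos[girk_idx]) if girk_idx.size else None
    gabab_idx = np.flatnonzero(is_gabab)
    mobile_idx = np.flatnonzero(layout.mobile)

    g_hood = None          # cluster -> candidate trimer indices cache
    g_hood_refresh = 0
    n_steps = int(round(t_end / dt))
    rec_every = max(1, int(round(record_interval / dt)))
    times, rec = [], {k: [] for k in (
        "gaba_free", "gabab_active_total", "gabab_active_shaft", "gabab_active_spine",
        "g_trimer", "gbg_free", "gbg_bound",
        "girk_open_total", "girk_open_shaft", "girk_open_spine",
    )}

    def record(t):
        times.append(t)
        rec["gaba_free"].append(gaba_pos.shape[0])
        act = n_active[gabab_idx]
        rec["gabab_active_total"].append(int(act.sum()))
        for c in COMPARTMENTS:
            m = comp[gabab_idx] == c
            rec[f"gabab_active_{c}"].append(int(act[m].sum()))
        rec["g_trimer"].append(int(np.sum(g_state == G_TRIMER)))
        rec["gbg_free"].append(int(np.sum(g_state == G_FREE)))
        rec["gbg_bound"].append(int(np.sum(g_state == G_BOUND)))
        open_now = np.minimum(bound // SITES_PER_CHANNEL, size)
        rec["girk_open_total"].append(int(open_now[girk_idx].sum()))
        for c in COMPARTMENTS:
            m = comp[girk_idx] == c
            rec[f"girk_open_{c}"].append(int(open_now[girk_idx][m].sum()))

    record(0.0)
    for step in range(1, n_steps + 1):
        t = step * dt

        # releases scheduled in (t - dt, t]
        while ap_queue and ap_queue[0] < t:
            ap_queue.pop(0)
            if sites.shape[0] and schedule.gaba_per_release:
                puff = np.repeat(sites, schedule.gaba_per_release, axis=0)
                puff = puff + rng.normal(scale=0.05, size=puff.shape)
                gaba_pos = np.vstack([gaba_pos, _reflect(puff, lo, hi)])

        # GABA diffusion + clearance
        if gaba_pos.shape[0]:
            gaba_pos += rng.normal(scale=sigma_gaba, size=gaba_pos.shape)
            _reflect(gaba_pos, lo, hi)
            keep = rng.random(gaba_pos.shape[0]) >= p_sink
            gaba_pos = gaba_pos[keep]

        # GABA -> receptor activation (per-cluster binomial batching; the
        # within-step depletion correction is second order in dt)
        if gaba_pos.shape[0] and gabab_idx.size and p_on_pair > 0:
            rec_tree = cKDTree(cl_pos[gabab_idx])
            d_near, j_near = rec_tree.query(gaba_pos, k=1,
                                            distance_upper_bound=R)
            cand = np.flatnonzero(np.isfinite(d_near))
            consumed = np.zeros(gaba_pos.shape[0], dtype=bool)
            if cand.size:
                for jc in np.unique(j_near[cand]):
                    ci = gabab_idx[jc]
                    n_free = size[ci] - n_active[ci]
                    if n_free <= 0:
                        continue
                    members = cand[j_near[cand] == jc]
                    p_bind = 1.0 - (1.0 - p_on_pair) ** n_free
                    hits = members[rng.random(members.size) < p_bind]
                    n_new = min(hits.size, n_free)
                    if n_new == 0:
                        continue
                    n_from_virgin = rng.hypergeometric(
                        n_virgin[ci], n_free - n_virgin[ci], n_new
                    ) if n_virgin[ci] < n_free else n_new
                    n_virgin[ci] -= n_from_virgin
                    ever_act[ci] += n_from_virgin
                    n_active[ci] += n_new
                    consumed[hits[:n_new]] = True
            if consumed.any():
                gaba_pos = gaba_pos[~consumed]

        # receptor deactivation
        if p_off > 0:
            act_idx = np.flatnonzero(n_active > 0)
            if act_idx.size:
                n_active[act_idx] -= rng.binomial(n_active[act_idx], p_off)

        # Gbg production near active receptor clusters; per-cluster trimer
        # neighborhoods are cached (trimers are immobile, clusters drift
        # slowly) and refreshed every reproject interval
        act_cl = np.flatnonzero((n_active > 0) & is_gabab)
        if act_cl.size and p_cat_pair > 0:
            if g_hood is None or step >= g_hood_refresh:
                g_tree = cKDTree(g_pos)
                margin = 0.1 * R
                g_hood = {
                    int(ci): np.asarray(idx, dtype=int)
                    for ci, idx in zip(
                        gabab_idx,
                        g_tree.query_ball_point(cl_pos[gabab_idx], R + margin),
                    )
                }
                g_hood_refresh = step + 25
            for ci in act_cl:
                near_all = g_hood[int(ci)]
                if near_all.size == 0:
                    continue
                d2 = np.einsum("ij,ij->i", g_pos[near_all] - cl_pos[ci],
                               g_pos[near_all] - cl_pos[ci])
                near = near_all[(g_state[near_all] == G_TRIMER) & (d2 <= R * R)]
                if near.size == 0:
                    continue
                p_conv = 1.0 - (1.0 - p_cat_pair) ** n_active[ci]
                hits = near[rng.random(near.size) < p_conv]
                if hits.size:
                    g_state[hits] = G_FREE

        # Gbg lateral diffusion
        free = np.flatnonzero(g_state == G_FREE)
        if free.size:
            kick = rng.normal(scale=sigma_gbg, size=(free.size, 3))
            if geometry is None:
                kick[:, 2] = 0.0
            g_pos[free] += kick
            if geometry is not None and step % reproject_every == 0:
                g_pos[free], _ = geometry.nearest_face(g_pos[free])

        # Gbg -> GIRK binding (per-cluster binomial batching)
        if girk_tree is not None and free.size and p_gon_pair > 0:
            d_near, j_near = girk_tree.query(g_pos[free], k=1,
                                             distance_upper_bound=R)
            cand = np.flatnonzero(np.isfinite(d_near))
            for jc in np.unique(j_near[cand]) if cand.size else ():
                ci = girk_idx[jc]
                free_sites = SITES_PER_CHANNEL * size[ci] - bound[ci]
                if free_sites <= 0:
                    continue
                members = free[cand[j_near[cand] == jc]]
                p_bind = 1.0 - (1.0 - p_gon_pair) ** free_sites
                hits = members[rng.random(members.size) < p_bind][:free_sites]
                if hits.size == 0:
                    continue
                bound[ci] += hits.size
                g_state[hits] = G_BOUND
                g_cluster[hits] = ci
                g_pos[hits] = cl_pos[ci]
                open_now = min(bound[ci] // SITES_PER_CHANNEL, size[ci])
                if open_now > ever_open[ci]:
                    ever_open[ci] = open_now

        # Gbg unbinding
        if p_goff > 0 and girk_idx.size:
            n_un_all = rng.binomial(bound[girk_idx], p_goff)
            for jc in np.flatnonzero(n_un_all):
                ci = girk_idx[jc]
                n_un = n_un_all[jc]
                bnd = np.flatnonzero((g_state == G_BOUND) & (g_cluster == ci))
                rel = rng.choice(bnd, size=n_un, replace=False)
                g_state[rel] = G_FREE
                g_cluster[rel] = -1
                bound[ci] -= n_un

        # Gbg reassociation with Ga (back to heterotrimer, in place)
        free = np.flatnonzero(g_state == G_FREE)
        if free.size and p_reas > 0:
            back = free[rng.random(free.size) < p_reas]
            g_state[back] = G_TRIMER

        # mobile receptor clusters drift
        if mobile_idx.size and sigma_cl > 0:
            kick = rng.normal(scale=sigma_cl, size=(mobile_idx.size, 3))
            if geometry is None:
                kick[:, 2] = 0.0
            cl_pos[mobile_idx] += kick
            if geometry is not None and step % reproject_every == 0:
                cl_pos[mobile_idx], _ = geometry.nearest_face(cl_pos[mobile_idx])

        if step % rec_every == 0:
            record(t)

    series = {k: np.asarray(v) for k, v in rec.items()}
    receptors_activated = {c: int(ever_act[comp == c].sum()) for c in COMPARTMENTS}
    receptors_activated["total"] = int(ever_act.sum())
    channels_opened = {c: int(ever_open[(comp == c) & is_girk].sum()) for c in COMPARTMENTS}
    channels_opened["total"] = int(ever_open[is_girk].sum())
    totals = {
        "receptors": int(size[is_gabab].sum()),
        "channels": int(size[is_girk].sum()),
        "g_total": n_g_total,
    }
    return SimResult(
        times=np.asarray(times),
        series=series,
        receptors_activated=receptors_activated,
        channels_opened=channels_opened,
        totals=totals,
        dt=dt,
        seed=seed,
    )


@dataclass
class SimSummary:
    """Activation totals and compartment effectiveness of one run."""

    receptors_activated: dict
    channels_opened: dict
    peak_gbg: int
    gaba_decay_tau: float            # ms; nan if not measurable
    effectiveness: dict              # compartment -> opened/activated or None


def summarize(result: SimResult) -> SimSummary:
    """Totals, peak Gbg, free-GABA decay and per-compartment effectiveness.

    Effectiveness = distinct GIRK channels opened / distinct receptors
    activated; flagged ``None`` (undefined) for compartments with zero
    activated receptors.
    """
    if result.times.size == 0:
        raise ConfigurationError("empty simulation result")
    eff = {}
    for c in COMPARTMENTS:
        n_act = result.receptors_activated[c]
        eff[c] = (result.channels_opened[c] / n_act) if n_act > 0 else None

    # free-GABA decay: fit log-linear tail after the last release peak
    gaba = result.series["gaba_free"].astype(float)
    tau = float("nan")
    if gaba.max() > 0:
        i_pk = int(np.argmax(gaba))
        tail = gaba[i_pk:]
        pos = tail > max(1.0, 0.01 * tail[0])
        if pos.sum() > 3:
            tt = result.times[i_pk:][pos]
            slope = np.polyfit(tt, np.log(tail[pos]), 1)[0]
            if slope < 0:
                tau = float(-1.0 / slope)
    gbg_total = result.series["gbg_free"] + result.series["gbg_bound"]
    return SimSummary(
        receptors_activated=dict(result.receptors_activated),
        channels_opened=dict(result.channels_opened),
        peak_gbg=int(gbg_total.max()),
        gaba_decay_tau=tau,
        effectiveness=eff,
    )


def girk_summation_linearity(results: dict) -> dict:
    """Deviation of burst GIRK recruitment from the arithmetic sum.

    ``results`` maps AP count k -> SimResult (must include k = 1). For
    each k > 1 and scope (total / shaft / spine),

        deviation_k = 100 * (opened_k - k * opened_1) / (k * opened_1)  [%].

    Scopes where the single-AP run opened no channel are flagged None.
    """
    if 1 not in results:
        raise ConfigurationError("need a 1-AP reference result")
    ref = results[1].channels_opened
    out = {}
    for k, res in sorted(results.items()):
        if k == 1:
            continue
        dev = {}
        for scope in ("total", *COMPARTMENTS):
            o1 = ref[scope]
            ok = res.channels_opened[scope]
            dev[scope] = (100.0 * (ok - k * o1) / (k * o1)) if o1 > 0 else None
        out[k] = dev
    return out
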