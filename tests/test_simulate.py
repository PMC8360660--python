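"""Simulator invariants: conservation, limiting behaviors, summaries."""

import math

import numpy as np
import pytest

from ngfc.errors import ConfigurationError, StabilityError
from ngfc.signaling import (
    ClusterLayout,
    ReactionScheme,
    ReleaseSchedule,
    SimResult,
    girk_summation_linearity,
    run_simulation,
    summarize,
)

BOX = ((0.0, 3.0), (0.0, 3.0), (0.0, 3.0))


def planar_layout(n_gabab=6, n_girk=6, seed=0):
    rng = np.random.default_rng(seed)
    n = n_gabab + n_girk
    pos = np.column_stack([rng.random(n) * 3.0, rng.random(n) * 3.0, np.zeros(n)])
    types = np.array(["gabab"] * n_gabab + ["girk"] * n_girk, dtype=object)
    sizes = np.where(types == "gabab", 4, 2)
    comps = np.array(["shaft"] * n, dtype=object)
    mobile = types == "gabab"
    return ClusterLayout(positions=pos, types=types, sizes=sizes,
                         compartments=comps, mobile=mobile)


def planar_run(scheme=None, schedule=None, layout=None, seed=0, t_end=5.0,
               dt=0.02, g_density=30.0):
    scheme = scheme or ReactionScheme(k_on=0.001)
    if schedule is None:
        sites = np.array([[1.5, 1.5, 1.0]])
        schedule = ReleaseSchedule(site_positions=sites, ap_times=(0.0,),
                                   gaba_per_release=300)
    layout = layout if layout is not None else planar_layout()
    return run_simulation(None, layout, scheme, schedule, dt=dt, t_end=t_end,
                          seed=seed, g_density=g_density, box=BOX)


class TestLimitingBehaviors:
    def test_no_release_means_no_activation(self):
        sched = ReleaseSchedule(site_positions=np.empty((0, 3)), ap_times=(0.0,),
                                gaba_per_release=0)
        res = planar_run(schedule=sched)
        assert res.receptors_activated["total"] == 0
        assert res.channels_opened["total"] == 0
        assert np.all(res.series["gaba_free"] == 0)

    def test_zero_rates_leave_receptors_silent_while_gaba_decays(self):
        scheme = ReactionScheme(k_on=0.0, k_cat=0.0, k_girk_on=0.0)
        res = planar_run(scheme=scheme, t_end=30.0)
        assert res.receptors_activated["total"] == 0
        gaba = res.series["gaba_free"]
        # the puff is never consumed by binding, only by the sink
        assert gaba.max() >= 300 * math.exp(-0.0868 * 0.2)
        assert gaba[-1] < 0.5 * gaba.max()

    def test_gaba_count_nonincreasing_between_releases(self):
        res = planar_run(t_end=10.0)
        gaba = res.series["gaba_free"]
        # single release at t=0: strictly nonincreasing after the puff
        assert np.all(np.diff(gaba[1:]) <= 0)

    def test_too_coarse_time_step_rejected(self):
        with pytest.raises(StabilityError):
            planar_run(scheme=ReactionScheme(k_cat=0.5), dt=0.1)


class TestConservation:
    def test_invariants_hold_throughout_a_run(self):
        res = planar_run(t_end=10.0, seed=3)
        assert res.check_conservation()

    def test_more_aps_recruit_at_least_as_many_receptors(self):
        acts = []
        for k in (1, 2):
            sites = np.array([[1.5, 1.5, 0.5]])
            sched = ReleaseSchedule(site_positions=sites,
                                    ap_times=tuple(10.0 * i for i in range(k)),
                                    gaba_per_release=300)
            per_seed = [
                planar_run(schedule=sched, seed=s, t_end=15.0 + 10 * (k - 1))
                .receptors_activated["total"]
                for s in range(3)
            ]
            acts.append(np.mean(per_seed))
        assert acts[1] >= acts[0]


class TestSummaries:
    def fake_result(self, activated, opened):
        times = np.arange(5.0)
        series = {k: np.zeros(5, dtype=int) for k in (
            "gaba_free", "gabab_active_total", "gabab_active_shaft",
            "gabab_active_spine", "g_trimer", "gbg_free", "gbg_bound",
            "girk_open_total", "girk_open_shaft", "girk_open_spine")}
        return SimResult(
            times=times, series=series,
            receptors_activated=activated, channels_opened=opened,
            totals={"receptors": 100, "channels": 100, "g_total": 0},
            dt=0.02, seed=0,
        )

    def test_effectiveness_is_opened_over_activated(self):
        res = self.fake_result(
            {"shaft": 10, "spine": 0, "total": 10},
            {"shaft": 5, "spine": 0, "total": 5})
        s = summarize(res)
        assert s.effectiveness["shaft"] == pytest.approx(0.5)

    def test_zero_activation_flags_undefined_effectiveness(self):
        res = self.fake_result(
            {"shaft": 0, "spine": 4, "total": 4},
            {"shaft": 0, "spine": 2, "total": 2})
        s = summarize(res)
        assert s.effectiveness["shaft"] is None
        assert s.effectiveness["spine"] == pytest.approx(0.5)

    def test_linearity_of_exact_doubling_is_zero(self):
        r1 = self.fake_result({"total": 5, "shaft": 2, "spine": 3},
                              {"total": 4, "shaft": 2, "spine": 2})
        r2 = self.fake_result({"total": 10, "shaft": 4, "spine": 6},
                              {"total": 8, "shaft": 4, "spine": 4})
        dev = girk_summation_linearity({1: r1, 2: r2})
        assert dev[2]["total"] == pytest.approx(0.0)

    def test_five_percent_shortfall(self):
        r1 = self.fake_result({"total": 5, "shaft": 5, "spine": 0},
                              {"total": 4, "shaft": 4, "spine": 0})
        r2 = self.fake_result({"total": 9, "shaft": 9, "spine": 0},
                              {"total": 7.6, "shaft": 7.6, "spine": 0})
        dev = girk_summation_linearity({1: r1, 2: r2})
        assert dev[2]["total"] == pytest.approx(-5.0)
        assert dev[2]["spine"] is None

    def test_missing_reference_rejected(self):
        r2 = self.fake_result({"total": 1, "shaft": 1, "spine": 0},
                              {"total": 1, "shaft": 1, "spine": 0})
        with pytest.raises(ConfigurationError):
            girk_summation_linearity({2: r2})


class TestDeterminism:
    def test_same_seed_reproduces_series(self):
        a = planar_run(seed=11, t_end=5.0)
        b = planar_run(seed=11, t_end=5.0)
        for key in a.series:
            assert np.array_equal(a.series[key], b.series[key])
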