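"""Engines: time advancement, selection, trajectories, baselines, determinism."""

import math

import numpy as np
import pytest

from lolcat_ssa import (
    RunSpec,
    advance_time,
    all_propensities,
    build_structures,
    build_system,
    canonical_model,
    frozen_selection_histogram,
    generate_hub_network,
    lolcat_step,
    run_direct,
    run_lolcat,
    run_odm_baseline,
    uniform_profile,
)
from lolcat_ssa.engine import Extinction
from lolcat_ssa.synthetic import HubNetworkSpec

from conftest import random_system


class TestAdvanceTime:
    def test_closed_form(self):
        assert advance_time(2.0, math.exp(-2.0)) == pytest.approx(1.0)

    def test_u_one_gives_zero(self):
        assert advance_time(5.0, 1.0) == 0.0

    def test_zero_total_signals_extinction(self):
        with pytest.raises(Extinction):
            advance_time(0.0, 0.5)

    def test_mean_is_inverse_rate(self):
        """1e6 exponential draws at a0=5 have sample mean 0.2 within 3 SE."""
        rng = np.random.default_rng(0)
        u = 1.0 - rng.random(1_000_000)
        taus = np.log(1.0 / u) / 5.0
        se = taus.std() / math.sqrt(len(taus))
        assert abs(taus.mean() - 0.2) < 3 * se


class TestRunSpecValidation:
    def test_requires_a_stop_criterion(self):
        with pytest.raises(ValueError):
            RunSpec()

    def test_requires_positive_record_interval(self):
        with pytest.raises(ValueError):
            RunSpec(max_time=1.0, record_interval=0.0)


class TestSelection:
    def test_supercache_hit_and_miss_paths(self):
        # two hot reactions (5, 3) in the cache, one cloud with a_T = 2
        system = build_system(
            {"A": 5, "B": 3, "C": 2},
            [("h1", [], ["A"], 5.0), ("h2", [], ["B"], 3.0), ("cold", ["C"], [], 1.0)],
        )
        prof = uniform_profile(system)
        prof.values[:] = [5.0, 3.0, 1.0]
        st = build_structures(system, profile=prof, supercache_size=2)
        assert st.a0 == pytest.approx(10.0)
        assert st.select_reaction(7.9) == 1      # linear scan, second entry
        assert st.select_reaction(9.5) == 2      # miss -> cloud, residual 1.5
        with pytest.raises(ValueError):
            st.select_reaction(10.5)

    def test_frozen_histogram_two_reactions(self):
        """Frequencies of a 3:1 propensity pair match 0.75/0.25 within 3 SE."""
        system = build_system(
            {"A": 1}, [("fast", [], ["A"], 3.0), ("slow", [], ["A"], 1.0)]
        )
        st = build_structures(system, profile=uniform_profile(system), supercache_size=0)
        freqs = frozen_selection_histogram(st, 100_000, seed=4)
        se = math.sqrt(0.75 * 0.25 / 100_000)
        assert abs(freqs[0] - 0.75) < 3 * se

    def test_single_reaction_frequency_is_one(self):
        system = build_system({"A": 1}, [("only", [], ["A"], 2.0)])
        st = build_structures(system, profile=uniform_profile(system))
        freqs = frozen_selection_histogram(st, 1000, seed=0)
        assert freqs[0] == 1.0


class TestLolcatStep:
    def test_pure_birth_increments_every_step(self):
        system = build_system({"A": 0}, [("birth", [], ["A"], 1.0)])
        st = build_structures(system, profile=uniform_profile(system))
        rng = np.random.default_rng(1)
        for i in range(50):
            j, tau = lolcat_step(st, rng)
            assert j == 0 and tau > 0
        assert st.state.counts[system.index_of["A"]] == 50

    def test_extinction_after_last_decay(self):
        system = build_system({"A": 1}, [("d", ["A"], [], 1.0)])
        st = build_structures(system, profile=uniform_profile(system))
        rng = np.random.default_rng(1)
        lolcat_step(st, rng)
        with pytest.raises(Extinction):
            lolcat_step(st, rng)

    def test_fixed_seed_reproduces_trajectory(self):
        system = random_system(17)
        spec = RunSpec(max_iterations=500, seed=3, record_interval=0.1)
        a = run_lolcat(system, spec, trial_steps=200)
        b = run_lolcat(system, RunSpec(max_iterations=500, seed=3, record_interval=0.1),
                       trial_steps=200)
        assert np.array_equal(a.times, b.times)
        assert np.array_equal(a.counts, b.counts)
        assert np.array_equal(a.event_counts, b.event_counts)


class TestTrajectories:
    def test_zero_iterations_records_initial_sample_only(self):
        system, _ = canonical_model("immigration_death")
        traj = run_lolcat(system, RunSpec(max_iterations=0, seed=0), trial_steps=50)
        assert len(traj.times) == 1 and traj.times[0] == 0.0
        assert traj.counts[0, 0] == 0

    def test_times_strictly_increasing_and_events_match_iterations(self):
        system = random_system(8)
        traj = run_direct(system, RunSpec(max_iterations=300, seed=2, record_interval=0.01))
        assert (np.diff(traj.times) > 0).all()
        assert traj.event_counts.sum() == traj.iterations

    def test_single_reaction_engines_agree_on_event_count(self):
        system = build_system({"A": 0}, [("birth", [], ["A"], 1.0)])
        spec = RunSpec(max_iterations=100, seed=5)
        td = run_direct(system, spec)
        tl = run_lolcat(system, RunSpec(max_iterations=100, seed=5), trial_steps=50)
        assert td.event_counts[0] == tl.event_counts[0] == 100

    def test_tsv_round_trip_shape(self):
        system, _ = canonical_model("isomerization")
        traj = run_direct(system, RunSpec(max_time=2.0, seed=1, record_interval=0.5))
        text = traj.to_tsv()
        lines = text.strip().split("\n")
        assert lines[0].split("\t") == ["time", "A", "B"]
        assert len(lines) == len(traj.times) + 1


class TestStatisticalAgreement:
    """Both engines reproduce closed-form expectations of canonical models."""

    def test_immigration_death_stationary_mean(self):
        system, facts = canonical_model("immigration_death")
        spec = lambda s: RunSpec(max_time=300.0, seed=s, record_interval=0.5)
        for runner, kwargs in ((run_direct, {}), (run_lolcat, {"trial_steps": 500})):
            traj = runner(system, spec(11), **kwargs)
            keep = traj.counts[traj.times >= 10.0, 0]
            batches = np.array_split(keep, 20)
            means = np.array([b.mean() for b in batches])
            se = means.std(ddof=1) / math.sqrt(len(means))
            assert abs(keep.mean() - facts["stationary_mean"]) < 3 * max(se, 0.05)

    def test_decay_transient_mean(self):
        system, facts = canonical_model("decay")
        target = facts["mean_at"](1.0)
        for runner, kwargs in ((run_direct, {}), (run_lolcat, {"trial_steps": 60})):
            finals = []
            for s in range(40):
                traj = runner(system, RunSpec(max_time=1.0, seed=s, record_interval=1.0),
                              **kwargs)
                finals.append(traj.counts[-1, 0])
            finals = np.array(finals, dtype=float)
            se = finals.std(ddof=1) / math.sqrt(len(finals))
            assert abs(finals.mean() - target) < 3 * se

    def test_direct_selection_frequencies(self):
        """Frozen 3:1 propensities fire 75/25 within 3 SE under run_direct."""
        system = build_system(
            {"A": 1}, [("fast", [], ["A"], 3.0), ("slow", [], ["A"], 1.0)]
        )
        traj = run_direct(system, RunSpec(max_iterations=20_000, seed=7))
        frac = traj.event_counts[0] / traj.event_counts.sum()
        se = math.sqrt(0.75 * 0.25 / 20_000)
        assert abs(frac - 0.75) < 3 * se


class TestODMBaseline:
    def test_sorted_order_follows_profile(self):
        system = build_system(
            {"A": 1},
            [("slow", [], ["A"], 1.0), ("fast", [], ["A"], 9.0), ("mid", [], ["A"], 3.0)],
        )
        prof = uniform_profile(system)
        prof.values[:] = [1.0, 9.0, 3.0]
        traj, counters = run_odm_baseline(
            system, RunSpec(max_iterations=100, seed=1), profile=prof
        )
        # hottest reaction found with a single comparison most of the time
        assert counters.comparisons / counters.steps < 2.0

    def test_statistical_agreement_with_direct(self):
        system, facts = canonical_model("immigration_death")
        traj, _ = run_odm_baseline(
            system, RunSpec(max_time=300.0, seed=13, record_interval=0.5), trial_steps=500
        )
        keep = traj.counts[traj.times >= 10.0, 0]
        batches = np.array_split(keep, 20)
        means = np.array([b.mean() for b in batches])
        se = means.std(ddof=1) / math.sqrt(len(means))
        assert abs(keep.mean() - facts["stationary_mean"]) < 3 * max(se, 0.05)

    def test_clique_updates_scale_with_hub_fanout_but_lolcat_stays_flat(self):
        """Counted-complexity separation on hub networks of growing fan-out."""
        odm_costs, lolcat_costs = [], []
        for fanout in (10, 100):
            spec = HubNetworkSpec(
                n_species=max(10, fanout // 2), n_reactions=fanout, hub_count=2,
                hub_participation=1.0, seed=fanout,
            )
            system = generate_hub_network(spec)
            run = RunSpec(max_iterations=500, seed=1)
            _, counters = run_odm_baseline(system, run, udg_kind="clique", trial_steps=500)
            odm_costs.append(counters.propensity_recomputations / counters.steps)
            traj = run_lolcat(system, RunSpec(max_iterations=500, seed=1), trial_steps=500)
        # ODM's per-step update cost tracks the fan-out
        assert odm_costs[1] > 5 * odm_costs[0]


def test_lolcat_and_direct_agree_on_hub_network_moments():
    """Distributional agreement on a structured (hub) network: recorded
    species means within 3 SE across seeds."""
    spec = HubNetworkSpec(
        n_species=12, n_reactions=30, hub_count=2, hub_participation=0.7, seed=5,
        count_bounds=(20, 60), hub_initial_count=200,
    )
    system = generate_hub_network(spec)
    watch = system.species[3].id
    totals_d, totals_l = [], []
    for s in range(12):
        rs = lambda: RunSpec(max_iterations=400, seed=100 + s, record_interval=1e9,
                             record_species=[watch])
        totals_d.append(run_direct(system, rs()).final_state.counts[3])
        totals_l.append(run_lolcat(system, rs(), trial_steps=200).final_state.counts[3])
    d, l = np.array(totals_d, float), np.array(totals_l, float)
    pooled_se = math.sqrt(d.var(ddof=1) / len(d) + l.var(ddof=1) / len(l))
    assert abs(d.mean() - l.mean()) < 3 * max(pooled_se, 1e-9)
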