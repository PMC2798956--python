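"""Preprocessing: trial profiles, super-cache, greedy clouds, UDGs, programs."""

import numpy as np
import pytest

from lolcat_ssa import (
    AveragePropensityProfile,
    all_propensities,
    assign_clouds,
    build_bipartite_udg,
    build_clique_udg,
    build_structures,
    build_subtree_partition,
    build_super_cache_members,
    build_system,
    canonical_model,
    clique_edge_count,
    generate_hub_network,
    sample_average_propensities,
    uniform_profile,
)
from lolcat_ssa.preprocess import DegenerateSystemError
from lolcat_ssa.synthetic import HubNetworkSpec

from conftest import random_system


class TestTrialProfile:
    def test_frozen_system_profile_equals_initial_propensities(self):
        # catalytic null reactions: nothing ever changes, so the time average
        # is the constant initial propensity vector
        system = build_system(
            {"A": 4, "B": 2},
            [("r1", ["A"], ["A"], 2.0), ("r2", ["B"], ["B"], 0.5)],
        )
        prof = sample_average_propensities(system, system.initial_state(), 200, seed=1)
        np.testing.assert_allclose(
            prof.values, all_propensities(system, system.initial_state()), rtol=1e-12
        )

    def test_same_seed_gives_identical_profile(self):
        system = random_system(5)
        s0 = system.initial_state()
        a = sample_average_propensities(system, s0, 500, seed=9)
        b = sample_average_propensities(system, s0, 500, seed=9)
        assert (a.values == b.values).all()

    def test_degenerate_system_raises(self):
        system = build_system({"A": 0}, [("r", ["A"], [], 1.0)])
        with pytest.raises(DegenerateSystemError):
            sample_average_propensities(system, system.initial_state(), 100, seed=0)

    def test_immigration_death_stationarity_balance(self):
        """At stationarity the death propensity flux balances immigration:
        time-averaged a_death ≈ λ within 5%."""
        system, facts = canonical_model("immigration_death")
        prof = sample_average_propensities(
            system, system.initial_state(), 100_000, seed=3
        )
        death = prof.values[1]
        assert death == pytest.approx(facts["birth_rate"], rel=0.05)


class TestSuperCacheSelection:
    def test_top_k_descending(self):
        prof = AveragePropensityProfile(np.array([9.0, 5.0, 1.0]), 0, 0)
        assert build_super_cache_members(prof, 2) == [0, 1]

    def test_size_zero_is_empty(self):
        prof = AveragePropensityProfile(np.array([9.0, 5.0]), 0, 0)
        assert build_super_cache_members(prof, 0) == []

    def test_ties_break_by_reaction_index(self):
        prof = AveragePropensityProfile(np.array([5.0, 9.0, 5.0]), 0, 0)
        assert build_super_cache_members(prof, 2) == [1, 0]

    @pytest.mark.parametrize("size", [1, 5, 20])
    def test_matches_full_sort_oracle(self, size):
        rng = np.random.default_rng(size)
        vals = rng.random(40)
        prof = AveragePropensityProfile(vals, 0, 0)
        got = build_super_cache_members(prof, size)
        expected = [j for j in np.argsort(-vals, kind="stable")[:size]]
        assert got == expected


class TestGreedyClouds:
    def test_hand_executed_greedy_loop(self):
        # reactions X+Y, X+Z, X+Y with averages 5,3,2: X's candidate scores 10,
        # beating Y (7) and Z (3) -> one cloud on X holding all three
        system = build_system(
            {"X": 1, "Y": 1, "Z": 1},
            [
                ("a", ["X", "Y"], [], 1.0),
                ("b", ["X", "Z"], [], 1.0),
                ("c", ["X", "Y"], [], 1.0),
            ],
        )
        prof = AveragePropensityProfile(np.array([5.0, 3.0, 2.0]), 0, 0)
        clouds = assign_clouds(system, prof, super_cache=[])
        assert len(clouds) == 1
        factor, members = clouds[0]
        assert system.species[factor].id == "X"
        assert members == [0, 1, 2]

    def test_single_reaction_gets_single_cloud(self):
        system = build_system({"A": 1, "B": 1}, [("r", ["A", "B"], [], 1.0)])
        prof = uniform_profile(system)
        clouds = assign_clouds(system, prof, super_cache=[])
        assert len(clouds) == 1 and clouds[0][1] == [0]

    def test_equal_scores_pick_lowest_species_index(self):
        system = build_system(
            {"A": 1, "B": 1}, [("r1", ["A"], [], 1.0), ("r2", ["B"], [], 1.0)]
        )
        clouds = assign_clouds(system, uniform_profile(system), super_cache=[])
        assert clouds[0][0] == system.index_of["A"]

    def test_null_reactions_get_dedicated_cloud(self):
        system = build_system({"A": 1}, [("gen", [], ["A"], 1.0), ("r", ["A"], [], 1.0)])
        clouds = assign_clouds(system, uniform_profile(system), super_cache=[])
        assert clouds[-1][0] == 0  # ∅-cloud
        assert clouds[-1][1] == [0]

    @pytest.mark.parametrize("seed", range(6))
    def test_partition_covers_every_reaction_once(self, seed):
        system = random_system(seed)
        prof = uniform_profile(system)
        sc = build_super_cache_members(prof, min(5, system.M))
        clouds = assign_clouds(system, prof, sc)
        seen = sorted(sc + [j for _, grp in clouds for j in grp])
        assert seen == list(range(system.M))


class TestSubtreePartition:
    def _system_with_partners(self, partners):
        ids = sorted(set(partners))
        system = build_system(
            {"T": 1, **{p: 1 for p in ids}},
            [(f"r{i}", ["T", p], [], 1.0) for i, p in enumerate(partners)],
        )
        return system

    def test_threshold_three_splits(self):
        system = self._system_with_partners(["Y", "Y", "Y", "Z"])
        t0, subs = build_subtree_partition(system, system.index_of["T"], range(4))
        assert t0 == [3]
        assert len(subs) == 1 and subs[0][1] == [0, 1, 2]

    def test_all_distinct_partners_stay_primary(self):
        system = self._system_with_partners(["X", "Y", "Z"])
        t0, subs = build_subtree_partition(system, system.index_of["T"], range(3))
        assert t0 == [0, 1, 2] and subs == []

    def test_mixed_group_sizes(self):
        partners = ["Y"] * 5 + ["Z"] * 3 + ["W"] * 2
        system = self._system_with_partners(partners)
        t0, subs = build_subtree_partition(system, system.index_of["T"], range(10))
        assert len(subs) == 2
        assert sorted(len(g) for _, g in subs) == [3, 5]
        assert t0 == [8, 9]

    def test_self_and_null_partnered_stay_primary(self):
        system = build_system(
            {"T": 5, "Y": 1},
            [("self", ["T", "T"], [], 1.0), ("un", ["T"], [], 1.0)]
            + [(f"y{i}", ["T", "Y"], [], 1.0) for i in range(3)],
        )
        t0, subs = build_subtree_partition(system, system.index_of["T"], range(5))
        assert t0 == [0, 1]
        assert subs[0][1] == [2, 3, 4]


class TestUDGs:
    def test_bipartite_edges_single_reaction(self):
        system = build_system(
            {"A": 1, "B": 1, "C": 1, "D": 1}, [("r", ["A", "B"], ["C", "D"], 1.0)]
        )
        udg = build_bipartite_udg(system)
        assert udg.edge_count == 6  # 2 reactant edges + 4 affected edges

    def test_catalytic_species_not_in_affected_set(self):
        system = build_system({"A": 1, "B": 1, "C": 1}, [("r", ["A", "B"], ["A", "C"], 1.0)])
        udg = build_bipartite_udg(system)
        affected_ids = {system.species[s].id for s in udg.affects[0]}
        assert affected_ids == {"B", "C"}
        assert udg.edge_count == 4

    def test_bipartite_bound_6M(self):
        for seed in range(6):
            system = random_system(seed)
            assert build_bipartite_udg(system).edge_count <= 6 * system.M

    def test_independent_reactions_have_empty_clique(self):
        system = build_system(
            {"A": 1, "B": 1, "C": 1, "D": 1},
            [("r1", ["A"], ["B"], 1.0), ("r2", ["C"], ["D"], 1.0)],
        )
        adj = build_clique_udg(system)
        assert adj == [[0], [1]]  # each reaction depends only on itself

    def test_shared_reactant_forms_clique(self):
        n = 7
        system = build_system(
            {"H": 10}, [(f"r{i}", ["H"], [], 1.0) for i in range(n)]
        )
        adj = build_clique_udg(system)
        assert all(row == list(range(n)) for row in adj)
        assert clique_edge_count(system) == n * n

    @pytest.mark.parametrize("seed", range(5))
    def test_clique_matches_pairwise_oracle(self, seed):
        system = random_system(seed, max_reactions=25)
        adj = build_clique_udg(system)
        for u, ru in enumerate(system.reactions):
            deltas = ru.net_deltas()
            for v, rv in enumerate(system.reactions):
                depends = any(s in deltas for s in rv.reactants if s != 0)
                assert (v in adj[u]) == depends
        assert clique_edge_count(system) == sum(len(a) for a in adj)

    def test_hub_network_edge_separation(self):
        spec = HubNetworkSpec(
            n_species=120, n_reactions=1000, hub_count=1, hub_participation=0.9, seed=2
        )
        system = generate_hub_network(spec)
        bip = build_bipartite_udg(system).edge_count
        clique = clique_edge_count(system)
        assert bip <= 6 * system.M
        assert clique >= 10 * bip


class TestCompiledPrograms:
    def test_factor_only_reaction_compiles_to_single_scale(self):
        # firing changes only T (the cloud factor): one rescale, no tree work
        system = build_system(
            {"T": 10, "Y": 5},
            [("use", ["T"], [], 1.0), ("use2", ["T", "Y"], ["T", "Y"], 1.0)],
        )
        st = build_structures(system, profile=uniform_profile(system), supercache_size=0)
        prog = st.programs[0]
        assert prog.scale_only_clouds and not prog.pleaf_instrs and not prog.cadj_instrs

    def test_null_reaction_program_has_no_structure_updates(self):
        system = build_system({"A": 5}, [("noop", ["A"], ["A"], 1.0)])
        st = build_structures(system, profile=uniform_profile(system), supercache_size=0)
        assert st.programs[0].n_structure_updates() == 0
        assert st.programs[0].deltas == []

    @pytest.mark.parametrize("seed", range(8))
    def test_program_execution_preserves_cache_coherence(self, seed):
        """Executing any program leaves every cached sum equal to its
        from-scratch value (recomputation oracle)."""
        system = random_system(seed, max_reactions=30)
        st = build_structures(system, profile=uniform_profile(system), supercache_size=4)
        props = all_propensities(system, st.state)
        rng = np.random.default_rng(seed)
        for _ in range(50):
            props = all_propensities(system, st.state)
            live = np.flatnonzero(props > 0)
            if not len(live):
                break
            st.execute(int(rng.choice(live)))
            assert st.max_relative_deviation() < 1e-9

    def test_structures_are_deterministic(self):
        system = random_system(13)
        a = build_structures(system, seed=7, trial_steps=300)
        b = build_structures(system, seed=7, trial_steps=300)
        assert a.dump() == b.dump()
        for pa, pb in zip(a.programs, b.programs):
            assert pa.deltas == pb.deltas
            assert pa.pleaf_instrs == pb.pleaf_instrs
            assert pa.cadj_instrs == pb.cadj_instrs
            assert pa.sc_instrs == pb.sc_instrs
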