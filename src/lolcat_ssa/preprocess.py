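"""Preprocessing: turn a ReactionSystem into ready-to-run SimStructures.

Steps, in order:

1. *Trial run* — a short direct-method simulation whose holding-time-weighted
   average propensities estimate how hot each reaction is.
2. *Super-cache selection* — the reactions with the largest average
   propensity go into a small linear array that is scanned first.
3. *Greedy cloud assignment* — a candidate cloud per species scores the sum
   of its members' average propensities; the best candidate is fixed, its
   members are removed from every other candidate, and the loop repeats
   until every remaining reaction belongs to exactly one cloud.
4. *Sub-tree partition* — within a cloud, members sharing a secondary
   reactant form a constant sub-tree when there are at least three of them.
5. *Bipartite update dependency graph* — species → reactions-as-reactant
   and reaction → net-affected species (≤ 6M edges total).
6. *Program compilation* — per reaction, a static instruction list that
   applies stoichiometric deltas and the cheapest correct cache updates.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .clouds import Cloud, SimStructures, SubTree, SuperCache
from .sumtree import SumTree
from .network import (
    NULL_INDEX,
    ReactionSystem,
    SystemState,
    all_propensities,
)


class DegenerateSystemError(RuntimeError):
    """No reaction can ever fire from the initial state."""


# ---------------------------------------------------------------------------
# Trial-run propensity profile


@dataclass
class AveragePropensityProfile:
    values: np.ndarray  # length M, holding-time-weighted mean propensities
    trial_steps: int
    seed: int

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)
        if (self.values < 0).any():
            raise ValueError("negative average propensity")


def sample_average_propensities(
    system: ReactionSystem,
    state: SystemState,
    n_steps: int,
    seed: int,
    *,
    self_rate_halved: bool = True,
) -> AveragePropensityProfile:
    """Direct-SSA trial run; each a_j is averaged weighted by holding times."""
    if n_steps < 1:
        raise ValueError("n_steps must be >= 1")
    rng = np.random.default_rng(seed)
    work = state.copy()
    x = work.counts
    M = system.M
    acc = np.zeros(M)
    total_time = 0.0
    for _ in range(n_steps):
        a = all_propensities(system, work, self_rate_halved=self_rate_halved)
        a0 = float(a.sum())
        if a0 <= 0.0:
            break
        u1 = rng.random()
        u2 = 1.0 - rng.random()  # (0, 1]
        tau = np.log(1.0 / u2) / a0
        acc += a * tau
        total_time += tau
        cum = np.cumsum(a)
        j = int(np.searchsorted(cum, u1 * a0, side="right"))
        j = min(j, M - 1)
        rx = system.reactions[j]
        for s in rx.reactants:
            if s != NULL_INDEX:
                x[s] -= 1
        for s in rx.products:
            if s != NULL_INDEX:
                x[s] += 1
    if total_time <= 0.0:
        raise DegenerateSystemError("all propensities are zero in the initial state")
    return AveragePropensityProfile(values=acc / total_time, trial_steps=n_steps, seed=seed)


def uniform_profile(system: ReactionSystem) -> AveragePropensityProfile:
    """All-equal fallback profile for systems whose trial run stalls."""
    return AveragePropensityProfile(values=np.ones(system.M), trial_steps=0, seed=0)


# ---------------------------------------------------------------------------
# Super-cache and greedy cloud assignment


def build_super_cache_members(profile: AveragePropensityProfile, size: int) -> list[int]:
    """Indices of the `size` reactions with largest average propensity,
    descending; ties broken by ascending reaction index."""
    M = len(profile.values)
    if not (0 <= size <= M):
        raise ValueError("super-cache size out of range")
    order = sorted(range(M), key=lambda j: (-profile.values[j], j))
    return order[:size]


def assign_clouds(
    system: ReactionSystem,
    profile: AveragePropensityProfile,
    super_cache: Sequence[int],
) -> list[tuple[int, list[int]]]:
    """Greedy partition of non-super-cache reactions into factor-species groups.

    Returns (factor species index, sorted member reaction indices) in fixing
    order; a trailing ∅-cloud collects reactions with two ∅ reactants.
    Score ties resolve to the lowest species index.
    """
    sc = set(super_cache)
    eligible = [j for j in range(system.M) if j not in sc]
    # candidate clouds: species -> member set
    members: dict[int, set[int]] = {}
    scores: dict[int, float] = {}
    cand_of: dict[int, list[int]] = {}  # reaction -> candidate species
    for j in eligible:
        rx = system.reactions[j]
        cands = sorted({s for s in rx.reactants if s != NULL_INDEX})
        cand_of[j] = cands
        for s in cands:
            members.setdefault(s, set()).add(j)
            scores[s] = scores.get(s, 0.0) + float(profile.values[j])
    fixed: list[tuple[int, list[int]]] = []
    while members:
        best = min(members, key=lambda s: (-scores[s], s))
        group = sorted(members.pop(best))
        scores.pop(best)
        fixed.append((best, group))
        for j in group:
            for s in cand_of[j]:
                if s == best or s not in members:
                    continue
                if j in members[s]:
                    members[s].discard(j)
                    scores[s] -= float(profile.values[j])
                    if not members[s]:
                        del members[s]
                        del scores[s]
    null_rxns = sorted(j for j in eligible if not cand_of[j])
    if null_rxns:
        fixed.append((NULL_INDEX, null_rxns))
    return fixed


def build_subtree_partition(
    system: ReactionSystem,
    factor: int,
    member_reactions: Sequence[int],
    threshold: int = 3,
) -> tuple[list[int], list[tuple[int, list[int]]]]:
    """Split members into the primary set T0 and secondary groups T_j.

    Members are grouped by their non-factor reactant; groups of size >=
    `threshold` become sub-trees.  ∅-partnered members and factor-species
    self-reactions always stay in T0.
    """
    by_partner: dict[int, list[int]] = {}
    t0: list[int] = []
    for j in member_reactions:
        r1, r2 = system.reactions[j].reactants
        partner = r2 if r1 == factor else r1
        if partner == NULL_INDEX or partner == factor:
            t0.append(j)
        else:
            by_partner.setdefault(partner, []).append(j)
    subtrees: list[tuple[int, list[int]]] = []
    for s in sorted(by_partner):
        group = sorted(by_partner[s])
        if len(group) >= threshold:
            subtrees.append((s, group))
        else:
            t0.extend(group)
    return sorted(t0), subtrees


# ---------------------------------------------------------------------------
# Update dependency graphs


@dataclass
class BipartiteUDG:
    """Species → reactions-as-reactant; reaction → net-affected species."""

    reactant_of: dict[int, list[int]]   # ∅ excluded
    affects: list[list[int]]            # per reaction, species with net delta != 0

    @property
    def edge_count(self) -> int:
        return sum(len(v) for v in self.reactant_of.values()) + sum(
            len(v) for v in self.affects
        )


def build_bipartite_udg(system: ReactionSystem) -> BipartiteUDG:
    reactant_of: dict[int, list[int]] = {}
    affects: list[list[int]] = []
    for j, rx in enumerate(system.reactions):
        for s in sorted({s for s in rx.reactants if s != NULL_INDEX}):
            reactant_of.setdefault(s, []).append(j)
        affects.append(sorted(rx.net_deltas()))
    return BipartiteUDG(reactant_of=reactant_of, affects=affects)


def build_clique_udg(system: ReactionSystem) -> list[list[int]]:
    """Reaction-to-reaction adjacency: u → v iff firing u changes a reactant
    of v.  Quadratic in hub networks; used for baselines and diagnostics."""
    udg = build_bipartite_udg(system)
    adj: list[list[int]] = []
    for j in range(system.M):
        touched: set[int] = set()
        for s in udg.affects[j]:
            touched.update(udg.reactant_of.get(s, ()))
        adj.append(sorted(touched))
    return adj


def clique_edge_count(system: ReactionSystem) -> int:
    """Edge count of the clique UDG without materializing adjacency lists."""
    is_reactant = np.zeros((system.N, system.M), dtype=bool)
    for j, rx in enumerate(system.reactions):
        for s in rx.reactants:
            if s != NULL_INDEX:
                is_reactant[s, j] = True
    total = 0
    for j, rx in enumerate(system.reactions):
        affected = sorted(rx.net_deltas())
        if affected:
            total += int(np.any(is_reactant[affected], axis=0).sum())
    return total


# ---------------------------------------------------------------------------
# Compiled per-reaction update programs


class UpdateProgram:
    """Static instruction list executed every time one reaction fires.

    Instruction groups, in fixed order: stoichiometric count deltas, then
    self-reaction leaf refreshes, primary-leaf refreshes, secondary C
    adjustments, super-cache entry refreshes, and finally one a_T/main-tree
    finalize per touched cloud.  The list is identical on every execution.
    """

    __slots__ = (
        "reaction", "needs", "deltas", "self_instrs", "pleaf_instrs", "cadj_instrs",
        "sc_instrs", "touched_clouds", "scale_only_clouds", "tree_node_cost",
    )

    def __init__(self, reaction: int):
        self.reaction = reaction
        self.needs: list[tuple[int, int]] = []   # (species, required count)
        self.deltas: list[tuple[int, int]] = []
        self.self_instrs: list[tuple[int, int, float]] = []        # (cloud, pos, rate)
        self.pleaf_instrs: list[tuple[int, int, float, int]] = []  # (cloud, pos, rate, species)
        self.cadj_instrs: list[tuple[int, int, int]] = []          # (cloud, j, species)
        self.sc_instrs: list[tuple[int, int, int, float, bool]] = []  # (entry, i1, i2, rate, self)
        self.touched_clouds: list[int] = []
        self.scale_only_clouds: list[int] = []  # factor changed (O(1) rescale)
        self.tree_node_cost = 0

    def n_structure_updates(self) -> int:
        return (
            len(self.self_instrs) + len(self.pleaf_instrs) + len(self.cadj_instrs)
            + len(self.sc_instrs) + len(self.scale_only_clouds)
        )

    def run(self, st: SimStructures) -> None:
        x = st.state.counts
        for s, need in self.needs:
            if x[s] < need:
                from .network import ImpossibleEventError

                raise ImpossibleEventError(
                    f"reaction index {self.reaction} fired with insufficient reactants"
                )
        for s, d in self.deltas:
            x[s] += d
        clouds = st.clouds
        halved = st.self_rate_halved
        for ci, pos, rate in self.self_instrs:
            cloud = clouds[ci]
            cloud.refresh_self_leaf(pos, rate, int(x[cloud.factor]), halved)
        for ci, pos, rate, s in self.pleaf_instrs:
            clouds[ci].refresh_primary_leaf(pos, rate, int(x[s]))
        for ci, j, s in self.cadj_instrs:
            clouds[ci].refresh_secondary(j, int(x[s]))
        sc = st.super_cache
        for entry, i1, i2, rate, is_self in self.sc_instrs:
            if is_self:
                xi = float(x[i1])
                a = rate * xi * (xi - 1.0)
                a = a / 2.0 if halved else a
                if a < 0.0:
                    a = 0.0
            else:
                a = rate * float(x[i1]) * float(x[i2])
            sc.refresh(entry, a)
        mt = st.main_tree
        for ci in self.touched_clouds:
            cloud = clouds[ci]
            cloud.finalize(int(x[cloud.factor]))
            mt.update_leaf(ci, cloud.a_T)
        st.a0 = sc.P_sc + mt.root
        c = st.counters
        n_cloud = (
            len(self.self_instrs) + len(self.pleaf_instrs)
            + len(self.cadj_instrs) + len(self.scale_only_clouds)
        )
        c.structure_updates += n_cloud + len(self.sc_instrs)
        c.cloud_structure_updates += n_cloud
        c.propensity_recomputations += len(self.sc_instrs)
        c.tree_node_updates += self.tree_node_cost


def compile_update_programs(
    system: ReactionSystem,
    structures: SimStructures,
) -> list[UpdateProgram]:
    """Build the per-reaction instruction table against frozen structures."""
    clouds = structures.clouds
    sc = structures.super_cache
    factor_cloud: dict[int, int] = {}
    primary_pos: dict[int, list[tuple[int, int, float]]] = {}
    secondary: dict[int, list[tuple[int, int, float]]] = {}
    assigned: set[int] = set(sc.reactions)
    for ci, cloud in enumerate(clouds):
        factor_cloud[cloud.factor] = ci
        assigned.update(cloud.member_reactions())
        for pos, (p, rate) in enumerate(zip(cloud.primary_partners, cloud.primary_rates)):
            if p != NULL_INDEX and p != cloud.factor:
                primary_pos.setdefault(p, []).append((ci, pos, rate))
        for j, st in enumerate(cloud.subtrees):
            secondary.setdefault(st.species, []).append((ci, j, st.S))
    missing = [j for j in range(system.M) if j not in assigned]
    if missing:
        raise RuntimeError(f"reactions reachable by no structure: {missing}")
    sc_by_species: dict[int, list[int]] = {}
    for entry, j in enumerate(sc.reactions):
        for s in {s for s in system.reactions[j].reactants if s != NULL_INDEX}:
            sc_by_species.setdefault(s, []).append(entry)
    mt_height = max(len(structures.main_tree.levels) - 1, 0)
    programs: list[UpdateProgram] = []
    for j, rx in enumerate(system.reactions):
        prog = UpdateProgram(j)
        need: dict[int, int] = {}
        for s in rx.reactants:
            if s != NULL_INDEX:
                need[s] = need.get(s, 0) + 1
        prog.needs = sorted(need.items())
        prog.deltas = sorted(rx.net_deltas().items())
        touched: dict[int, None] = {}
        sc_entries: dict[int, None] = {}
        for s, d in prog.deltas:
            ci = factor_cloud.get(s)
            if ci is not None:
                cloud = clouds[ci]
                prog.scale_only_clouds.append(ci)
                touched[ci] = None
                for pos, rate in cloud.self_leaves:
                    prog.self_instrs.append((ci, pos, rate))
            for ci, pos, rate in primary_pos.get(s, ()):
                prog.pleaf_instrs.append((ci, pos, rate, s))
                touched[ci] = None
            for ci, jj, _S in secondary.get(s, ()):
                prog.cadj_instrs.append((ci, jj, s))
                touched[ci] = None
            for entry in sc_by_species.get(s, ()):
                sc_entries[entry] = None
        for entry in sc_entries:
            v = sc.reactions[entry]
            vrx = system.reactions[v]
            prog.sc_instrs.append(
                (entry, vrx.reactants[0], vrx.reactants[1], vrx.rate, vrx.is_self_reaction)
            )
        prog.self_instrs.sort()
        prog.pleaf_instrs.sort()
        prog.cadj_instrs.sort()
        prog.sc_instrs.sort()
        prog.scale_only_clouds = sorted(set(prog.scale_only_clouds))
        prog.touched_clouds = sorted(touched)
        tree_cost = 0
        for ci, _, _ in prog.self_instrs:
            tree_cost += len(clouds[ci].primary.levels)
        for ci, _, _, _ in prog.pleaf_instrs:
            tree_cost += len(clouds[ci].primary.levels)
        tree_cost += len(prog.touched_clouds) * (mt_height + 1)
        prog.tree_node_cost = tree_cost
        programs.append(prog)
    return programs


# ---------------------------------------------------------------------------
# Top-level builder


def build_structures(
    system: ReactionSystem,
    *,
    seed: int = 0,
    profile: Optional[AveragePropensityProfile] = None,
    trial_steps: int = 100_000,
    k: int = 4,
    supercache_size: int = 16,
    subtree_threshold: int = 3,
    self_rate_halved: bool = True,
    state: Optional[SystemState] = None,
) -> SimStructures:
    """Full preprocessing pipeline; returns run-ready SimStructures.

    ``profile`` short-circuits the trial run (useful when the caller already
    has average propensities, or wants the uniform fallback).
    """
    if state is None:
        state = system.initial_state()
    if profile is None:
        profile = sample_average_propensities(
            system, state, trial_steps, seed, self_rate_halved=self_rate_halved
        )
    sc_members = build_super_cache_members(profile, min(supercache_size, system.M))
    cloud_specs = assign_clouds(system, profile, sc_members)
    run_state = state.copy()
    clouds: list[Cloud] = []
    for factor, group in cloud_specs:
        t0, sub_specs = build_subtree_partition(
            system, factor, group, threshold=subtree_threshold
        )
        partners = []
        rates = []
        for j in t0:
            r1, r2 = system.reactions[j].reactants
            partners.append(r2 if r1 == factor else r1)
            rates.append(system.reactions[j].rate)
        subtrees = [
            SubTree(
                species=s,
                tree=SumTree([system.reactions[j].rate for j in group_j], k=k),
                reactions=list(group_j),
            )
            for s, group_j in sub_specs
        ]
        clouds.append(
            Cloud(
                factor=factor,
                primary_reactions=t0,
                primary_partners=partners,
                primary_rates=rates,
                subtrees=subtrees,
                state=run_state,
                k=k,
                self_rate_halved=self_rate_halved,
            )
        )
    super_cache = SuperCache.build(
        sc_members, system, run_state, self_rate_halved=self_rate_halved
    )
    structures = SimStructures(
        system, run_state, super_cache, clouds, k=k, self_rate_halved=self_rate_halved
    )
    structures.udg = build_bipartite_udg(system)
    structures.programs = compile_update_programs(system, structures)
    return structures


def structure_report(structures: SimStructures) -> dict:
    """Summary of the built structures (cloud sizes, caches, UDG edges)."""
    system = structures.system
    bip = structures.udg or build_bipartite_udg(system)
    return {
        "n_species": system.N,
        "n_reactions": system.M,
        "super_cache": {
            "size": len(structures.super_cache.reactions),
            "reactions": [system.reactions[j].id for j in structures.super_cache.reactions],
        },
        "clouds": [
            {
                "factor": system.species[c.factor].id,
                "n_reactions": c.n_reactions(),
                "n_primary": len(c.primary_reactions),
                "n_subtrees": len(c.subtrees),
                "subtree_sizes": [len(st.reactions) for st in c.subtrees],
            }
            for c in structures.clouds
        ],
        "bipartite_edges": bip.edge_count,
        "clique_edges": clique_edge_count(system),
    }
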