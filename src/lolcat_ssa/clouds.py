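"""Factored propensity storage: clouds, the main tree, and the super-cache.

A *cloud* groups reactions that share a common reactant, the *factor-species*
x_T.  Because every member propensity carries a factor of x_T, the group's
total factors as

    a_T = x_T · (R + C),        R = Σ_{i ∈ T0} c_i·x_{o_i},
                                C = Σ_j x_{s_j}·S_j,   S_j = Σ_{i ∈ Tj} c_i,

where T0 holds members without a shared secondary reactant (primary tree,
leaf value c_i·x_{o_i}) and each Tj holds members that additionally share a
secondary species s_j (sub-tree of *constants* c_i with constant root S_j).
The payoff is update cost: a change of x_T rescales the whole cloud in O(1);
a change of a secondary species s_j adjusts C in O(1); only a change of a
primary partner touches a tree path (O(log_k |T0|)).

Clouds are leaves of a k-ary *main tree* keyed by a_T; the hottest reactions
bypass trees entirely in a small linear *super-cache* with running total
P_sc.  The cached grand total a0 = P_sc + main-tree root drives time
advancement exactly as in the plain direct method.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .network import (
    NULL_INDEX,
    Reaction,
    ReactionSystem,
    SystemState,
    all_propensities,
    propensity,
)
from .sumtree import SumTree


class WiringError(RuntimeError):
    """A reaction was addressed through a structure it does not belong to."""


@dataclass
class OpCounters:
    """Per-run operation tallies supporting complexity claims without timing."""

    propensity_recomputations: int = 0
    tree_node_updates: int = 0
    structure_updates: int = 0
    cloud_structure_updates: int = 0
    comparisons: int = 0
    steps: int = 0

    def reset(self) -> None:
        self.propensity_recomputations = 0
        self.tree_node_updates = 0
        self.structure_updates = 0
        self.cloud_structure_updates = 0
        self.comparisons = 0
        self.steps = 0


@dataclass
class SubTree:
    """Constant sub-tree for members sharing secondary species s_j."""

    species: int                  # s_j
    tree: SumTree                 # leaves are the constants c_i
    reactions: list[int]          # leaf position -> reaction index
    S: float = 0.0                # cached root; constant for the cloud's lifetime

    def __post_init__(self):
        self.S = self.tree.root


class Cloud:
    """One factor-species group with cached aggregates R, C and a_T."""

    __slots__ = (
        "factor", "index", "primary", "primary_reactions", "primary_partners",
        "primary_rates", "self_leaves", "subtrees", "sub_terms", "R", "C", "a_T",
        "op_count",
    )

    def __init__(
        self,
        factor: int,
        primary_reactions: list[int],
        primary_partners: list[int],
        primary_rates: list[float],
        subtrees: list[SubTree],
        state: SystemState,
        *,
        k: int = 4,
        self_rate_halved: bool = True,
        index: int = -1,
    ):
        self.factor = factor
        self.index = index
        self.primary_reactions = primary_reactions
        self.primary_partners = primary_partners
        self.primary_rates = primary_rates
        # leaf positions of factor-species self-reactions: their leaf value
        # c·(x_T−1)/2 depends on x_T, so the O(1) rescale alone is not enough
        self.self_leaves = [
            (pos, rate)
            for pos, (p, rate) in enumerate(zip(primary_partners, primary_rates))
            if p == factor and factor != NULL_INDEX
        ]
        leaves = [
            self._primary_leaf_value(p, rate, state, self_rate_halved)
            for p, rate in zip(primary_partners, primary_rates)
        ]
        self.primary = SumTree(leaves, k=k)
        self.subtrees = subtrees
        self.R = self.primary.root
        # one cached term x_{s_j}·S_j per sub-tree; C is their exact sum, so
        # it returns to exactly 0.0 when every secondary count does
        self.sub_terms = np.array(
            [float(state.counts[st.species]) * st.S for st in self.subtrees]
        )
        self.C = float(self.sub_terms.sum())
        self.a_T = float(state.counts[self.factor]) * (self.R + self.C)
        self.op_count = 0  # arithmetic-update tally for complexity assertions

    def _primary_leaf_value(
        self, partner: int, rate: float, state: SystemState, halved: bool
    ) -> float:
        if partner == self.factor and self.factor != NULL_INDEX:
            x = int(state.counts[self.factor])
            v = rate * max(x - 1, 0)
            return v / 2.0 if halved else v
        return float(rate * state.counts[partner])

    # -- bookkeeping ------------------------------------------------------

    def n_reactions(self) -> int:
        return len(self.primary_reactions) + sum(len(st.reactions) for st in self.subtrees)

    def member_reactions(self) -> list[int]:
        out = list(self.primary_reactions)
        for st in self.subtrees:
            out.extend(st.reactions)
        return out

    def total(self) -> float:
        """a_T = x_T·(R + C), read from cache."""
        return self.a_T

    # -- incremental updates (each returns nothing; caller refreshes a_T) --

    def scale_factor(self, new_count: int) -> None:
        """O(1) response to a factor-species count change: trees untouched."""
        self.a_T = float(new_count) * (self.R + self.C)
        self.op_count += 1

    def refresh_primary_leaf(self, pos: int, rate: float, partner_count: int) -> None:
        """Primary partner o_i changed: leaf := c_i·x_{o_i}, R from the root."""
        self.primary.update_leaf(pos, rate * partner_count)
        self.R = max(self.primary.root, 0.0)  # root can drift a few ulp below 0
        self.op_count += 1

    def refresh_self_leaf(self, pos: int, rate: float, factor_count: int, halved: bool) -> None:
        v = rate * max(factor_count - 1, 0)
        self.primary.update_leaf(pos, v / 2.0 if halved else v)
        self.R = max(self.primary.root, 0.0)
        self.op_count += 1

    def refresh_secondary(self, j: int, new_count: int) -> None:
        """Secondary species s_j changed: refresh its term x_{s_j}·S_j and C.

        The sub-tree itself is untouched — its leaves are constants and its
        root S_j never changes; only the cached factor x_{s_j} moves.  The
        term is an exact product and C the exact sum of the (few) terms, so
        repeated secondary changes accumulate no round-off.
        """
        self.sub_terms[j] = float(new_count) * self.subtrees[j].S
        self.C = float(self.sub_terms.sum())
        self.op_count += 1

    def finalize(self, factor_count: int) -> float:
        """Refresh a_T from caches; returns the change for main-tree/a0 upkeep."""
        new = float(factor_count) * (self.R + self.C)
        if new < 0.0:  # float residue only; true member propensities are >= 0
            new = 0.0
        delta = new - self.a_T
        self.a_T = new
        return delta

    # -- selection --------------------------------------------------------

    def select(self, r: float, state: SystemState) -> int:
        """Map r ∈ [0, a_T) to a member reaction index.

        The residual is rescaled by 1/x_T on entry (the trees store factored
        weights) and again by 1/x_{s_j} on sub-tree entry, preserving the
        per-reaction selection measure exactly.
        """
        if not (0.0 <= r < self.a_T):
            raise ValueError(f"r={r!r} outside [0, a_T={self.a_T!r})")
        x_T = float(state.counts[self.factor])
        r /= x_T  # a_T > 0 implies x_T > 0
        if r < self.R:
            pos, _ = self.primary.locate(min(r, np.nextafter(self.R, 0.0)))
            return self.primary_reactions[pos]
        r -= self.R
        last = None
        for st in self.subtrees:
            x_s = float(state.counts[st.species])
            span = x_s * st.S
            if span <= 0.0:
                continue
            if r < span:
                pos, _ = st.tree.locate(min(r / x_s, np.nextafter(st.S, 0.0)))
                return st.reactions[pos]
            r -= span
            last = st
        # float excess past the last positive span: clamp into it
        if last is not None:
            pos, _ = last.tree.locate(np.nextafter(last.S, 0.0))
            return last.reactions[pos]
        if self.primary.root > 0.0:
            pos, _ = self.primary.locate(np.nextafter(self.primary.root, 0.0))
            return self.primary_reactions[pos]
        raise WiringError("selection reached a cloud with no positive weight")

    # -- exact rebuild (drift control / consistency oracle) ---------------

    def recompute(self, state: SystemState, *, self_rate_halved: bool = True) -> None:
        for pos, (p, rate) in enumerate(zip(self.primary_partners, self.primary_rates)):
            self.primary.update_leaf(
                pos, self._primary_leaf_value(p, rate, state, self_rate_halved)
            )
        self.primary.recompute()
        self.R = self.primary.root
        self.sub_terms = np.array(
            [float(state.counts[st.species]) * st.S for st in self.subtrees]
        )
        self.C = float(self.sub_terms.sum())
        self.a_T = float(state.counts[self.factor]) * (self.R + self.C)


@dataclass
class SuperCache:
    """Small static array of the hottest reactions, scanned linearly."""

    reactions: list[int]
    propensities: np.ndarray  # parallel to reactions
    P_sc: float = 0.0
    entry_of: dict[int, int] = field(default_factory=dict)

    @classmethod
    def build(cls, reactions: list[int], system: ReactionSystem, state: SystemState,
              *, self_rate_halved: bool = True) -> "SuperCache":
        props = np.array(
            [propensity(system.reactions[j], state, self_rate_halved=self_rate_halved)
             for j in reactions],
            dtype=np.float64,
        )
        return cls(
            reactions=list(reactions),
            propensities=props,
            P_sc=float(props.sum()),
            entry_of={j: e for e, j in enumerate(reactions)},
        )

    def select(self, r: float) -> tuple[Optional[int], float]:
        """Linear scan: (reaction index, 0) on a hit, (None, residual) on a miss."""
        props = self.propensities
        for e in range(len(self.reactions)):
            w = props[e]
            if r < w:
                return self.reactions[e], 0.0
            r -= w
        return None, float(r)

    def refresh(self, entry: int, new_propensity: float) -> float:
        delta = new_propensity - self.propensities[entry]
        self.propensities[entry] = new_propensity
        # re-sum the (constant, small) array: O(1) in system size and free of
        # incremental drift, so P_sc always equals the entries' exact sum
        self.P_sc = float(self.propensities.sum())
        return float(delta)

    def recompute(self, system: ReactionSystem, state: SystemState,
                  *, self_rate_halved: bool = True) -> None:
        for e, j in enumerate(self.reactions):
            self.propensities[e] = propensity(
                system.reactions[j], state, self_rate_halved=self_rate_halved
            )
        self.P_sc = float(self.propensities.sum())


class SimStructures:
    """Everything a factored-SSA run mutates: state, caches, trees, programs.

    Built by :func:`lolcat_ssa.preprocess.build_structures`; the engine only
    calls :meth:`select_reaction` and :meth:`execute`.
    """

    def __init__(
        self,
        system: ReactionSystem,
        state: SystemState,
        super_cache: SuperCache,
        clouds: list[Cloud],
        *,
        k: int = 4,
        self_rate_halved: bool = True,
    ):
        self.system = system
        self.state = state
        self.super_cache = super_cache
        self.clouds = clouds
        self.k = k
        self.self_rate_halved = self_rate_halved
        for i, c in enumerate(clouds):
            c.index = i
        self.main_tree = SumTree([c.a_T for c in clouds], k=k)
        self.a0 = self.super_cache.P_sc + self.main_tree.root
        self.udg = None          # BipartiteUDG, attached by the preprocessor
        self.programs = None     # list[UpdateProgram], attached by the preprocessor
        self.counters = OpCounters()

    # -- Phase 1: selection ----------------------------------------------

    def select_reaction(self, r: float) -> int:
        """Map r ∈ [0, a0) to a reaction: super-cache scan, then main tree."""
        if not (0.0 <= r < self.a0):
            raise ValueError(f"r={r!r} outside [0, a0={self.a0!r})")
        hit, residual = self.super_cache.select(r)
        if hit is not None:
            return hit
        root = self.main_tree.root
        if root <= 0.0:
            # float excess past P_sc with no cloud mass: clamp to the last
            # positive super-cache entry
            for e in range(len(self.super_cache.reactions) - 1, -1, -1):
                if self.super_cache.propensities[e] > 0.0:
                    return self.super_cache.reactions[e]
            raise WiringError("selection with no positive weight anywhere")
        if residual >= root:  # float excess from P_sc subtraction
            residual = np.nextafter(root, 0.0)
        cloud_pos, leftover = self.main_tree.locate(residual)
        cloud = self.clouds[cloud_pos]
        if leftover >= cloud.a_T:
            leftover = np.nextafter(cloud.a_T, 0.0)
        return cloud.select(leftover, self.state)

    # -- Phase 2: execution ----------------------------------------------

    def execute(self, reaction_index: int) -> None:
        """Run the reaction's compiled update program (counts + caches)."""
        prog = self.programs[reaction_index]
        prog.run(self)

    # -- consistency ------------------------------------------------------

    def recompute_all(self) -> None:
        """Rebuild every cached sum exactly from the current state."""
        self.super_cache.recompute(self.system, self.state,
                                   self_rate_halved=self.self_rate_halved)
        for i, cloud in enumerate(self.clouds):
            cloud.recompute(self.state, self_rate_halved=self.self_rate_halved)
            self.main_tree.update_leaf(i, cloud.a_T)
        self.main_tree.recompute()
        self.a0 = self.super_cache.P_sc + self.main_tree.root

    def consistency_report(self) -> dict[str, float]:
        """Max relative deviation of every cached sum from brute-force truth."""

        def rel(cached: float, fresh: float) -> float:
            return abs(cached - fresh) / max(abs(fresh), 1e-12)

        props = all_propensities(self.system, self.state,
                                 self_rate_halved=self.self_rate_halved)
        report = {
            "a0": rel(self.a0, float(props.sum())),
            "P_sc": 0.0, "sc_entries": 0.0, "a_T": 0.0, "R": 0.0, "C": 0.0,
            "primary_leaves": 0.0, "tree_nodes": 0.0, "main_tree_leaves": 0.0,
        }
        sc = self.super_cache
        for e, j in enumerate(sc.reactions):
            report["sc_entries"] = max(report["sc_entries"], rel(sc.propensities[e], props[j]))
        report["P_sc"] = rel(sc.P_sc, float(props[sc.reactions].sum()) if sc.reactions else 0.0)
        x = self.state.counts
        for i, cloud in enumerate(self.clouds):
            member_sum = float(props[cloud.member_reactions()].sum())
            report["a_T"] = max(report["a_T"], rel(cloud.a_T, member_sum))
            x_T = float(x[cloud.factor])
            fresh_R = float(
                sum(
                    cloud._primary_leaf_value(p, c, self.state, self.self_rate_halved)
                    for p, c in zip(cloud.primary_partners, cloud.primary_rates)
                )
            )
            report["R"] = max(report["R"], rel(cloud.R, fresh_R))
            fresh_C = float(sum(x[st.species] * st.S for st in cloud.subtrees))
            report["C"] = max(report["C"], rel(cloud.C, fresh_C))
            for pos, (p, c) in enumerate(zip(cloud.primary_partners, cloud.primary_rates)):
                fresh = cloud._primary_leaf_value(p, c, self.state, self.self_rate_halved)
                report["primary_leaves"] = max(
                    report["primary_leaves"], rel(cloud.primary.leaf(pos), fresh)
                )
            report["tree_nodes"] = max(report["tree_nodes"], cloud.primary.max_node_deviation())
            for st in cloud.subtrees:
                report["tree_nodes"] = max(report["tree_nodes"], st.tree.max_node_deviation())
            report["main_tree_leaves"] = max(
                report["main_tree_leaves"], rel(self.main_tree.leaf(i), cloud.a_T)
            )
        report["tree_nodes"] = max(report["tree_nodes"], self.main_tree.max_node_deviation())
        return report

    def max_relative_deviation(self) -> float:
        return max(self.consistency_report().values())

    # -- serialization -----------------------------------------------------

    def dump(self) -> str:
        """Deterministic JSON text of the full structure, for golden tests."""
        ids = [s.id for s in self.system.species]
        rids = [r.id for r in self.system.reactions]
        doc = {
            "a0": self.a0,
            "k": self.k,
            "state": {ids[i]: int(c) for i, c in enumerate(self.state.counts)},
            "super_cache": {
                "reactions": [rids[j] for j in self.super_cache.reactions],
                "propensities": list(map(float, self.super_cache.propensities)),
                "P_sc": self.super_cache.P_sc,
            },
            "clouds": [
                {
                    "factor": ids[c.factor],
                    "a_T": c.a_T,
                    "R": c.R,
                    "C": c.C,
                    "primary": {
                        "reactions": [rids[j] for j in c.primary_reactions],
                        "leaves": list(map(float, c.primary.leaves)),
                    },
                    "subtrees": [
                        {
                            "species": ids[st.species],
                            "S": st.S,
                            "reactions": [rids[j] for j in st.reactions],
                            "constants": list(map(float, st.tree.leaves)),
                        }
                        for st in c.subtrees
                    ],
                }
                for c in self.clouds
            ],
        }
        return json.dumps(doc, indent=1, sort_keys=True)
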