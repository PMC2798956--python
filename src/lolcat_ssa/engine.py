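"""Simulation loops: the factored two-phase engine, the textbook direct
method (the statistical oracle), and an ODM-style linear-scan baseline with
operation counting.

All engines share the same probabilistic contract: reaction j fires with
probability a_j/a0 and the holding time is Exp(a0).  They differ only in how
a0 and the per-reaction propensities are stored and refreshed, so their
trajectories agree distributionally (never path-wise — the same uniform
variate maps to different reactions under different data layouts).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .clouds import OpCounters, SimStructures
from .network import (
    NULL_INDEX,
    ReactionSystem,
    SystemState,
    all_propensities,
)
from .preprocess import (
    AveragePropensityProfile,
    build_bipartite_udg,
    build_structures,
    sample_average_propensities,
)


class Extinction(RuntimeError):
    """a0 = 0: no reaction can ever fire again."""


def advance_time(a0: float, u: float) -> float:
    """Exponential holding time τ = (1/a0)·ln(1/u), u ∈ (0, 1]."""
    if a0 <= 0.0:
        raise Extinction("total propensity is zero")
    if not (0.0 < u <= 1.0):
        raise ValueError("u must lie in (0, 1]")
    return math.log(1.0 / u) / a0


@dataclass
class RunSpec:
    """Stop criteria, seed, and recording policy for one run."""

    max_time: Optional[float] = None       # simulated seconds
    max_iterations: Optional[int] = None
    seed: int = 0
    record_interval: float = 1.0           # simulated seconds between samples
    record_species: Optional[Sequence[str]] = None  # None = all non-∅ species
    drift_recompute_period: int = 1_000_000
    max_samples: int = 1_000_000  # recording stops (run continues) at this many

    def __post_init__(self):
        if self.max_time is None and self.max_iterations is None:
            raise ValueError("set max_time and/or max_iterations")
        if self.record_interval <= 0:
            raise ValueError("record_interval must be > 0")


@dataclass
class Trajectory:
    """Time-gridded samples plus per-reaction event counts."""

    species: list[str]
    times: np.ndarray                  # sample times, strictly increasing
    counts: np.ndarray                 # (n_samples, n_species) int64
    event_counts: np.ndarray           # (M,) int64
    final_state: SystemState
    iterations: int

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(self.counts, columns=self.species, index=pd.Index(self.times, name="time"))

    def to_tsv(self) -> str:
        frame = self.to_frame()
        return frame.to_csv(sep="\t", lineterminator="\n")

    def event_counts_tsv(self, system: ReactionSystem) -> str:
        lines = ["reaction\tevents"]
        lines += [f"{r.id}\t{int(n)}" for r, n in zip(system.reactions, self.event_counts)]
        return "\n".join(lines) + "\n"


class _Recorder:
    """Sample-and-hold recording on a fixed time grid starting at t = 0."""

    def __init__(self, interval: float, indices: np.ndarray, max_samples: int = 1_000_000):
        self.interval = interval
        self.indices = indices
        self.max_samples = max_samples
        self.next_time = 0.0
        self.times: list[float] = []
        self.samples: list[np.ndarray] = []

    def hold_until(self, t_new: float, counts: np.ndarray, limit: Optional[float]) -> None:
        """Record every grid point in [next, t_new] with the current counts.

        A holding interval can dwarf the grid spacing when the total
        propensity collapses, so the sample cap bounds memory; past it the
        simulation continues unrecorded.
        """
        while self.next_time <= t_new:
            if limit is not None and self.next_time > limit:
                return
            if len(self.times) >= self.max_samples:
                return
            self.times.append(self.next_time)
            self.samples.append(counts[self.indices].copy())
            self.next_time += self.interval

    def finish(self, counts: np.ndarray, limit: Optional[float]) -> None:
        if limit is None:
            return
        while self.next_time <= limit * (1 + 1e-12) and len(self.times) < self.max_samples:
            self.times.append(self.next_time)
            self.samples.append(counts[self.indices].copy())
            self.next_time += self.interval

    def build(self, species: list[str], events: np.ndarray, state: SystemState,
              iterations: int) -> Trajectory:
        counts = (
            np.array(self.samples, dtype=np.int64)
            if self.samples
            else np.zeros((0, len(self.indices)), dtype=np.int64)
        )
        return Trajectory(
            species=species,
            times=np.array(self.times, dtype=np.float64),
            counts=counts,
            event_counts=events,
            final_state=state,
            iterations=iterations,
        )


def _recorded_indices(system: ReactionSystem, spec: RunSpec) -> tuple[list[str], np.ndarray]:
    if spec.record_species is None:
        ids = [s.id for s in system.species if s.index != NULL_INDEX]
    else:
        ids = list(spec.record_species)
    return ids, np.array([system.index_of[i] for i in ids], dtype=np.int64)


# ---------------------------------------------------------------------------
# Direct method (reference oracle)


def run_direct(
    system: ReactionSystem,
    spec: RunSpec,
    *,
    self_rate_halved: bool = True,
) -> Trajectory:
    """Textbook direct-method SSA with a full propensity scan per step."""
    rng = np.random.default_rng(spec.seed)
    state = system.initial_state()
    x = state.counts
    ids, idx = _recorded_indices(system, spec)
    rec = _Recorder(spec.record_interval, idx, spec.max_samples)
    events = np.zeros(system.M, dtype=np.int64)
    t = 0.0
    it = 0
    M = system.M
    while spec.max_iterations is None or it < spec.max_iterations:
        a = all_propensities(system, state, self_rate_halved=self_rate_halved)
        a0 = float(a.sum())
        if a0 <= 0.0:
            break
        u1 = rng.random()
        u2 = 1.0 - rng.random()
        tau = math.log(1.0 / u2) / a0
        t_new = t + tau
        if spec.max_time is not None and t_new > spec.max_time:
            t = spec.max_time
            break
        rec.hold_until(t_new, x, spec.max_time)
        cum = np.cumsum(a)
        j = min(int(np.searchsorted(cum, u1 * a0, side="right")), M - 1)
        rx = system.reactions[j]
        for s in rx.reactants:
            if s != NULL_INDEX:
                x[s] -= 1
        for s in rx.products:
            if s != NULL_INDEX:
                x[s] += 1
        events[j] += 1
        t = t_new
        it += 1
    state.time = t
    if not rec.times:
        rec.hold_until(0.0, x, spec.max_time)  # at least the initial sample
    rec.finish(x, spec.max_time)
    return rec.build(ids, events, state, it)


# ---------------------------------------------------------------------------
# Factored (cloud) engine


def lolcat_step(structures: SimStructures, rng: np.random.Generator) -> tuple[int, float]:
    """One two-phase iteration: select (u1), advance time (u2), execute.

    Returns (reaction index, holding time).  Raises :class:`Extinction`
    when a0 = 0.
    """
    a0 = structures.a0
    if a0 <= 0.0:
        raise Extinction("total propensity is zero")
    u1 = rng.random()
    j = _select_with_recovery(structures, u1)
    u2 = 1.0 - rng.random()
    tau = math.log(1.0 / u2) / structures.a0
    structures.execute(j)
    structures.counters.steps += 1
    return j, tau


def _select_with_recovery(structures: SimStructures, u1: float) -> int:
    """Select with u1·a0; on a drift-induced failure, rebuild caches exactly
    and retry once.  A truly extinct system raises :class:`Extinction`."""
    from .clouds import WiringError

    try:
        return structures.select_reaction(u1 * structures.a0)
    except (WiringError, ValueError):
        structures.recompute_all()
        if structures.a0 <= 0.0:
            raise Extinction("total propensity is zero") from None
        return structures.select_reaction(u1 * structures.a0)


def run_lolcat(
    system: ReactionSystem,
    spec: RunSpec,
    *,
    structures: Optional[SimStructures] = None,
    trial_steps: int = 100_000,
    profile: Optional[AveragePropensityProfile] = None,
    k: int = 4,
    supercache_size: int = 16,
    subtree_threshold: int = 3,
    self_rate_halved: bool = True,
) -> Trajectory:
    """Preprocess (unless given prebuilt structures) and run the factored engine."""
    seeds = np.random.SeedSequence(spec.seed).generate_state(2)
    if structures is None:
        structures = build_structures(
            system,
            seed=int(seeds[0] % (2**31)),
            profile=profile,
            trial_steps=trial_steps,
            k=k,
            supercache_size=supercache_size,
            subtree_threshold=subtree_threshold,
            self_rate_halved=self_rate_halved,
        )
    rng = np.random.default_rng(int(seeds[1] % (2**31)))
    state = structures.state
    ids, idx = _recorded_indices(system, spec)
    rec = _Recorder(spec.record_interval, idx, spec.max_samples)
    events = np.zeros(system.M, dtype=np.int64)
    t = 0.0
    it = 0
    peak = max(structures.a0, 1.0)
    while spec.max_iterations is None or it < spec.max_iterations:
        a0 = structures.a0
        if a0 <= 1e-12 * peak:
            # possible float residue of a truly extinct system: settle it exactly
            structures.recompute_all()
            a0 = structures.a0
            if a0 <= 0.0:
                break
        peak = max(peak, a0)
        u1 = rng.random()
        u2 = 1.0 - rng.random()
        tau = math.log(1.0 / u2) / a0
        t_new = t + tau
        if spec.max_time is not None and t_new > spec.max_time:
            t = spec.max_time
            break
        if rec.next_time <= t_new:
            structures.recompute_all()  # drift control before each recorded sample
            rec.hold_until(t_new, state.counts, spec.max_time)
        # select with the (possibly just refreshed) cached total; u1 < 1
        # guarantees r < a0 either way
        try:
            j = _select_with_recovery(structures, u1)
        except Extinction:
            break
        structures.execute(j)
        events[j] += 1
        t = t_new
        it += 1
        structures.counters.steps += 1
        if it % spec.drift_recompute_period == 0:
            structures.recompute_all()
    state.time = t
    if not rec.times:
        rec.hold_until(0.0, state.counts, spec.max_time)
    rec.finish(state.counts, spec.max_time)
    return rec.build(ids, events, state, it)


def frozen_selection_histogram(
    structures: SimStructures, n_draws: int, seed: int
) -> np.ndarray:
    """Selection frequencies from n_draws independent Phase-1 selections with
    no execution; the state and caches never change."""
    rng = np.random.default_rng(seed)
    counts = np.zeros(structures.system.M, dtype=np.int64)
    a0 = structures.a0
    select = structures.select_reaction
    us = rng.random(n_draws)
    for u in us:
        counts[select(u * a0)] += 1
    return counts / float(n_draws)


# ---------------------------------------------------------------------------
# ODM-style baseline (propensity-sorted linear scan + UDG-driven updates)


def run_odm_baseline(
    system: ReactionSystem,
    spec: RunSpec,
    *,
    udg_kind: str = "clique",
    profile: Optional[AveragePropensityProfile] = None,
    trial_steps: int = 10_000,
    self_rate_halved: bool = True,
) -> tuple[Trajectory, OpCounters]:
    """Optimized-direct-method baseline.

    Reactions are sorted by trial-run average propensity (descending) and
    selection is a linear scan.  After each firing, the chosen update
    dependency graph drives propensity refreshes: the clique UDG recomputes
    each dependent reaction directly; the bipartite variant (``udg_kind=
    "bipartite"``, i.e. MODM) walks changed species → reactions-as-reactant,
    at a counted cost of the species fan-out sum.
    """
    if udg_kind not in ("clique", "bipartite"):
        raise ValueError("udg_kind must be 'clique' or 'bipartite'")
    seeds = np.random.SeedSequence(spec.seed).generate_state(2)
    if profile is None:
        profile = sample_average_propensities(
            system, system.initial_state(), trial_steps, int(seeds[0] % (2**31)),
            self_rate_halved=self_rate_halved,
        )
    order = sorted(range(system.M), key=lambda j: (-profile.values[j], j))
    order = np.array(order, dtype=np.int64)
    bip = build_bipartite_udg(system)
    # static per-reaction update sets (indices into the sorted array)
    pos_of = np.empty(system.M, dtype=np.int64)
    pos_of[order] = np.arange(system.M)
    dependents: list[np.ndarray] = []
    fanout_cost = np.zeros(system.M, dtype=np.int64)
    for j in range(system.M):
        touched: set[int] = set()
        cost = 0
        for s in bip.affects[j]:
            lst = bip.reactant_of.get(s, [])
            touched.update(lst)
            cost += len(lst)
        dependents.append(pos_of[np.fromiter(sorted(touched), dtype=np.int64, count=len(touched))])
        fanout_cost[j] = cost if udg_kind == "bipartite" else len(touched)

    rng = np.random.default_rng(int(seeds[1] % (2**31)))
    state = system.initial_state()
    x = state.counts
    ids, idx = _recorded_indices(system, spec)
    rec = _Recorder(spec.record_interval, idx, spec.max_samples)
    events = np.zeros(system.M, dtype=np.int64)
    counters = OpCounters()
    a_sorted = all_propensities(system, state, self_rate_halved=self_rate_halved)[order]
    a0 = float(a_sorted.sum())
    r1s, r2s = system.r1[order], system.r2[order]
    rates, selfm = system.rates[order], system.self_mask[order]
    t = 0.0
    it = 0
    while spec.max_iterations is None or it < spec.max_iterations:
        if a0 <= 1e-12 * max(1.0, float(a_sorted.max(initial=0.0)) * system.M):
            a0 = float(a_sorted.sum())
            if a0 <= 0.0:
                break
        u1 = rng.random()
        u2 = 1.0 - rng.random()
        tau = math.log(1.0 / u2) / a0
        t_new = t + tau
        if spec.max_time is not None and t_new > spec.max_time:
            t = spec.max_time
            break
        rec.hold_until(t_new, x, spec.max_time)
        r = u1 * a0
        pos = 0
        n = len(a_sorted)
        while pos < n - 1:
            w = a_sorted[pos]
            counters.comparisons += 1
            if r < w:
                break
            r -= w
            pos += 1
        j = int(order[pos])
        rx = system.reactions[j]
        for s in rx.reactants:
            if s != NULL_INDEX:
                x[s] -= 1
        for s in rx.products:
            if s != NULL_INDEX:
                x[s] += 1
        dep = dependents[j]
        if len(dep):
            x1 = x[r1s[dep]].astype(np.float64)
            x2 = x[r2s[dep]].astype(np.float64)
            sm = selfm[dep]
            if sm.any():
                x2 = np.where(sm, x1 - 1, x2)
            newa = rates[dep] * x1 * x2
            if self_rate_halved and sm.any():
                newa = np.where(sm, newa / 2.0, newa)
            np.maximum(newa, 0.0, out=newa)
            a0 += float(newa.sum() - a_sorted[dep].sum())
            a_sorted[dep] = newa
        counters.propensity_recomputations += int(fanout_cost[j])
        counters.structure_updates += int(fanout_cost[j])
        events[j] += 1
        t = t_new
        it += 1
        counters.steps += 1
        if it % spec.drift_recompute_period == 0:
            a0 = float(a_sorted.sum())
    state.time = t
    if not rec.times:
        rec.hold_until(0.0, x, spec.max_time)
    rec.finish(x, spec.max_time)
    return rec.build(ids, events, state, it), counters
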