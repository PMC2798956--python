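"""Synthetic reaction systems: hub ("super-species") networks and canonical
analytically solvable models.

Large biochemical models tend to have a few species (ATP-like currency
metabolites, scaffold proteins) that appear as reactants in a large fraction
of reactions, and a heavy-tailed propensity distribution in which a few
reactions carry most of the firing probability.  ``generate_hub_network``
reproduces exactly that structure with controllable knobs, so the factoring
machinery can be exercised and benchmarked without any external model files.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .network import ReactionSystem, build_system


class SpecError(ValueError):
    """Infeasible generator specification."""


@dataclass
class HubNetworkSpec:
    n_species: int = 50
    n_reactions: int = 500
    hub_count: int = 2
    hub_participation: float = 0.9      # fraction of reactions with a hub reactant
    rate_bounds: tuple[float, float] = (1e-2, 1e2)   # log-uniform
    count_bounds: tuple[int, int] = (0, 100)         # uniform inclusive, non-hubs
    hub_initial_count: int = 1000
    catalytic_fraction: float = 0.1     # reactions whose first reactant reappears as product
    buffer_non_hubs: bool = False       # clamp substrate pools: non-hub reactants return as products
    seed: int = 0

    def validate(self) -> None:
        if self.hub_count >= self.n_species:
            raise SpecError("hub_count must be < n_species")
        if not (0.0 <= self.hub_participation <= 1.0):
            raise SpecError("hub_participation must lie in [0, 1]")
        if self.hub_count == 0 and self.hub_participation > 0:
            raise SpecError("hub participation requested but hub_count is 0")
        if self.n_reactions < 1:
            raise SpecError("need at least one reaction")
        if self.n_species - self.hub_count < 1:
            raise SpecError("need at least one non-hub species")


def generate_hub_network(spec: HubNetworkSpec) -> ReactionSystem:
    """Deterministic-in-seed hub network generator.

    The first ``hub_count`` species are hubs (initial count
    ``hub_initial_count``); exactly ``round(participation · M)`` reactions
    draw a hub as first reactant, so realized participation is within one
    reaction of the request.  Non-hub partners, products and rates are drawn
    as documented on :class:`HubNetworkSpec`.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    hubs = [f"H{i}" for i in range(spec.hub_count)]
    others = [f"S{i}" for i in range(spec.n_species - spec.hub_count)]
    all_ids = hubs + others
    lo, hi = spec.rate_bounds
    n_hub_rxns = int(round(spec.hub_participation * spec.n_reactions))
    reactions = []
    for j in range(spec.n_reactions):
        if j < n_hub_rxns:
            # with >= 2 hubs, hub reactions convert one hub form into another
            # — total hub mass is conserved, so long runs cannot exhaust the
            # super-species, mimicking currency metabolites cycling between
            # forms (ATP → ADP and back); a lone hub is simply consumed
            h_idx = int(rng.integers(len(hubs)))
            r1 = hubs[h_idx]
            r2 = others[int(rng.integers(len(others)))]
            if len(hubs) > 1:
                p1 = hubs[(h_idx + 1 + int(rng.integers(len(hubs) - 1))) % len(hubs)]
            else:
                p1 = others[int(rng.integers(len(others)))]
            p2 = others[int(rng.integers(len(others)))]
        else:
            r1 = others[int(rng.integers(len(others)))]
            r2 = others[int(rng.integers(len(others)))]
            p1 = others[int(rng.integers(len(others)))]
            p2 = others[int(rng.integers(len(others)))]
            if rng.random() < spec.catalytic_fraction:
                p1 = r1  # catalytic: reactant reappears, exercising the net-delta rule
        if spec.buffer_non_hubs:
            # buffered substrates: every non-hub reactant is returned, so only
            # hub counts evolve and the load is stationary for arbitrarily
            # long runs (the idiom of clamped substrate pools)
            if j < n_hub_rxns:
                p2 = r2
            else:
                p1, p2 = r1, r2
        rate = float(np.exp(rng.uniform(np.log(lo), np.log(hi))))
        reactions.append((f"R{j}", [r1, r2], [p1, p2], rate))
    # guarantee every species appears in >= 1 reaction
    used = {s for _, rs, ps, _ in reactions for s in (*rs, *ps)}
    unused = [s for s in all_ids if s not in used]
    for i, s in enumerate(unused):
        rid, rs, ps, rate = reactions[i % len(reactions)]
        reactions[i % len(reactions)] = (rid, rs, [ps[0], s], rate)
    c_lo, c_hi = spec.count_bounds
    counts = {s: int(rng.integers(c_lo, c_hi + 1)) for s in others}
    counts.update({h: spec.hub_initial_count for h in hubs})
    return build_system(counts, reactions)


# ---------------------------------------------------------------------------
# Canonical models with closed-form facts


def canonical_model(name: str) -> tuple[ReactionSystem, dict]:
    """Small models with known analytics, used as statistical oracles.

    ``immigration_death``  ∅→A at λ=10, A→∅ at γ=1 per molecule: the
        stationary law of x_A is Poisson(λ/γ), mean = variance = 10.
    ``decay``              A→∅ at c=1 from x_A(0)=1000: E[x_A(t)] = 1000·e^{−t}.
    ``isomerization``      A⇌B, both rates 1, 100 molecules total: stationary
        mean x_A = 50 by symmetry.
    ``dimerization``       A+A→B at c=0.01 from x_A(0)=1000: x_A parity is
        invariant along every trajectory.
    ``enzyme_toy``         one enzyme hub E catalyzing five substrate→product
        conversions plus product decay; exercises a shared-factor cloud.
    """
    if name == "immigration_death":
        system = build_system(
            {"A": 0},
            [("birth", [], ["A"], 10.0), ("death", ["A"], [], 1.0)],
        )
        facts = {"species": "A", "stationary_mean": 10.0, "stationary_variance": 10.0,
                 "birth_rate": 10.0, "death_rate": 1.0}
    elif name == "decay":
        system = build_system({"A": 1000}, [("decay", ["A"], [], 1.0)])
        facts = {"species": "A", "x0": 1000, "rate": 1.0,
                 "mean_at": lambda t: 1000.0 * np.exp(-t)}
    elif name == "isomerization":
        system = build_system(
            {"A": 100, "B": 0},
            [("fwd", ["A"], ["B"], 1.0), ("rev", ["B"], ["A"], 1.0)],
        )
        facts = {"species": "A", "total": 100, "stationary_mean": 50.0}
    elif name == "dimerization":
        system = build_system({"A": 1000, "B": 0}, [("dim", ["A", "A"], ["B"], 0.01)])
        facts = {"species": "A", "x0": 1000, "parity": 0}
    elif name == "enzyme_toy":
        rx = []
        counts = {"E": 10}
        for i in range(1, 6):
            counts[f"S{i}"] = 100
            counts[f"P{i}"] = 0
            rx.append((f"cat{i}", ["E", f"S{i}"], ["E", f"P{i}"], 0.1))
            rx.append((f"deg{i}", [f"P{i}"], [], 1.0))
        system = build_system(counts, rx)
        facts = {"hub": "E", "n_catalytic": 5}
    else:
        raise KeyError(f"unknown canonical model {name!r}")
    return system, facts
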