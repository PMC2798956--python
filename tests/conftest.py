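"""Shared fixtures: seeded random mass-action systems of varied shape."""

import numpy as np
import pytest

from lolcat_ssa import ReactionSystem, build_system


def random_system(seed: int, max_reactions: int = 50) -> ReactionSystem:
    """Seeded random network mixing binary, unary, zero-order, self- and
    catalytic reactions, with some zero-count species so that zero
    propensities occur."""
    rng = np.random.default_rng(seed)
    n_species = int(rng.integers(3, 12))
    ids = [f"X{i}" for i in range(n_species)]
    counts = {s: int(rng.integers(0, 50)) for s in ids}
    counts[ids[0]] = max(counts[ids[0]], 5)  # at least one live species
    m = int(rng.integers(3, max_reactions + 1))
    reactions = []
    for j in range(m):
        kind = rng.random()
        if kind < 0.1:
            lhs = []  # zero-order
        elif kind < 0.25:
            lhs = [ids[int(rng.integers(n_species))]]
        elif kind < 0.35:
            s = ids[int(rng.integers(n_species))]
            lhs = [s, s]  # self-reaction
        else:
            lhs = [ids[int(rng.integers(n_species))], ids[int(rng.integers(n_species))]]
        n_prod = int(rng.integers(0, 3))
        rhs = [ids[int(rng.integers(n_species))] for _ in range(n_prod)]
        if lhs and rng.random() < 0.2:
            rhs = [lhs[0]] + rhs[:1]  # catalytic
        rate = float(10.0 ** rng.uniform(-2, 2))
        reactions.append((f"R{j}", lhs, rhs, rate))
    return build_system(counts, reactions)


@pytest.fixture
def tiny_system() -> ReactionSystem:
    """A+B→C (c=2), A+A→B (c=1), ∅→A (c=5) with x=(A:3, B:4, C:0)."""
    return build_system(
        {"A": 3, "B": 4, "C": 0},
        [
            ("bind", ["A", "B"], ["C"], 2.0),
            ("dimer", ["A", "A"], ["B"], 1.0),
            ("birth", [], ["A"], 5.0),
        ],
    )
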