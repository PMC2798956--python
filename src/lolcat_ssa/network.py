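"""Reaction-network data model: species, mass-action reactions, state, and I/O.

The model follows the standard stochastic-chemical-kinetics setting: a
well-mixed, constant-volume system of species with integer molecule counts
and mass-action reactions with at most two reactants and two products.
Zero- and first-order reactions are expressed uniformly by padding empty
reactant/product slots with the omnipresent species ``∅`` (written ``0`` in
the text format), which lives at index 0 with a frozen count of 1.
"""

from __future__ import annotations

import io
import re
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

NULL_ID = "0"
NULL_INDEX = 0


class NetworkError(ValueError):
    """Malformed network definition."""


class ParseError(NetworkError):
    """Syntax error in the native text format, carries a line number."""

    def __init__(self, message: str, line: int):
        super().__init__(f"line {line}: {message}")
        self.line = line


class UnsupportedKineticsError(NetworkError):
    """SBML kinetic law that is not constant-rate mass action."""


class InvalidStateError(ValueError):
    """State violates an invariant (negative count)."""


class ImpossibleEventError(RuntimeError):
    """A reaction fired that its reactant counts cannot support.

    Signals a propensity bookkeeping bug: a positive propensity implies
    feasibility, so this should never happen in a correct engine.
    """


@dataclass(frozen=True)
class Species:
    id: str
    index: int
    initial_count: int

    def __post_init__(self):
        if self.initial_count < 0:
            raise NetworkError(f"species {self.id!r}: negative initial count")


@dataclass(frozen=True)
class Reaction:
    """Mass-action reaction with exactly two (possibly ∅) slots per side.

    ``reactants`` and ``products`` hold species *indices*; ``rate`` is the
    stochastic rate constant c (events per unit time, already scaled by
    volume).
    """

    id: str
    index: int
    reactants: tuple[int, int]
    products: tuple[int, int]
    rate: float

    def __post_init__(self):
        if self.rate <= 0:
            raise NetworkError(f"reaction {self.id!r}: rate must be > 0")

    @property
    def is_self_reaction(self) -> bool:
        r1, r2 = self.reactants
        return r1 == r2 and r1 != NULL_INDEX

    def net_deltas(self) -> dict[int, int]:
        """Signed stoichiometric change per species, ∅ excluded, zeros dropped."""
        d: dict[int, int] = {}
        for s in self.reactants:
            if s != NULL_INDEX:
                d[s] = d.get(s, 0) - 1
        for s in self.products:
            if s != NULL_INDEX:
                d[s] = d.get(s, 0) + 1
        return {s: v for s, v in d.items() if v != 0}


class ReactionSystem:
    """Immutable network description plus vectorized views of its reactions."""

    def __init__(self, species: Sequence[Species], reactions: Sequence[Reaction]):
        if not species or species[0].id != NULL_ID:
            raise NetworkError("species list must start with the ∅ species '0'")
        self.species = list(species)
        self.reactions = list(reactions)
        self.N = len(self.species)
        self.M = len(self.reactions)
        self.index_of = {s.id: s.index for s in self.species}
        if len(self.index_of) != self.N:
            raise NetworkError("duplicate species ids")
        for i, s in enumerate(self.species):
            if s.index != i:
                raise NetworkError(f"species {s.id!r}: index mismatch")
        for j, r in enumerate(self.reactions):
            if r.index != j:
                raise NetworkError(f"reaction {r.id!r}: index mismatch")
            for s in (*r.reactants, *r.products):
                if not (0 <= s < self.N):
                    raise NetworkError(f"reaction {r.id!r}: undeclared species index {s}")
        # vectorized views used by the direct-method engine
        self.r1 = np.array([r.reactants[0] for r in reactions], dtype=np.int64)
        self.r2 = np.array([r.reactants[1] for r in reactions], dtype=np.int64)
        self.rates = np.array([r.rate for r in reactions], dtype=np.float64)
        self.self_mask = np.array([r.is_self_reaction for r in reactions], dtype=bool)

    def initial_state(self) -> "SystemState":
        counts = np.array([s.initial_count for s in self.species], dtype=np.int64)
        counts[NULL_INDEX] = 1
        return SystemState(counts=counts, time=0.0)

    def __eq__(self, other) -> bool:
        if not isinstance(other, ReactionSystem):
            return NotImplemented
        return self.species == other.species and self.reactions == other.reactions

    def __repr__(self) -> str:
        return f"<ReactionSystem N={self.N} M={self.M}>"


@dataclass
class SystemState:
    counts: np.ndarray  # int64, length N; counts[0] (∅) frozen at 1
    time: float = 0.0

    def copy(self) -> "SystemState":
        return SystemState(counts=self.counts.copy(), time=self.time)

    def validate(self) -> None:
        if (self.counts < 0).any():
            bad = int(np.argmax(self.counts < 0))
            raise InvalidStateError(f"negative count for species index {bad}")
        if self.counts[NULL_INDEX] != 1:
            raise InvalidStateError("∅ count must be frozen at 1")


def propensity(reaction: Reaction, state: SystemState, *, self_rate_halved: bool = True) -> float:
    """Mass-action propensity a_j of one reaction in the given state.

    Distinct reactants: a = c·x_i·x_j (with x_∅ = 1 folding in the zero- and
    first-order cases).  Self-reactions use the combinatorial form
    a = c·x·(x−1)/2 by default; ``self_rate_halved=False`` selects the
    unhalved c·x·(x−1) convention.
    """
    if (state.counts < 0).any():
        raise InvalidStateError("negative count in state")
    i, j = reaction.reactants
    if reaction.is_self_reaction:
        x = int(state.counts[i])
        a = reaction.rate * x * (x - 1)
        return a / 2.0 if self_rate_halved else float(a)
    return float(reaction.rate * state.counts[i] * state.counts[j])


def all_propensities(
    system: ReactionSystem, state: SystemState, *, self_rate_halved: bool = True
) -> np.ndarray:
    """Vector of all M propensities, computed from scratch (O(M))."""
    x = state.counts
    x1 = x[system.r1].astype(np.float64)
    x2 = x[system.r2].astype(np.float64)
    sm = system.self_mask
    if sm.any():
        x2 = np.where(sm, x1 - 1, x2)
    a = system.rates * x1 * x2
    if self_rate_halved and sm.any():
        a = np.where(sm, a / 2.0, a)
    np.maximum(a, 0.0, out=a)  # self-reaction with x=0 would give -c·x
    return a


def total_propensity(
    system: ReactionSystem, state: SystemState, *, self_rate_halved: bool = True
) -> float:
    """Brute-force a0 = Σ_j a_j; the oracle all incremental totals are checked against."""
    return float(
        sum(propensity(r, state, self_rate_halved=self_rate_halved) for r in system.reactions)
    )


def apply_reaction(state: SystemState, reaction: Reaction) -> SystemState:
    """Execute one reaction in place: −1 per reactant slot, +1 per product slot."""
    c = state.counts
    for s in reaction.reactants:
        if s != NULL_INDEX:
            c[s] -= 1
    for s in reaction.products:
        if s != NULL_INDEX:
            c[s] += 1
    if (c < 0).any():
        # roll back for diagnosability before raising
        for s in reaction.reactants:
            if s != NULL_INDEX:
                c[s] += 1
        for s in reaction.products:
            if s != NULL_INDEX:
                c[s] -= 1
        raise ImpossibleEventError(
            f"reaction {reaction.id!r} fired with insufficient reactants"
        )
    return state


def validate_system(system: ReactionSystem) -> list[str]:
    """Report-only validation; returns a list of human-readable violations."""
    issues: list[str] = []
    seen: set[str] = set()
    for s in system.species:
        if s.id in seen:
            issues.append(f"duplicate species id {s.id!r}")
        seen.add(s.id)
        if s.initial_count < 0:
            issues.append(f"species {s.id!r}: negative initial count")
    rseen: set[str] = set()
    for r in system.reactions:
        if r.id in rseen:
            issues.append(f"duplicate reaction id {r.id!r}")
        rseen.add(r.id)
        if r.rate <= 0:
            issues.append(f"reaction {r.id!r}: non-positive rate")
        for s in (*r.reactants, *r.products):
            if not (0 <= s < system.N):
                issues.append(f"reaction {r.id!r}: undeclared species index {s}")
    return issues


# ---------------------------------------------------------------------------
# Construction helpers


def build_system(
    species_counts: dict[str, int],
    reactions: Iterable[tuple[str, Sequence[str], Sequence[str], float]],
) -> ReactionSystem:
    """Build a ReactionSystem from id-based descriptions.

    ``reactions`` yields (id, reactant ids, product ids, rate); each side may
    list 0–2 species, and the literal id ``"0"`` denotes ∅.  Species appearing
    only in reactions are implicitly declared with count 0.
    """
    ids = [NULL_ID] + [s for s in species_counts if s != NULL_ID]
    known = set(ids)
    rx_descr = list(reactions)
    for _, rs, ps, _ in rx_descr:
        for s in (*rs, *ps):
            if s not in known:
                known.add(s)
                ids.append(s)
    index = {s: i for i, s in enumerate(ids)}
    species = [
        Species(id=s, index=i, initial_count=1 if s == NULL_ID else int(species_counts.get(s, 0)))
        for i, s in enumerate(ids)
    ]

    def pad(side: Sequence[str], what: str, rid: str) -> tuple[int, int]:
        if len(side) > 2:
            raise NetworkError(f"reaction {rid!r}: more than two {what}s")
        idx = [index[s] for s in side]
        while len(idx) < 2:
            idx.append(NULL_INDEX)
        return (idx[0], idx[1])

    rx = [
        Reaction(id=rid, index=j, reactants=pad(rs, "reactant", rid),
                 products=pad(ps, "product", rid), rate=float(rate))
        for j, (rid, rs, ps, rate) in enumerate(rx_descr)
    ]
    return ReactionSystem(species, rx)


# ---------------------------------------------------------------------------
# Native text format
#
#   # comment
#   species: A=100, B=50
#   R1: A + B -> C + 0 @ 2.0
#
# A slot written `0` is ∅; one-entity sides are padded with ∅.

_REACTION_RE = re.compile(
    r"^(?P<id>[^:]+):\s*(?P<lhs>[^-]*?)\s*->\s*(?P<rhs>.*?)\s*@\s*(?P<rate>\S+)\s*$"
)


def _parse_side(text: str, lineno: int) -> list[str]:
    parts = [p.strip() for p in text.split("+")]
    if parts == [""]:
        raise ParseError("empty reaction side", lineno)
    if any(p == "" for p in parts):
        raise ParseError("missing species name in reaction side", lineno)
    if len(parts) > 2:
        raise ParseError("more than two entities on one side", lineno)
    return parts


def read_network(stream) -> ReactionSystem:
    """Parse the native line-oriented network format."""
    if isinstance(stream, str):
        stream = io.StringIO(stream)
    counts: dict[str, int] = {}
    reactions: list[tuple[str, list[str], list[str], float]] = []
    for lineno, raw in enumerate(stream, start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if line.lower().startswith("species:"):
            body = line.split(":", 1)[1]
            for item in body.split(","):
                item = item.strip()
                if not item:
                    continue
                if "=" not in item:
                    raise ParseError(f"bad species entry {item!r}", lineno)
                name, val = (p.strip() for p in item.split("=", 1))
                try:
                    counts[name] = int(val)
                except ValueError:
                    raise ParseError(f"bad count {val!r} for species {name!r}", lineno) from None
            continue
        m = _REACTION_RE.match(line)
        if not m:
            raise ParseError(f"unrecognized line {line!r}", lineno)
        rid = m.group("id").strip()
        lhs = _parse_side(m.group("lhs"), lineno)
        rhs = _parse_side(m.group("rhs"), lineno)
        try:
            rate = float(m.group("rate"))
        except ValueError:
            raise ParseError(f"bad rate {m.group('rate')!r}", lineno) from None
        reactions.append((rid, lhs, rhs, rate))
    try:
        return build_system(counts, reactions)
    except NetworkError as exc:
        raise NetworkError(f"invalid network: {exc}") from exc


def write_network(system: ReactionSystem) -> str:
    """Serialize to canonical native text; read(write(s)) == s."""
    out = ["# lolcat-ssa network"]
    decl = ", ".join(
        f"{s.id}={s.initial_count}" for s in system.species if s.index != NULL_INDEX
    )
    out.append(f"species: {decl}")
    ids = [s.id for s in system.species]
    for r in system.reactions:
        lhs = " + ".join(ids[i] for i in r.reactants)
        rhs = " + ".join(ids[i] for i in r.products)
        out.append(f"{r.id}: {lhs} -> {rhs} @ {r.rate!r}")
    return "\n".join(out) + "\n"


# ---------------------------------------------------------------------------
# Minimal SBML Level-3 ingest (constant-rate mass action only)

_MATHML_NS = "http://www.w3.org/1998/Math/MathML"


def _mathml_factors(math_el) -> list[str] | None:
    """Flatten a MathML expression into <ci> factor names if it is a plain
    product (possibly nested <times>); otherwise None."""
    tag = math_el.tag.split("}")[-1]
    if tag == "math":
        children = list(math_el)
        if len(children) != 1:
            return None
        return _mathml_factors(children[0])
    if tag == "ci":
        return [math_el.text.strip()]
    if tag == "apply":
        children = list(math_el)
        if not children or children[0].tag.split("}")[-1] != "times":
            return None
        factors: list[str] = []
        for child in children[1:]:
            sub = _mathml_factors(child)
            if sub is None:
                return None
            factors.extend(sub)
        return factors
    return None


def read_sbml(stream) -> ReactionSystem:
    """Ingest an SBML model whose kinetic laws are products c·X (·Y).

    Any kinetic law that is not a plain product of one rate parameter and the
    reaction's reactant species raises :class:`UnsupportedKineticsError`.
    """
    from lxml import etree

    if isinstance(stream, str):
        root = etree.fromstring(stream.encode())
    else:
        root = etree.parse(stream).getroot()
    ns = {"s": root.nsmap.get(None, ""), "m": _MATHML_NS}
    counts: dict[str, int] = {}
    for sp in root.findall(".//s:listOfSpecies/s:species", ns):
        sid = sp.get("id")
        amount = sp.get("initialAmount", "0")
        counts[sid] = int(float(amount))
    global_params = {
        p.get("id"): float(p.get("value"))
        for p in root.findall(".//s:model/s:listOfParameters/s:parameter", ns)
    }
    reactions: list[tuple[str, list[str], list[str], float]] = []
    for rx in root.findall(".//s:listOfReactions/s:reaction", ns):
        rid = rx.get("id")

        def side(tag: str) -> list[str]:
            refs = rx.findall(f"s:{tag}/s:speciesReference", ns)
            out: list[str] = []
            for ref in refs:
                stoich = int(float(ref.get("stoichiometry", "1")))
                out.extend([ref.get("species")] * stoich)
            if len(out) > 2:
                raise NetworkError(f"reaction {rid!r}: more than two entities per side")
            return out

        reactants, products = side("listOfReactants"), side("listOfProducts")
        kl = rx.find("s:kineticLaw", ns)
        if kl is None:
            raise UnsupportedKineticsError(f"reaction {rid!r}: no kinetic law")
        local = {
            p.get("id"): float(p.get("value"))
            for p in kl.findall(".//s:localParameter", ns)
        } | {
            p.get("id"): float(p.get("value"))
            for p in kl.findall(".//s:parameter", ns)
        }
        math_el = kl.find(f"{{{_MATHML_NS}}}math")
        factors = _mathml_factors(math_el) if math_el is not None else None
        if factors is None:
            raise UnsupportedKineticsError(f"reaction {rid!r}: kinetic law is not a product")
        params = [f for f in factors if f in local or f in global_params]
        species_factors = sorted(f for f in factors if f in counts)
        if len(params) != 1 or species_factors != sorted(reactants):
            raise UnsupportedKineticsError(
                f"reaction {rid!r}: kinetic law is not constant-rate mass action"
            )
        rate = local.get(params[0], global_params.get(params[0]))
        reactions.append((rid, reactants, products, rate))
    return build_system(counts, reactions)
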