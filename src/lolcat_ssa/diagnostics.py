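"""Structural analytics: reaction valence and its propensity-weighted CDF,
plus memory accounting for the two update-dependency-graph representations.

The valence of a reaction is the number of reactions whose propensities
change when it executes.  Systems dominated by a super-species show most of
their firing probability concentrated at valences near the hub fan-out —
visible as a steep climb in the weighted valence CDF — and those are exactly
the systems where factoring pays off and a reaction-clique dependency graph
blows up quadratically.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .network import ReactionSystem
from .preprocess import (
    AveragePropensityProfile,
    build_bipartite_udg,
    build_clique_udg,
    clique_edge_count,
)


def valence(reaction_index: int, clique_udg: list[list[int]], *, include_self: bool = True) -> int:
    """Out-degree of the reaction in the clique UDG.

    A reaction that changes its own reactants' counts depends on itself;
    ``include_self=False`` subtracts that self-edge.
    """
    deg = len(clique_udg[reaction_index])
    if not include_self and reaction_index in clique_udg[reaction_index]:
        deg -= 1
    return deg


@dataclass
class ValenceProfile:
    valences: np.ndarray   # per-reaction valence, length M
    weights: np.ndarray    # normalized average propensities, length M
    cdf: list[tuple[int, float]]  # sorted (valence, cumulative weight)


def valence_cdf(
    system: ReactionSystem,
    profile: AveragePropensityProfile,
    *,
    include_self: bool = True,
) -> ValenceProfile:
    """Propensity-weighted PDF of reaction valence, accumulated into a CDF."""
    udg = build_clique_udg(system)
    vals = np.array(
        [valence(j, udg, include_self=include_self) for j in range(system.M)],
        dtype=np.int64,
    )
    w = np.asarray(profile.values, dtype=np.float64).copy()
    total = w.sum()
    if total <= 0.0:
        import warnings

        warnings.warn("all-zero propensity weights; falling back to uniform", stacklevel=2)
        w[:] = 1.0
        total = w.sum()
    w /= total
    pdf: dict[int, float] = {}
    for v, wt in zip(vals, w):
        pdf[int(v)] = pdf.get(int(v), 0.0) + float(wt)
    cdf = []
    acc = 0.0
    for v in sorted(pdf):
        acc += pdf[v]
        cdf.append((v, acc))
    return ValenceProfile(valences=vals, weights=w, cdf=cdf)


def udg_memory_report(system: ReactionSystem, *, bytes_per_edge: int = 8) -> dict:
    """Edge and nominal byte accounting for clique vs bipartite UDGs.

    Byte figures use a fixed per-edge cost (an index pair) so the report is
    hardware-independent.
    """
    bip = build_bipartite_udg(system).edge_count
    clique = clique_edge_count(system)
    return {
        "M": system.M,
        "bipartite_edges": bip,
        "clique_edges": clique,
        "bipartite_bytes": bip * bytes_per_edge,
        "clique_bytes": clique * bytes_per_edge,
        "edge_ratio": clique / bip if bip else float("nan"),
    }


def selection_intervals(structures) -> list[tuple[int, float, float]]:
    """Phase-1 breakpoint enumeration for a frozen structure.

    Walks the selection order — super-cache entries, then clouds in main-tree
    leaf order, within a cloud the primary leaves then each sub-tree — and
    returns (reaction index, interval start, interval width) for every
    positive-width interval of r ∈ [0, a0).  The width mapped to a reaction
    is precisely the probability mass the selector assigns it, so comparing
    widths against brute-force propensities audits the exactness claim.
    """
    out: list[tuple[int, float, float]] = []
    cum = 0.0
    sc = structures.super_cache
    for e, j in enumerate(sc.reactions):
        w = float(sc.propensities[e])
        if w > 0.0:
            out.append((j, cum, w))
            cum += w
    x = structures.state.counts
    for cloud in structures.clouds:
        x_T = float(x[cloud.factor])
        if cloud.a_T <= 0.0:
            continue
        for pos, j in enumerate(cloud.primary_reactions):
            w = x_T * cloud.primary.leaf(pos)
            if w > 0.0:
                out.append((j, cum, w))
                cum += w
        for st in cloud.subtrees:
            x_s = float(x[st.species])
            for pos, j in enumerate(st.reactions):
                w = x_T * x_s * st.tree.leaf(pos)
                if w > 0.0:
                    out.append((j, cum, w))
                    cum += w
    return out


def selection_measure(structures) -> np.ndarray:
    """Per-reaction total selection measure over r ∈ [0, a0)."""
    measure = np.zeros(structures.system.M)
    for j, _, w in selection_intervals(structures):
        measure[j] += w
    return measure


def valence_cdf_tsv(profile: ValenceProfile) -> str:
    lines = ["valence\tpdf\tcdf"]
    prev = 0.0
    for v, c in profile.cdf:
        lines.append(f"{v}\t{c - prev:.10g}\t{c:.10g}")
        prev = c
    return "\n".join(lines) + "\n"
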