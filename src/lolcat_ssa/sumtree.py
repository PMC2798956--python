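"""Balanced k-ary cumulative-sum tree.

Leaves hold non-negative weights; every internal node holds the sum of its
children, so the root is the total weight.  Updating one leaf touches only
the leaf-to-root path (O(log_k n)); ``locate`` maps a real r ∈ [0, root) to
the unique leaf whose cumulative-weight interval contains it, which is the
primitive behind weighted random reaction selection.

The leaf set is fixed at construction: capacity is padded to a power of k
with zero-weight dummy leaves (never selectable under the half-open locate
convention), so no rebalancing is ever needed.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np


class SumTree:
    __slots__ = ("k", "n_leaves", "levels")

    def __init__(self, weights: Sequence[float], k: int = 4):
        if k < 2:
            raise ValueError("branching factor k must be >= 2")
        w = np.asarray(weights, dtype=np.float64)
        if w.ndim != 1:
            raise ValueError("weights must be one-dimensional")
        if (w < 0).any():
            raise ValueError("negative weight")
        self.k = k
        self.n_leaves = int(w.size)
        # capacity = k^h >= n, h >= 1 so even a 1-leaf tree has a root level
        cap = 1
        while cap < self.n_leaves:
            cap *= k
        leaves = np.zeros(cap, dtype=np.float64)
        leaves[: self.n_leaves] = w
        self.levels: list[np.ndarray] = [leaves]
        while self.levels[-1].size > 1:
            below = self.levels[-1]
            self.levels.append(below.reshape(-1, k).sum(axis=1))
        # levels[-1] is the root (size 1), even for the empty tree

    # -- queries ----------------------------------------------------------

    @property
    def root(self) -> float:
        return float(self.levels[-1][0])

    def leaf(self, index: int) -> float:
        if not (0 <= index < self.n_leaves):
            raise IndexError("leaf index out of range")
        return float(self.levels[0][index])

    @property
    def leaves(self) -> np.ndarray:
        """Read-only view of the live leaves (dummy padding excluded)."""
        v = self.levels[0][: self.n_leaves]
        v.flags.writeable = False
        return v

    # -- mutation ---------------------------------------------------------

    def update_leaf(self, index: int, new_value: float) -> float:
        """Set one leaf and refresh the sums along its path; returns the delta.

        Each ancestor is recomputed as the sum of its k children rather than
        adjusted by the delta, so every internal node is always bit-identical
        to a from-scratch rebuild — incremental updates accumulate no
        floating-point drift.  Still O(k·log_k n).
        """
        if not (0 <= index < self.n_leaves):
            raise IndexError("leaf index out of range")
        if new_value < 0:
            raise ValueError("negative weight")
        lv = self.levels
        delta = new_value - lv[0][index]
        if delta == 0.0:
            return 0.0
        lv[0][index] = new_value
        k = self.k
        for d in range(1, len(lv)):
            index //= k
            base = index * k
            lv[d][index] = lv[d - 1][base:base + k].sum()
        return float(delta)

    def recompute(self) -> None:
        """Rebuild every internal sum exactly from the leaves (drift control)."""
        k = self.k
        for i in range(1, len(self.levels)):
            np.sum(self.levels[i - 1].reshape(-1, k), axis=1, out=self.levels[i])

    # -- weighted locate --------------------------------------------------

    def locate(self, r: float) -> tuple[int, float]:
        """Return (leaf index, residual) with Σ_{j<i} w_j <= r < Σ_{j<=i} w_j.

        Zero-weight leaves are never selected (half-open intervals).  Tiny
        floating-point excess at the upper boundary is clamped onto the last
        positive-weight child rather than raised, since incremental updates
        can leave node sums a few ulp short of their children's true total.
        """
        if not (0.0 <= r < self.root):
            raise ValueError(f"r={r!r} outside [0, root={self.root!r})")
        k = self.k
        idx = 0
        for depth in range(len(self.levels) - 2, -1, -1):
            level = self.levels[depth]
            base = idx * k
            last_pos = -1
            for c in range(base, base + k):
                w = level[c]
                if r < w:
                    idx = c
                    break
                if w > 0.0:
                    last_pos = c
                r -= w
            else:  # float excess: clamp to the last positive child
                if last_pos < 0:
                    raise ValueError("locate descended into an all-zero subtree")
                idx = last_pos
                r += level[last_pos]
                r = min(r, np.nextafter(level[last_pos], 0.0))
        return idx, float(r)

    # -- diagnostics ------------------------------------------------------

    def max_node_deviation(self) -> float:
        """Max relative deviation of any internal node from its children's sum."""
        worst = 0.0
        k = self.k
        for i in range(1, len(self.levels)):
            true = self.levels[i - 1].reshape(-1, k).sum(axis=1)
            stored = self.levels[i]
            denom = np.maximum(np.abs(true), 1e-300)
            worst = max(worst, float(np.max(np.abs(stored - true) / denom, initial=0.0)))
        return worst

    def __len__(self) -> int:
        return self.n_leaves

    def __repr__(self) -> str:
        return f"<SumTree k={self.k} n={self.n_leaves} root={self.root:.6g}>"
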