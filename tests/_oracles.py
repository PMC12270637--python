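"""Independent brute-force oracles.

Everything here is written as a literal transcription of the defining
formulas, with no shared code paths with the package, so agreement is a
meaningful cross-check rather than a tautology.
"""

from __future__ import annotations

import itertools
import math
from collections import deque

import numpy as np


# ---------------------------------------------------------------------------
# Exhaustive enumeration of integer matrices with fixed marginals


def integer_matrices(row_totals, col_totals):
    """Yield every non-negative integer matrix with the given marginals."""
    row_totals = list(row_totals)
    col_totals = list(col_totals)
    n_cols = len(col_totals)

    def compositions(total, caps):
        if len(caps) == 1:
            if total <= caps[0]:
                yield (total,)
            return
        for first in range(min(total, caps[0]) + 1):
            for rest in compositions(total - first, caps[1:]):
                yield (first,) + rest

    def recurse(i, remaining_cols, rows):
        if i == len(row_totals):
            if all(v == 0 for v in remaining_cols):
                yield np.array(rows)
            return
        for row in compositions(row_totals[i], tuple(remaining_cols)):
            yield from recurse(
                i + 1, [remaining_cols[j] - row[j] for j in range(n_cols)], rows + [row]
            )

    yield from recurse(0, col_totals, [])


def matrix_entropy(w):
    """−Σ p ln p over positive cells of an integer matrix."""
    w = np.asarray(w, dtype=float)
    m = w.sum()
    acc = 0.0
    for v in w.flat:
        if v > 0:
            acc -= (v / m) * math.log(v / m)
    return acc


def h2_extremes_oracle(row_totals, col_totals):
    """(min, max) matrix entropy by full enumeration."""
    ents = [matrix_entropy(w) for w in integer_matrices(row_totals, col_totals)]
    return min(ents), max(ents)


def d_extremes_oracle(row_total, col_totals):
    """(min, max) KL divergence over every feasible visit distribution.

    Feasible vectors sum to row_total with entries bounded by the
    partner totals; availability q comes from the full column totals.
    """
    caps = list(col_totals)
    m = float(sum(caps))
    q = [c / m for c in caps]

    def kl(vec):
        acc = 0.0
        for v, qj in zip(vec, q):
            if v > 0:
                p = v / row_total
                acc += p * math.log(p / qj)
        return acc

    def compositions(total, caps):
        if len(caps) == 1:
            if total <= caps[0]:
                yield (total,)
            return
        for first in range(min(total, caps[0]) + 1):
            for rest in compositions(total - first, caps[1:]):
                yield (first,) + rest

    vals = [kl(vec) for vec in compositions(row_total, tuple(caps))]
    return min(vals), max(vals)


# ---------------------------------------------------------------------------
# Betweenness by explicit shortest-path counting


def betweenness_oracle(adjacency: dict[str, set[str]], vertex: str) -> float:
    """Raw betweenness: Σ over unordered pairs (s, t), both != v, of the
    fraction of shortest s-t paths passing through v."""

    def shortest_paths(s, t):
        """(count of shortest s-t paths, count of those through `vertex`)."""
        if s == t:
            return 0, 0
        # BFS layering from s
        dist = {s: 0}
        queue = deque([s])
        while queue:
            u = queue.popleft()
            for nb in adjacency[u]:
                if nb not in dist:
                    dist[nb] = dist[u] + 1
                    queue.append(nb)
        if t not in dist:
            return 0, 0
        # count paths by DFS over the layered DAG
        def count(u, through):
            if u == t:
                return 1 if through else 0, 1
            hits = total = 0
            for nb in adjacency[u]:
                if dist.get(nb) == dist[u] + 1:
                    h, n = count(nb, through or nb == vertex)
                    hits += h
                    total += n
            return hits, total

        hits, total = count(s, False)
        return total, hits

    others = sorted(v for v in adjacency if v != vertex)
    acc = 0.0
    for s, t in itertools.combinations(others, 2):
        total, hits = shortest_paths(s, t)
        if total:
            acc += hits / total
    return acc


# ---------------------------------------------------------------------------
# Barber modularity by per-cell summation


def barber_q_oracle(weights, plant_modules, pollinator_modules):
    """Q via the cell-by-cell form Σ_ij [A_ij/m − k_i d_j/m²]·δ(g_i, g_j)."""
    w = np.asarray(weights, dtype=float)
    m = w.sum()
    row_deg = w.sum(axis=1)
    col_deg = w.sum(axis=0)
    q = 0.0
    for i in range(w.shape[0]):
        for j in range(w.shape[1]):
            if plant_modules[i] == pollinator_modules[j]:
                q += w[i, j] / m - row_deg[i] * col_deg[j] / m**2
    return q
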