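"""Network-level structure indices for quantitative bipartite networks.

Implements from first principles the four indices used to describe each
monthly plant-pollinator network:

* **weighted connectance** — Bersier-style quantitative linkage density
  (entropy-based mean effective number of partners) divided by the total
  species number I + J;
* **H2'** — community-level interaction specialization: the
  two-dimensional Shannon entropy of the interaction matrix standardized
  between the extreme entropies attainable under the observed integer
  marginal totals (0 = perfectly opportunistic, 1 = fully specialized);
* **weighted NODF** — quantitative nestedness (Almeida-Neto & Ulrich
  2011): do species with smaller totals interact with proper subsets,
  at lower weights, of the partners of species with larger totals;
* **Barber's modularity Q** — bipartite modularity of a given module
  assignment, comparing within-module link mass against the expectation
  from plant and pollinator degree products.

H2 uses natural logs; the connectance entropy is base-2. Both follow
their source definitions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import TYPE_CHECKING

import numpy as np

from .data_io import MetaNetwork, MonthlyNetwork

if TYPE_CHECKING:  # pragma: no cover
    from .modules import ModulePartition

__all__ = [
    "NetworkIndexSet",
    "weighted_connectance",
    "h2_prime",
    "shannon_h2",
    "h2_extremes",
    "weighted_nodf",
    "barber_modularity",
    "compute_index_set",
]

# Entropy extremes are computed exactly (bounded enumeration of the
# transportation polytope) when the matrix is tiny; otherwise the greedy
# heuristics apply, refined by local 2x2 swaps up to this many cells.
_EXACT_MAX_TOTAL = 24
_EXACT_MAX_DIM = 5
_REFINE_MAX_CELLS = 100


def _as_matrix(net: MonthlyNetwork | MetaNetwork | np.ndarray) -> np.ndarray:
    if isinstance(net, (MonthlyNetwork, MetaNetwork)):
        return np.asarray(net.weights, dtype=float)
    return np.asarray(net, dtype=float)


# ---------------------------------------------------------------------------
# Weighted connectance


def weighted_connectance(net: MonthlyNetwork | MetaNetwork | np.ndarray) -> float:
    """Quantitative linkage density / (I + J).

    Linkage density is the flow-weighted mean of each species' effective
    number of partners ``2**H``, with ``H`` the base-2 Shannon entropy of
    its interaction frequencies:

    ``LD = 1/2 [ sum_j (A_.j/m) 2**H_j  +  sum_i (A_i./m) 2**H_i ]``
    """
    w = _as_matrix(net)
    m = w.sum()
    if w.size == 0 or m <= 0:
        raise ValueError("weighted connectance requires a non-empty matrix")

    def _side(marg: np.ndarray, axis: int) -> float:
        p = w / marg[:, None] if axis == 1 else w / marg[None, :]
        logs = np.zeros_like(p)
        np.log2(p, where=p > 0, out=logs)
        h = -(p * logs).sum(axis=axis)
        return float(((marg / m) * 2.0**h).sum())

    row_tot = w.sum(axis=1)
    col_tot = w.sum(axis=0)
    ld = 0.5 * (_side(row_tot, 1) + _side(col_tot, 0))
    return ld / (w.shape[0] + w.shape[1])


# ---------------------------------------------------------------------------
# H2' and the marginal-constrained entropy extremes


def shannon_h2(w: np.ndarray) -> float:
    """Two-dimensional Shannon entropy −Σ p ln p over positive cells."""
    w = np.asarray(w, dtype=float)
    m = w.sum()
    p = w[w > 0] / m
    return float(-(p * np.log(p)).sum())


def _entropy_cells(vals: np.ndarray, m: float) -> float:
    v = vals[vals > 0] / m
    return float(-(v * np.log(v)).sum()) if v.size else 0.0


def _greedy_min_fill(r: np.ndarray, c: np.ndarray) -> np.ndarray:
    """Most-concentrated integer fill: repeatedly pair the largest
    remaining row with the largest remaining column."""
    r = r.astype(np.int64).copy()
    c = c.astype(np.int64).copy()
    x = np.zeros((r.size, c.size), dtype=np.int64)
    while r.sum() > 0:
        i = int(np.argmax(r))
        j = int(np.argmax(c))
        v = min(r[i], c[j])
        x[i, j] += v
        r[i] -= v
        c[j] -= v
    return x

def _proportional_fill(r: np.ndarray, c: np.ndarray) -> np.ndarray:
    """Closest-to-independence integer fill: floor of the expected matrix
    r_i c_j / m, then largest-remainder repair of both marginals."""
    r = r.astype(np.int64)
    c = c.astype(np.int64)
    m = r.sum()
    expected = np.outer(r, c) / m
    x = np.floor(expected).astype(np.int64)
    rdef = r - x.sum(axis=1)
    cdef = c - x.sum(axis=0)
    frac = expected - np.floor(expected)
    while rdef.sum() > 0:
        # among cells with deficit on both axes, add where the fractional
        # remainder is largest (ties: first in row-major order)
        mask = (rdef[:, None] > 0) & (cdef[None, :] > 0)
        cand = np.where(mask, frac - (x - np.floor(expected)), -np.inf)
        i, j = np.unravel_index(int(np.argmax(cand)), x.shape)
        x[i, j] += 1
        rdef[i] -= 1
        cdef[j] -= 1
    return x


def _swap_refine(x: np.ndarray, maximize: bool, max_passes: int = 200) -> np.ndarray:
    """Hill-climb the matrix entropy with marginal-preserving 2x2 moves.

    A move shifts delta units from cells (i,j),(k,l) to (i,l),(k,j).
    Both delta = 1 and the largest feasible delta are tried. Exactness
    is only relied on for tiny matrices (see _REFINE_MAX_CELLS).
    """
    x = x.copy()
    m = float(x.sum())
    n_r, n_c = x.shape
    sign = 1.0 if maximize else -1.0
    for _ in range(max_passes):
        improved = False
        for i in range(n_r):
            for k in range(n_r):
                if i == k:
                    continue
                for j in range(n_c):
                    if x[i, j] == 0:
                        continue
                    for l in range(n_c):
                        if j == l or x[k, l] == 0:
                            continue
                        deltas = {1, int(min(x[i, j], x[k, l]))}
                        before = _entropy_cells(
                            np.array([x[i, j], x[k, l], x[i, l], x[k, j]], dtype=float), m
                        )
                        for d in deltas:
                            after = _entropy_cells(
                                np.array(
                                    [x[i, j] - d, x[k, l] - d, x[i, l] + d, x[k, j] + d],
                                    dtype=float,
                                ),
                                m,
                            )
                            if sign * (after - before) > 1e-12:
                                x[i, j] -= d
                                x[k, l] -= d
                                x[i, l] += d
                                x[k, j] += d
                                improved = True
                                break
        if not improved:
            break
    return x


def _exact_extremes(r: np.ndarray, c: np.ndarray) -> tuple[float, float]:
    """Exact entropy extremes by depth-first enumeration of every integer
    matrix with the given marginals. Only viable for tiny matrices."""
    import itertools

    nr, nc = r.size, c.size
    m = float(r.sum())

    def row_fills(total: int, caps: tuple[int, ...]):
        if len(caps) == 1:
            if total <= caps[0]:
                yield (total,)
            return
        for v in range(min(total, caps[0]) + 1):
            for rest in row_fills(total - v, caps[1:]):
                yield (v,) + rest

    best = [np.inf, -np.inf]

    def descend(i: int, caps: tuple[int, ...], cells: list[int]) -> None:
        if i == nr:
            if all(x == 0 for x in caps):
                h = _entropy_cells(np.array(cells, dtype=float), m)
                best[0] = min(best[0], h)
                best[1] = max(best[1], h)
            return
        for row in row_fills(int(r[i]), caps):
            descend(i + 1, tuple(caps[j] - row[j] for j in range(nc)), cells + list(row))

    descend(0, tuple(int(v) for v in c), [])
    return best[0], best[1]


def h2_extremes(
    row_totals: np.ndarray, col_totals: np.ndarray, refine: bool | None = None
) -> tuple[float, float]:
    """(H2min, H2max): extreme matrix entropies under fixed integer marginals.

    Tiny matrices (total <= 24, each dimension <= 5) are solved exactly by
    enumeration; larger ones use greedy heuristic fills (max-min pairing
    for the minimum, proportional largest-remainder for the maximum),
    refined by local 2x2 swaps while the matrix stays small enough.
    """
    r = np.rint(np.asarray(row_totals, dtype=float)).astype(np.int64)
    c = np.rint(np.asarray(col_totals, dtype=float)).astype(np.int64)
    if r.sum() != c.sum():
        raise ValueError("row and column totals must sum to the same value")
    m = float(r.sum())
    if m <= _EXACT_MAX_TOTAL and max(r.size, c.size) <= _EXACT_MAX_DIM:
        return _exact_extremes(r, c)
    lo = _greedy_min_fill(r, c)
    hi = _proportional_fill(r, c)
    if refine is None:
        refine = r.size * c.size <= _REFINE_MAX_CELLS
    if refine:
        lo = _swap_refine(lo, maximize=False)
        hi = _swap_refine(hi, maximize=True)
    return _entropy_cells(lo.astype(float), m), _entropy_cells(hi.astype(float), m)


def h2_prime(net: MonthlyNetwork | MetaNetwork | np.ndarray) -> float:
    """Standardized two-dimensional interaction specialization in [0, 1].

    ``H2' = (H2max − H2) / (H2max − H2min)`` where H2 is the Shannon
    entropy of the observed interaction frequencies and H2max / H2min
    are the extreme entropies attainable with the observed integer
    marginal totals. Returns 0 (with a warning) when the marginals admit
    a single matrix only (degenerate 1 x J / I x 1 case).
    """
    w = _as_matrix(net)
    m = w.sum()
    if m < 2:
        raise ValueError("H2' requires total interaction count >= 2")
    if w.shape[0] == 1 or w.shape[1] == 1:
        warnings.warn("H2' undefined for single-row/column networks; returning 0")
        return 0.0
    h2 = shannon_h2(w)
    h2min, h2max = h2_extremes(w.sum(axis=1), w.sum(axis=0))
    if h2max - h2min <= 1e-12:
        warnings.warn("degenerate marginals: H2max == H2min; returning 0")
        return 0.0
    return float(np.clip((h2max - h2) / (h2max - h2min), 0.0, 1.0))


# ---------------------------------------------------------------------------
# Weighted NODF


def _wnodf_pairs(w: np.ndarray) -> tuple[float, int]:
    """Sum of pair contributions over rows of ``w`` (callers transpose
    for columns) plus the pair count."""
    totals = w.sum(axis=1)
    fills = (w > 0).sum(axis=1)
    order = np.argsort(-totals, kind="stable")
    w = w[order]
    totals = totals[order]
    fills = fills[order]
    n = w.shape[0]
    acc = 0.0
    for u in range(n):
        for v in range(u + 1, n):
            # u has the larger (or equal) total after sorting
            if totals[u] > totals[v] and fills[v] > 0:
                overlap = int(((w[v] > 0) & (w[v] < w[u])).sum())
                acc += 100.0 * overlap / fills[v]
    return acc, n * (n - 1) // 2


def weighted_nodf(net: MonthlyNetwork | MetaNetwork | np.ndarray) -> float:
    """Weighted NODF in [0, 100].

    For each ordered pair with strictly decreasing marginal totals, the
    contribution is the percentage of the smaller species' links that
    are also used by the larger species at strictly higher weight; the
    index is the mean over all row pairs and column pairs.
    """
    w = _as_matrix(net)
    if w.shape[0] < 2 and w.shape[1] < 2:
        raise ValueError("weighted NODF requires at least two rows or two columns")
    row_acc, row_pairs = _wnodf_pairs(w)
    col_acc, col_pairs = _wnodf_pairs(w.T)
    n_pairs = row_pairs + col_pairs
    if n_pairs == 0:
        return 0.0
    return (row_acc + col_acc) / n_pairs


# ---------------------------------------------------------------------------
# Barber's bipartite modularity


def barber_modularity(
    net: MonthlyNetwork | MetaNetwork,
    partition: "ModulePartition | dict[str, int]",
    weighted: bool = True,
) -> float:
    """Barber's bipartite modularity of a module assignment.

    ``Q = sum_j [ m_j/m − s_j p_j / m^2 ]`` where m is the total link
    mass, m_j the mass inside module j, and s_j / p_j the summed plant /
    pollinator degrees of module j's members. With ``weighted=True``
    (default) mass and degrees are summed visit counts; otherwise link
    presence.
    """
    assignment = getattr(partition, "assignment", partition)
    w = np.asarray(net.weights, dtype=float)
    if not weighted:
        w = (w > 0).astype(float)
    m = w.sum()
    if m <= 0:
        raise ValueError("empty network")
    missing = [s for s in list(net.plants) + list(net.pollinators) if s not in assignment]
    if missing:
        raise KeyError(f"species missing from partition: {missing}")
    p_mod = np.array([assignment[p] for p in net.plants])
    a_mod = np.array([assignment[a] for a in net.pollinators])
    row_deg = w.sum(axis=1)
    col_deg = w.sum(axis=0)
    q = 0.0
    for mod in np.unique(np.concatenate([p_mod, a_mod])):
        rows = p_mod == mod
        cols = a_mod == mod
        m_j = w[np.ix_(rows, cols)].sum()
        s_j = row_deg[rows].sum()
        p_j = col_deg[cols].sum()
        q += m_j / m - (s_j * p_j) / m**2
    return float(q)


# ---------------------------------------------------------------------------
# Bundled per-network summary


@dataclass
class NetworkIndexSet:
    """The four structure indices for one network."""

    month: int
    weighted_connectance: float
    h2_prime: float
    weighted_nodf: float
    barber_q: float
    partition: "ModulePartition | None" = None

    def as_row(self) -> dict:
        return {
            "month": self.month,
            "weighted_connectance": self.weighted_connectance,
            "h2_prime": self.h2_prime,
            "weighted_nodf": self.weighted_nodf,
            "barber_q": self.barber_q,
        }


def compute_index_set(
    net: MonthlyNetwork,
    seed: int = 1,
    algorithm: str = "louvain",
    restarts: int = 100,
) -> NetworkIndexSet:
    """All four indices for one monthly network (modules via `modules`)."""
    from .modules import detect_modules

    part = detect_modules(net, algorithm=algorithm, seed=seed, restarts=restarts)
    return NetworkIndexSet(
        month=net.month,
        weighted_connectance=weighted_connectance(net),
        h2_prime=h2_prime(net),
        weighted_nodf=weighted_nodf(net),
        barber_q=part.q,
        partition=part,
    )
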