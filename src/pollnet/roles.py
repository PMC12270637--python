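"""Species-level position metrics and topological role classification.

Monthly networks: each plant's interaction specialization d' (the
Kullback–Leibler divergence of its visit distribution from partner
availability, standardized between the extremes achievable under the
integer marginals, so 1 − d' measures generality) and its betweenness
centrality on the binary bipartite graph, standardized to [0, 1] by
2B / ((n−1)(n−2)). Plants with standardized betweenness strictly above
0.25 are flagged as core (potential mediators for over a quarter of
vertex pairs).

Meta-network: Guimerà-style topological roles from the within-module
degree z-score and the among-module connectivity (participation
coefficient) c = 1 − Σ_j (k_ij / k_i)², with the classification
super generalist (z > 2.5 and c > 0.62), module hub (z > 2.5 only),
connector (c > 0.62 only), else peripheral. Degrees are binary link
counts by default, matching the defining formulas.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .data_io import (
    InteractionEvent,
    MetaNetwork,
    MonthlyNetwork,
    SpeciesMetadata,
    POLLINATOR_ORDERS,
)
from .modules import ModulePartition

__all__ = [
    "SpeciesMonthRole",
    "MetaRole",
    "d_prime",
    "d_extremes",
    "betweenness",
    "monthly_roles",
    "classify_core",
    "within_module_degree_z",
    "among_module_connectivity",
    "classify_meta_roles",
    "meta_roles",
    "hub_temporal_composition",
]

CORE_BETWEENNESS_THRESHOLD = 0.25
Z_THRESHOLD = 2.5
C_THRESHOLD = 0.62

# d' extremes solved exactly by enumeration for small problems;
# heuristic fills beyond.
_EXACT_MAX_UNITS = 12
_EXACT_MAX_PARTNERS = 6


@dataclass(frozen=True)
class SpeciesMonthRole:
    """Monthly position metrics for one plant."""

    month: int
    species: str
    d_prime: float
    betweenness_raw: float
    betweenness_std: float

    @property
    def generality(self) -> float:
        return 1.0 - self.d_prime

    @property
    def is_core(self) -> bool:
        return self.betweenness_std > CORE_BETWEENNESS_THRESHOLD


@dataclass(frozen=True)
class MetaRole:
    """Meta-network topological role of one species."""

    species: str
    z: float
    c: float
    role: str


# ---------------------------------------------------------------------------
# d' — standardized Kullback–Leibler specialization


def _kl(x: np.ndarray, r: float, q: np.ndarray) -> float:
    mask = x > 0
    p = x[mask] / r
    return float((p * np.log(p / q[mask])).sum())


def d_extremes(row_total: int, col_totals: np.ndarray) -> tuple[float, float]:
    """(d_min, d_max): extreme KL divergences for one species.

    Feasible visit distributions are integer vectors summing to
    ``row_total`` with each entry bounded by its partner's observed
    total (any such vector completes to a full matrix with the observed
    marginals). d_min is found by greedy unit allocation, which is exact
    for this separable convex minimization; d_max by exhaustive
    enumeration when small, otherwise by concentrating visits on the
    rarest partners.
    """
    caps = np.asarray(col_totals, dtype=np.int64)
    r = int(row_total)
    m = float(caps.sum())
    q = caps / m
    n = caps.size

    # minimum: allocate one unit at a time to the partner with the
    # smallest marginal KL increase (exact: separable convex objective)
    x = np.zeros(n, dtype=np.int64)
    for _ in range(r):
        best_j, best_delta = -1, np.inf
        for j in range(n):
            if x[j] >= caps[j]:
                continue
            xj = x[j]
            before = xj * np.log(xj / (r * q[j])) if xj > 0 else 0.0
            after = (xj + 1) * np.log((xj + 1) / (r * q[j]))
            delta = after - before
            if delta < best_delta - 1e-15:
                best_delta, best_j = delta, j
        x[best_j] += 1
    d_min = _kl(x, r, q)

    if r <= _EXACT_MAX_UNITS and n <= _EXACT_MAX_PARTNERS:
        d_max = -np.inf
        stack = [(0, r, ())]
        while stack:
            j, rem, prefix = stack.pop()
            if j == n - 1:
                if rem <= caps[j]:
                    vec = np.array(prefix + (rem,), dtype=float)
                    d_max = max(d_max, _kl(vec, r, q))
                continue
            for v in range(min(rem, int(caps[j])) + 1):
                stack.append((j + 1, rem - v, prefix + (v,)))
    else:
        # heuristic: fill the rarest partners first, to their caps
        order = np.argsort(q, kind="stable")
        y = np.zeros(n, dtype=np.int64)
        rem = r
        for j in order:
            take = min(rem, int(caps[j]))
            y[j] = take
            rem -= take
            if rem == 0:
                break
        d_max = _kl(y, r, q)
        # single-partner concentrations are often better than the fill
        for j in range(n):
            if caps[j] >= r:
                vec = np.zeros(n)
                vec[j] = r
                d_max = max(d_max, _kl(vec, r, q))
    return d_min, float(d_max)


def d_prime(net: MonthlyNetwork | MetaNetwork, species: str) -> float:
    """Standardized specialization d' in [0, 1] for one plant.

    ``d = Σ_j p'_ij ln(p'_ij / q_j)`` with p' the plant's visit
    distribution and q partner availability; standardized as
    ``(d − d_min) / (d_max − d_min)`` and clipped to [0, 1].
    """
    if species not in net.plants:
        raise KeyError(f"{species!r} is not a plant in this network")
    w = np.asarray(net.weights, dtype=float)
    i = net.plants.index(species)
    row = w[i]
    r = row.sum()
    if r <= 0:
        raise ValueError(f"{species!r} has zero interactions")
    m = w.sum()
    q = w.sum(axis=0) / m
    d_obs = _kl(row, r, q)
    d_min, d_max = d_extremes(int(round(r)), np.rint(w.sum(axis=0)).astype(np.int64))
    if d_max - d_min <= 1e-12:
        return 0.0
    return float(np.clip((d_obs - d_min) / (d_max - d_min), 0.0, 1.0))


# ---------------------------------------------------------------------------
# Betweenness centrality


def _binary_graph(net: MonthlyNetwork | MetaNetwork) -> nx.Graph:
    graph = nx.Graph()
    graph.add_nodes_from(net.plants)
    graph.add_nodes_from(net.pollinators)
    rows, cols = np.nonzero(net.weights)
    graph.add_edges_from(
        (net.plants[i], net.pollinators[j]) for i, j in zip(rows.tolist(), cols.tolist())
    )
    return graph


def betweenness_all(net: MonthlyNetwork | MetaNetwork) -> dict[str, tuple[float, float]]:
    """(raw, standardized) betweenness for every species in the network.

    Raw B sums, over unordered pairs of other vertices, the fraction of
    shortest paths through the focal vertex on the binary graph; the
    standardization 2B / ((n−1)(n−2)) uses the total vertex count n even
    when the graph is disconnected. Networks with n < 3 get 0.
    """
    graph = _binary_graph(net)
    n = graph.number_of_nodes()
    raw = nx.betweenness_centrality(graph, normalized=False)
    scale = 2.0 / ((n - 1) * (n - 2)) if n >= 3 else 0.0
    return {sp: (float(b), float(b) * scale) for sp, b in raw.items()}


def betweenness(net: MonthlyNetwork | MetaNetwork, species: str) -> tuple[float, float]:
    """(raw, standardized) betweenness of one species."""
    table = betweenness_all(net)
    if species not in table:
        raise KeyError(f"{species!r} not in network")
    return table[species]


# ---------------------------------------------------------------------------
# Monthly role tables and the core classification


def monthly_roles(net: MonthlyNetwork) -> list[SpeciesMonthRole]:
    """d' and betweenness for every plant in one monthly network."""
    btw = betweenness_all(net)
    out = []
    for sp in net.plants:
        raw, std = btw[sp]
        out.append(
            SpeciesMonthRole(
                month=net.month,
                species=sp,
                d_prime=d_prime(net, sp),
                betweenness_raw=raw,
                betweenness_std=std,
            )
        )
    return out


def classify_core(
    roles: Sequence[SpeciesMonthRole],
    metadata: dict[str, SpeciesMetadata] | None = None,
) -> pd.DataFrame:
    """Bidimensional surface table (generality vs betweenness) with the
    core flag; species above the 0.25 betweenness threshold (strict) are
    core, annotated with origin when metadata is given."""
    rows = []
    for role in roles:
        row = {
            "month": role.month,
            "species": role.species,
            "generality": role.generality,
            "d_prime": role.d_prime,
            "betweenness_raw": role.betweenness_raw,
            "betweenness_std": role.betweenness_std,
            "is_core": role.is_core,
        }
        if metadata is not None and role.species in metadata:
            row["origin"] = metadata[role.species].origin
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Meta-network topological roles


def _module_degrees(
    net: MetaNetwork | MonthlyNetwork,
    partition: ModulePartition | dict[str, int],
    weighted: bool = False,
) -> tuple[dict[str, np.ndarray], int]:
    """Per-species vector of link counts into each module."""
    assignment = getattr(partition, "assignment", partition)
    modules = sorted(set(assignment.values()))
    mod_index = {m: k for k, m in enumerate(modules)}
    w = np.asarray(net.weights, dtype=float)
    if not weighted:
        w = (w > 0).astype(float)
    out: dict[str, np.ndarray] = {}
    a_mod = np.array([mod_index[assignment[a]] for a in net.pollinators])
    p_mod = np.array([mod_index[assignment[p]] for p in net.plants])
    for i, sp in enumerate(net.plants):
        vec = np.zeros(len(modules))
        np.add.at(vec, a_mod, w[i])
        out[sp] = vec
    for j, sp in enumerate(net.pollinators):
        vec = np.zeros(len(modules))
        np.add.at(vec, p_mod, w[:, j])
        out[sp] = vec
    return out, len(modules)


def within_module_degree_z(
    net: MetaNetwork | MonthlyNetwork,
    partition: ModulePartition | dict[str, int],
    species: str,
    weighted: bool = False,
) -> float:
    """z-standardized within-module degree of one species.

    ``z = (k_is − mean_s) / SD_s`` over the members of the species' own
    module, with population SD; an all-equal module yields z = 0 with a
    warning.
    """
    assignment = getattr(partition, "assignment", partition)
    degrees, _ = _module_degrees(net, partition, weighted=weighted)
    own = assignment[species]
    members = [s for s, m in assignment.items() if m == own]
    k_within = np.array([degrees[s][_module_pos(assignment, own)] for s in members])
    sd = float(k_within.std(ddof=0))
    k_is = float(degrees[species][_module_pos(assignment, own)])
    if sd == 0.0:
        warnings.warn(f"module {own} has uniform within-degrees; z set to 0")
        return 0.0
    return (k_is - float(k_within.mean())) / sd


def _module_pos(assignment: dict[str, int], module: int) -> int:
    return sorted(set(assignment.values())).index(module)


def among_module_connectivity(
    net: MetaNetwork | MonthlyNetwork,
    partition: ModulePartition | dict[str, int],
    species: str,
    weighted: bool = False,
) -> float:
    """Participation coefficient c = 1 − Σ_j (k_ij / k_i)² in [0, 1)."""
    degrees, _ = _module_degrees(net, partition, weighted=weighted)
    vec = degrees[species]
    k_i = vec.sum()
    if k_i <= 0:
        raise ValueError(f"{species!r} has no links")
    return float(1.0 - ((vec / k_i) ** 2).sum())


def classify_meta_roles(z: float, c: float) -> str:
    """Four-way role from the (z, c) thresholds (strict inequalities)."""
    if z > Z_THRESHOLD:
        return "super_generalist" if c > C_THRESHOLD else "module_hub"
    return "connector" if c > C_THRESHOLD else "peripheral"


def meta_roles(
    net: MetaNetwork,
    partition: ModulePartition | dict[str, int],
    species: Sequence[str] | None = None,
    weighted: bool = False,
) -> list[MetaRole]:
    """z, c and role label for the given species (default: all plants)."""
    assignment = getattr(partition, "assignment", partition)
    if species is None:
        species = list(net.plants)
    degrees, _ = _module_degrees(net, partition, weighted=weighted)
    # z for all members per module in one pass
    zs: dict[str, float] = {}
    for module in sorted(set(assignment.values())):
        pos = _module_pos(assignment, module)
        members = [s for s, m in assignment.items() if m == module]
        k_within = np.array([degrees[s][pos] for s in members])
        sd = float(k_within.std(ddof=0))
        mean = float(k_within.mean())
        for s in members:
            zs[s] = 0.0 if sd == 0.0 else (float(degrees[s][pos]) - mean) / sd
    out = []
    for sp in species:
        vec = degrees[sp]
        k_i = vec.sum()
        c = float(1.0 - ((vec / k_i) ** 2).sum()) if k_i > 0 else np.nan
        out.append(MetaRole(species=sp, z=zs[sp], c=c, role=classify_meta_roles(zs[sp], c)))
    return out


# ---------------------------------------------------------------------------
# Temporal pollinator composition of hub plants


def hub_temporal_composition(
    species: str,
    events: Sequence[InteractionEvent],
    metadata: dict[str, SpeciesMetadata],
) -> pd.DataFrame:
    """Per-month visit counts to one plant, grouped by pollinator order.

    Rows are the months the plant was visited; columns the five orders.
    Monthly row sums equal the plant's monthly marginal totals.
    """
    sp_events = [ev for ev in events if ev.plant == species]
    if not sp_events:
        raise ValueError(f"{species!r} has no events")
    counts: dict[int, dict[str, int]] = {}
    for ev in sp_events:
        md = metadata.get(ev.pollinator)
        if md is None or md.order is None:
            raise KeyError(f"pollinator {ev.pollinator!r} lacks order metadata")
        month_row = counts.setdefault(ev.month, {order: 0 for order in POLLINATOR_ORDERS})
        month_row[md.order] += ev.count
    frame = pd.DataFrame.from_dict(counts, orient="index").sort_index()
    frame.index.name = "month"
    return frame[list(POLLINATOR_ORDERS)]
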