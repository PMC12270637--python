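"""Permutation null models, z-standardization and FDR control.

The null model permutes the plant labels across a month's interaction
events (the multiset of labels is preserved, pollinator identities and
visit counts untouched) and re-aggregates to a species-level network.
By construction every null network keeps the observed total weight and
every pollinator's marginal total.

Observed index values are standardized as z = (obs − mean_null) / SD_null
(sample SD) with a two-sided empirical p-value using the add-one
correction; significance across the twelve months of one index is
controlled with Benjamini–Hochberg FDR.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .data_io import InteractionEvent, MonthlyNetwork, build_monthly_networks
from . import metrics as _metrics

__all__ = [
    "NullEnsemble",
    "StandardizedIndex",
    "shuffle_plants",
    "null_ensemble",
    "standardize_index",
    "bh_fdr",
    "standardize_months",
]

INDEX_NAMES = ("h2_prime", "weighted_nodf", "barber_q")


@dataclass
class NullEnsemble:
    """Null distribution of one index for one month."""

    month: int
    index_name: str
    values: np.ndarray
    seed: int

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.size < 2:
            raise ValueError("null ensemble needs at least two values")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("null ensemble contains non-finite values")


@dataclass(frozen=True)
class StandardizedIndex:
    """Observed value with its null-standardized score.

    ``degenerate`` flags a zero-SD ensemble, for which z is undefined
    and p is reported as 1.
    """

    observed: float
    z: float
    p: float
    significant_fdr: bool | None = None
    degenerate: bool = False


def shuffle_plants(
    events: Sequence[InteractionEvent], month: int, rng: np.random.Generator | int
) -> MonthlyNetwork:
    """One null network: plant labels permuted across the month's events.

    The plant-label column of the month's event list is replaced by a
    uniform random permutation of itself; the result is aggregated to a
    species-level network.
    """
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(int(rng))
    month_events = [ev for ev in events if ev.month == month]
    if not month_events:
        raise ValueError(f"no events in month {month}")
    plants = [ev.plant for ev in month_events]
    order = rng.permutation(len(plants))
    shuffled = [
        InteractionEvent(
            month=ev.month,
            plant=plants[order[k]],
            pollinator=ev.pollinator,
            count=ev.count,
            site=ev.site,
        )
        for k, ev in enumerate(month_events)
    ]
    return build_monthly_networks(shuffled)[month]


def _index_fn(index_name: str, seed: int, restarts: int) -> Callable[[MonthlyNetwork], float]:
    if index_name == "h2_prime":
        return _metrics.h2_prime
    if index_name == "weighted_nodf":
        return _metrics.weighted_nodf
    if index_name == "barber_q":
        from .modules import detect_modules

        def _q(net: MonthlyNetwork) -> float:
            return detect_modules(net, algorithm="louvain", seed=seed, restarts=restarts).q

        return _q
    raise ValueError(f"unknown index {index_name!r}; choose from {INDEX_NAMES}")


def null_ensemble(
    events: Sequence[InteractionEvent],
    month: int,
    index_name: str,
    permutations: int = 1000,
    seed: int = 1,
    restarts: int = 10,
) -> NullEnsemble:
    """Null distribution of one index from repeated plant shuffles."""
    rng = np.random.default_rng(seed)
    fn = _index_fn(index_name, seed=seed, restarts=restarts)
    values = np.empty(permutations)
    for k in range(permutations):
        values[k] = fn(shuffle_plants(events, month, rng))
    return NullEnsemble(month=month, index_name=index_name, values=values, seed=seed)


def standardize_index(observed: float, ensemble: NullEnsemble) -> StandardizedIndex:
    """z-score and two-sided empirical p of an observed index value.

    z uses the sample (n−1) SD of the ensemble. The empirical p is
    ``2 · min[(1+#{null ≥ obs})/(N+1), (1+#{null ≤ obs})/(N+1)]``
    capped at 1. A zero-SD ensemble yields a flagged degenerate result.
    """
    values = ensemble.values
    sd = float(values.std(ddof=1))
    if sd == 0.0 or np.ptp(values) == 0.0:
        warnings.warn(
            f"null SD is zero for {ensemble.index_name} month {ensemble.month}; "
            "z undefined"
        )
        return StandardizedIndex(observed=observed, z=np.nan, p=1.0, degenerate=True)
    z = (observed - float(values.mean())) / sd
    n = values.size
    p_hi = (1 + int((values >= observed).sum())) / (n + 1)
    p_lo = (1 + int((values <= observed).sum())) / (n + 1)
    p = min(1.0, 2 * min(p_hi, p_lo))
    return StandardizedIndex(observed=observed, z=float(z), p=p)


def bh_fdr(pvalues: Sequence[float], alpha: float = 0.05) -> list[bool]:
    """Benjamini–Hochberg step-up rejections, stable in input order."""
    pvalues = list(pvalues)
    if not pvalues:
        return []
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    if any(not 0 < p <= 1 for p in pvalues):
        raise ValueError("p-values must lie in (0, 1]")
    reject, *_ = multipletests(pvalues, alpha=alpha, method="fdr_bh")
    return [bool(r) for r in reject]


def standardize_months(
    events: Sequence[InteractionEvent],
    index_name: str,
    permutations: int = 1000,
    seed: int = 1,
    alpha: float = 0.05,
    restarts: int = 10,
) -> pd.DataFrame:
    """Observed, z, p and FDR flag of one index for every month.

    The FDR family is the set of monthly p-values of this single index.
    Each month draws its permutations from an independent substream of
    ``seed``.
    """
    networks = build_monthly_networks(events)
    fn = _index_fn(index_name, seed=seed, restarts=restarts)
    rows = []
    child_seeds = np.random.SeedSequence(seed).spawn(len(networks))
    for child, (month, net) in zip(child_seeds, sorted(networks.items())):
        sub_seed = int(child.generate_state(1)[0] % (2**31 - 1))
        ensemble = null_ensemble(
            events, month, index_name, permutations=permutations, seed=sub_seed,
            restarts=restarts,
        )
        std = standardize_index(fn(net), ensemble)
        rows.append(
            {
                "month": month,
                "index": index_name,
                "observed": std.observed,
                "z": std.z,
                "p": std.p,
                "degenerate": std.degenerate,
            }
        )
    frame = pd.DataFrame(rows)
    frame["significant_fdr"] = bh_fdr(frame["p"].tolist(), alpha=alpha)
    return frame
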