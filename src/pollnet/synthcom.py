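"""Synthetic seasonal plant-pollinator community generator.

Produces ground-truth-labelled interaction data with the statistical
structure the analysis pipeline assumes: a year of monthly communities
drawn from fixed plant and pollinator pools, species phenology windows
(wrapping December to January) that force strong monthly turnover, a
few long-flowering generalists active most of the year, block-structured
affinities that plant modular networks, log-normal abundance variation
and Poisson-distributed visit counts.

The default configuration approximates an urban botanical garden
community observed over twelve months: 151 plants (77 native, 74
exotic), 142 pollinators in five orders (68 Hymenoptera, 24 Diptera,
45 Lepidoptera, 3 Coleoptera, 2 Passeriformes), short flowering windows
for most species, seven long-flowering plants, and eight affinity
blocks with a ten-fold within/between visitation-rate contrast.

Every draw is deterministic in ``config.seed``; the community and the
event stream use separate substreams so either can be regenerated
independently.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np

from .data_io import (
    InteractionEvent,
    SpeciesMetadata,
    POLLINATOR_ORDERS,
    MonthlyNetwork,
    build_monthly_networks,
)

__all__ = [
    "CommunityConfig",
    "GroundTruthLedger",
    "generate_community",
    "generate_events",
    "simulate_year",
    "planted_fission_fixture",
    "planted_blocks_network",
]

SITES = ("S1", "S2", "S3", "S4")


@dataclass
class CommunityConfig:
    """Knobs of the synthetic community.

    Rates are Poisson intensities per active (plant, pollinator) pair
    and month, multiplied by the two species' log-normal abundance /
    activity factors. ``duration_low/high`` bound (inclusive) the
    phenology window length of ordinary species; long-flowering species
    draw from 9-12 months.
    """

    n_plants: int = 151
    n_pollinators: int = 142
    native_fraction: float = 77 / 151
    order_probabilities: tuple[float, ...] = (68 / 142, 24 / 142, 45 / 142, 3 / 142, 2 / 142)
    duration_low: int = 2
    duration_high: int = 4
    n_long_flowering: int = 7
    n_long_active_pollinators: int = 7
    n_blocks: int = 8
    within_block_rate: float = 0.6
    between_block_rate: float = 0.06
    abundance_dispersion: float = 1.0
    seed: int = 1

    def validate(self) -> None:
        problems = []
        if self.n_plants < 1:
            problems.append("n_plants must be >= 1")
        if self.n_pollinators < 1:
            problems.append("n_pollinators must be >= 1")
        if not 0 <= self.native_fraction <= 1:
            problems.append("native_fraction must be in [0, 1]")
        if len(self.order_probabilities) != len(POLLINATOR_ORDERS):
            problems.append("order_probabilities needs one entry per order")
        elif abs(sum(self.order_probabilities) - 1) > 1e-9 or min(self.order_probabilities) < 0:
            problems.append("order_probabilities must be non-negative and sum to 1")
        if not 1 <= self.duration_low <= self.duration_high <= 12:
            problems.append("need 1 <= duration_low <= duration_high <= 12")
        if self.n_long_flowering > self.n_plants:
            problems.append("n_long_flowering exceeds n_plants")
        if self.n_blocks < 1:
            problems.append("n_blocks must be >= 1")
        if self.within_block_rate <= 0 or self.between_block_rate < 0:
            problems.append("rates must be positive (between-block may be 0)")
        if self.abundance_dispersion < 0:
            problems.append("abundance_dispersion must be >= 0")
        if problems:
            raise ValueError("invalid CommunityConfig: " + "; ".join(problems))


@dataclass
class GroundTruthLedger:
    """Everything the generator decided, for test assertions.

    ``phenology`` maps species -> (start month, duration); a species is
    active in month t iff ``(t - start) mod 12 < duration``. Expected
    monthly totals are the sums of the Poisson intensities over active
    pairs (filled in by :func:`generate_events`).
    """

    seed: int
    origin: dict[str, str] = field(default_factory=dict)
    order: dict[str, str] = field(default_factory=dict)
    block: dict[str, int] = field(default_factory=dict)
    phenology: dict[str, tuple[int, int]] = field(default_factory=dict)
    abundance: dict[str, float] = field(default_factory=dict)
    active_plants: dict[int, list[str]] = field(default_factory=dict)
    active_pollinators: dict[int, list[str]] = field(default_factory=dict)
    expected_totals: dict[int, float] = field(default_factory=dict)

    def is_active(self, species: str, month: int) -> bool:
        start, duration = self.phenology[species]
        return (month - start) % 12 < duration

    def to_json_dict(self) -> dict:
        obj = asdict(self)
        obj["phenology"] = {s: list(v) for s, v in obj["phenology"].items()}
        return obj


def _allocate_counts(n: int, probabilities: tuple[float, ...]) -> list[int]:
    """Largest-remainder integer allocation of n among the categories."""
    raw = np.asarray(probabilities) * n
    counts = np.floor(raw).astype(int)
    remainder = n - counts.sum()
    order = np.argsort(-(raw - counts), kind="stable")
    for k in range(remainder):
        counts[order[k]] += 1
    return counts.tolist()


def generate_community(
    config: CommunityConfig,
) -> tuple[list[SpeciesMetadata], GroundTruthLedger]:
    """Draw the species pools: labels, blocks, phenology, abundances."""
    config.validate()
    root = np.random.SeedSequence(config.seed)
    rng = np.random.default_rng(root.spawn(2)[0])

    plants = [f"P{k:03d}" for k in range(1, config.n_plants + 1)]
    pollinators = [f"A{k:03d}" for k in range(1, config.n_pollinators + 1)]
    ledger = GroundTruthLedger(seed=config.seed)

    n_native = int(round(config.native_fraction * config.n_plants))
    native_set = set(rng.choice(plants, size=n_native, replace=False))
    for p in plants:
        ledger.origin[p] = "native" if p in native_set else "exotic"

    order_counts = _allocate_counts(config.n_pollinators, config.order_probabilities)
    order_pool = [
        order for order, cnt in zip(POLLINATOR_ORDERS, order_counts) for _ in range(cnt)
    ]
    rng.shuffle(order_pool)
    for a, order in zip(pollinators, order_pool):
        ledger.order[a] = order

    for sp in plants + pollinators:
        ledger.block[sp] = int(rng.integers(0, config.n_blocks))
        ledger.abundance[sp] = float(rng.lognormal(0.0, config.abundance_dispersion))

    long_plants = set(rng.choice(plants, size=config.n_long_flowering, replace=False))
    long_pols = set(
        rng.choice(pollinators, size=min(config.n_long_active_pollinators, config.n_pollinators), replace=False)
    )
    for sp in plants + pollinators:
        if sp in long_plants or sp in long_pols:
            duration = int(rng.integers(9, 13))
        else:
            duration = int(rng.integers(config.duration_low, config.duration_high + 1))
        start = int(rng.integers(1, 13))
        ledger.phenology[sp] = (start, duration)

    for month in range(1, 13):
        ledger.active_plants[month] = [p for p in plants if ledger.is_active(p, month)]
        ledger.active_pollinators[month] = [
            a for a in pollinators if ledger.is_active(a, month)
        ]

    metadata = [
        SpeciesMetadata(species=p, guild="plant", origin=ledger.origin[p]) for p in plants
    ] + [
        SpeciesMetadata(species=a, guild="pollinator", order=ledger.order[a])
        for a in pollinators
    ]
    return metadata, ledger


def generate_events(
    ledger: GroundTruthLedger, config: CommunityConfig
) -> list[InteractionEvent]:
    """Draw the year of visitation events from the community.

    For every month and active (plant, pollinator) pair the visit count
    is Poisson with intensity abundance x activity x block rate; zero
    draws are omitted. Expected monthly totals are recorded on the
    ledger.
    """
    config.validate()
    root = np.random.SeedSequence(config.seed)
    rng = np.random.default_rng(root.spawn(2)[1])
    events: list[InteractionEvent] = []
    for month in range(1, 13):
        plants = ledger.active_plants[month]
        pollinators = ledger.active_pollinators[month]
        expected = 0.0
        for p in plants:
            for a in pollinators:
                rate = (
                    config.within_block_rate
                    if ledger.block[p] == ledger.block[a]
                    else config.between_block_rate
                )
                lam = ledger.abundance[p] * ledger.abundance[a] * rate
                expected += lam
                count = int(rng.poisson(lam))
                if count > 0:
                    events.append(
                        InteractionEvent(
                            month=month,
                            plant=p,
                            pollinator=a,
                            count=count,
                            site=SITES[int(rng.integers(0, len(SITES)))],
                        )
                    )
        ledger.expected_totals[month] = expected
    return events


def simulate_year(
    config: CommunityConfig | None = None,
) -> tuple[list[InteractionEvent], list[SpeciesMetadata], GroundTruthLedger]:
    """Community + events in one call (the packaged paper-like default)."""
    if config is None:
        config = CommunityConfig()
    metadata, ledger = generate_community(config)
    events = generate_events(ledger, config)
    return events, metadata, ledger


# ---------------------------------------------------------------------------
# Planted fixtures for the genealogy and recovery tests


def planted_fission_fixture(seed: int = 1) -> tuple[list[InteractionEvent], dict]:
    """Two-month event set in which one module splits into two.

    Month 1 holds a large complete block X (P001-P006 x A001-A006) plus
    a stable reference block Y (P007-P009 x A007-A009); in month 2, X
    splits into X1 (P001-P003 x A001-A003) and X2 (P004-P006 x
    A004-A006) while Y persists unchanged. All species occur in both
    months, so the X module shows exactly two out-flows.
    """
    rng = np.random.default_rng(seed)
    x_plants = [f"P{k:03d}" for k in range(1, 7)]
    x_pols = [f"A{k:03d}" for k in range(1, 7)]
    y_plants = [f"P{k:03d}" for k in range(7, 10)]
    y_pols = [f"A{k:03d}" for k in range(7, 10)]

    def block(month: int, plants: list[str], pols: list[str]) -> list[InteractionEvent]:
        return [
            InteractionEvent(month=month, plant=p, pollinator=a, count=1 + int(rng.poisson(2)))
            for p in plants
            for a in pols
        ]

    events = block(1, x_plants, x_pols) + block(1, y_plants, y_pols)
    events += (
        block(2, x_plants[:3], x_pols[:3])
        + block(2, x_plants[3:], x_pols[3:])
        + block(2, y_plants, y_pols)
    )
    info = {
        "source_block": x_plants + x_pols,
        "split": [x_plants[:3] + x_pols[:3], x_plants[3:] + x_pols[3:]],
        "reference_block": y_plants + y_pols,
        "seed": seed,
    }
    return events, info


def planted_blocks_network(
    seed: int = 1,
    n_plants: int = 30,
    n_pollinators: int = 30,
    n_blocks: int = 3,
    within_rate: float = 2.0,
    between_rate: float = 0.2,
) -> tuple[MonthlyNetwork, dict[str, int]]:
    """Single modular network with known block labels.

    Visit counts are Poisson with the within/between rate only (no
    abundance heterogeneity), giving a clean planted-partition signal;
    species drawing no interactions are dropped from both outputs.
    """
    rng = np.random.default_rng(seed)
    plants = [f"P{k:03d}" for k in range(1, n_plants + 1)]
    pollinators = [f"A{k:03d}" for k in range(1, n_pollinators + 1)]
    blocks = {sp: int(rng.integers(0, n_blocks)) for sp in plants + pollinators}
    events = []
    for p in plants:
        for a in pollinators:
            rate = within_rate if blocks[p] == blocks[a] else between_rate
            count = int(rng.poisson(rate))
            if count > 0:
                events.append(InteractionEvent(month=1, plant=p, pollinator=a, count=count))
    net = build_monthly_networks(events)[1]
    present = set(net.plants) | set(net.pollinators)
    return net, {sp: b for sp, b in blocks.items() if sp in present}
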