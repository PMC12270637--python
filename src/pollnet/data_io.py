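"""Interaction-event I/O and network assembly.

This module owns the data model the rest of the pipeline consumes:
single visitation records (:class:`InteractionEvent`), species metadata
(:class:`SpeciesMetadata`), monthly quantitative plant x pollinator
matrices (:class:`MonthlyNetwork`) and their annual union, the
:class:`MetaNetwork`.

Conventions
-----------
* Plants are matrix rows, pollinators are columns; both axes carry
  explicit species labels and are sorted lexicographically so every
  downstream computation is deterministic.
* Only observed interactors enter matrices: a species present in the
  metadata but absent from the event table appears in no network.
* Sites are annotation only; events from different sites within a month
  are pooled before network construction.
"""

from __future__ import annotations

import csv
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: The five pollinator orders recognised in species metadata.
POLLINATOR_ORDERS = (
    "Hymenoptera",
    "Diptera",
    "Lepidoptera",
    "Coleoptera",
    "Passeriformes",
)

PLANT_ORIGINS = ("native", "exotic")

DEFAULT_EVENT_SCHEMA = {
    "month": "month",
    "site": "site",
    "plant": "plant",
    "pollinator": "pollinator",
    "count": "count",
}


class SchemaError(ValueError):
    """A required column is missing or unresolvable."""


@dataclass(frozen=True)
class InteractionEvent:
    """One observed visitation record: the atomic unit of input.

    Parameters
    ----------
    month : int
        Calendar month of the observation, 1-12.
    plant, pollinator : str
        Species identifiers. The two guild namespaces must not overlap.
    count : int
        Number of pollinator individuals recorded, >= 1.
    site : str, optional
        Free-text site annotation; pooled before network assembly.
    """

    month: int
    plant: str
    pollinator: str
    count: int
    site: str | None = None

    def __post_init__(self) -> None:
        if not 1 <= int(self.month) <= 12:
            raise ValueError(f"month must be in 1..12, got {self.month}")
        if int(self.count) < 1:
            raise ValueError(f"stored events require count >= 1, got {self.count}")


@dataclass(frozen=True)
class SpeciesMetadata:
    """Guild-dependent species attributes.

    Plants carry an ``origin`` (native/exotic); pollinators carry a
    taxonomic ``order`` (one of :data:`POLLINATOR_ORDERS`). Exactly one
    of the two must be set, matching the guild.
    """

    species: str
    guild: str
    origin: str | None = None
    order: str | None = None

    def __post_init__(self) -> None:
        if self.guild not in ("plant", "pollinator"):
            raise ValueError(f"guild must be 'plant' or 'pollinator', got {self.guild!r}")
        if self.guild == "plant":
            if self.origin not in PLANT_ORIGINS:
                raise ValueError(
                    f"plant {self.species!r} needs origin in {PLANT_ORIGINS}, got {self.origin!r}"
                )
            if self.order is not None:
                raise ValueError(f"plant {self.species!r} must not carry a pollinator order")
        else:
            if self.order not in POLLINATOR_ORDERS:
                raise ValueError(
                    f"pollinator {self.species!r} needs order in {POLLINATOR_ORDERS}, "
                    f"got {self.order!r}"
                )
            if self.origin is not None:
                raise ValueError(f"pollinator {self.species!r} must not carry a plant origin")


@dataclass
class MonthlyNetwork:
    """Quantitative plant x pollinator count matrix for one month.

    Every row and column has at least one positive entry: species with
    no interaction that month are simply absent.
    """

    month: int
    plants: list[str]
    pollinators: list[str]
    weights: np.ndarray

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights)
        if self.weights.shape != (len(self.plants), len(self.pollinators)):
            raise ValueError("weights shape does not match species lists")
        if np.any(self.weights < 0):
            raise ValueError("weights must be non-negative")
        if self.weights.size and (
            np.any(self.weights.sum(axis=1) == 0) or np.any(self.weights.sum(axis=0) == 0)
        ):
            raise ValueError("every plant and pollinator must have >= 1 interaction")

    @property
    def total(self) -> float:
        return float(self.weights.sum())

    @property
    def n_plants(self) -> int:
        return len(self.plants)

    @property
    def n_pollinators(self) -> int:
        return len(self.pollinators)

    def links(self) -> dict[tuple[str, str], float]:
        """Positive cells as a ``{(plant, pollinator): weight}`` mapping."""
        out: dict[tuple[str, str], float] = {}
        rows, cols = np.nonzero(self.weights)
        for i, j in zip(rows.tolist(), cols.tolist()):
            out[(self.plants[i], self.pollinators[j])] = float(self.weights[i, j])
        return out

    def to_long_frame(self) -> pd.DataFrame:
        rows, cols = np.nonzero(self.weights)
        return pd.DataFrame(
            {
                "plant": [self.plants[i] for i in rows],
                "pollinator": [self.pollinators[j] for j in cols],
                "weight": self.weights[rows, cols],
            }
        )

    def to_json_dict(self) -> dict:
        return {
            "month": self.month,
            "plants": list(self.plants),
            "pollinators": list(self.pollinators),
            "weights": self.weights.tolist(),
        }


@dataclass
class MetaNetwork:
    """Annual union of the monthly networks with summed link weights.

    ``provenance`` maps month -> matrix of that month's contribution on
    the meta-network species indices, so every monthly network can be
    reconstructed exactly.
    """

    plants: list[str]
    pollinators: list[str]
    weights: np.ndarray
    provenance: dict[int, np.ndarray] = field(default_factory=dict)

    @property
    def total(self) -> float:
        return float(self.weights.sum())

    def monthly_slice(self, month: int) -> MonthlyNetwork:
        """Reconstruct one month's network from the stored provenance."""
        contrib = self.provenance[month]
        rows = np.nonzero(contrib.sum(axis=1))[0]
        cols = np.nonzero(contrib.sum(axis=0))[0]
        return MonthlyNetwork(
            month=month,
            plants=[self.plants[i] for i in rows],
            pollinators=[self.pollinators[j] for j in cols],
            weights=contrib[np.ix_(rows, cols)].copy(),
        )

    def to_json_dict(self) -> dict:
        return {
            "plants": list(self.plants),
            "pollinators": list(self.pollinators),
            "weights": self.weights.tolist(),
            "provenance": {str(m): w.tolist() for m, w in self.provenance.items()},
        }


# ---------------------------------------------------------------------------
# Event / metadata I/O


def read_events(
    path: str | Path,
    schema: Mapping[str, str] | None = None,
) -> list[InteractionEvent]:
    """Read interaction events from a delimited text file.

    Parameters
    ----------
    path : path-like
        CSV file (UTF-8, header row).
    schema : mapping, optional
        Maps canonical field names (``month``, ``site``, ``plant``,
        ``pollinator``, ``count``) to column names in the file. ``site``
        is optional; the other four are required.

    Returns
    -------
    list of InteractionEvent, in file order. Rows with count 0 are
    dropped with a logged warning.
    """
    colmap = dict(DEFAULT_EVENT_SCHEMA)
    if schema:
        colmap.update(schema)
    path = Path(path)
    events: list[InteractionEvent] = []
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        header = reader.fieldnames or []
        for fieldname in ("month", "plant", "pollinator", "count"):
            if colmap[fieldname] not in header:
                raise SchemaError(
                    f"required column {colmap[fieldname]!r} (field {fieldname!r}) "
                    f"not found in {path.name}; header is {header}"
                )
        has_site = colmap["site"] in header
        for lineno, row in enumerate(reader, start=2):
            try:
                count = int(row[colmap["count"]])
            except (TypeError, ValueError) as exc:
                raise ValueError(
                    f"{path.name}:{lineno}: count {row[colmap['count']]!r} "
                    "is not a non-negative integer"
                ) from exc
            if count < 0:
                raise ValueError(f"{path.name}:{lineno}: negative count {count}")
            if count == 0:
                logger.warning("%s:%d: dropping zero-count row", path.name, lineno)
                continue
            month = int(row[colmap["month"]])
            if not 1 <= month <= 12:
                raise ValueError(f"{path.name}:{lineno}: month {month} outside 1..12")
            events.append(
                InteractionEvent(
                    month=month,
                    plant=row[colmap["plant"]],
                    pollinator=row[colmap["pollinator"]],
                    count=count,
                    site=row[colmap["site"]] if has_site else None,
                )
            )
    return events


def write_events(events: Iterable[InteractionEvent], path: str | Path) -> None:
    """Write events as CSV with the canonical column names."""
    path = Path(path)
    with path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["month", "site", "plant", "pollinator", "count"])
        for ev in events:
            writer.writerow([ev.month, ev.site or "", ev.plant, ev.pollinator, ev.count])


def read_metadata(path: str | Path) -> list[SpeciesMetadata]:
    """Read species metadata (columns: species, guild, origin, order)."""
    frame = pd.read_csv(path, dtype=str, keep_default_na=False)
    out = []
    for rec in frame.to_dict("records"):
        out.append(
            SpeciesMetadata(
                species=rec["species"],
                guild=rec["guild"],
                origin=rec.get("origin") or None,
                order=rec.get("order") or None,
            )
        )
    return out


def write_metadata(metadata: Iterable[SpeciesMetadata], path: str | Path) -> None:
    with Path(path).open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["species", "guild", "origin", "order"])
        for md in metadata:
            writer.writerow([md.species, md.guild, md.origin or "", md.order or ""])


def metadata_index(metadata: Iterable[SpeciesMetadata]) -> dict[str, SpeciesMetadata]:
    return {md.species: md for md in metadata}


# ---------------------------------------------------------------------------
# Network assembly


def build_monthly_networks(
    events: Sequence[InteractionEvent],
) -> dict[int, MonthlyNetwork]:
    """Aggregate events into one quantitative network per month.

    Duplicate (month, site, plant, pollinator) rows are summed; sites
    are pooled. Months with no events are absent from the mapping.
    """
    if not events:
        raise ValueError("cannot build networks from an empty event list")
    by_month: dict[int, dict[tuple[str, str], int]] = {}
    for ev in events:
        cell = by_month.setdefault(ev.month, {})
        cell[(ev.plant, ev.pollinator)] = cell.get((ev.plant, ev.pollinator), 0) + ev.count
    networks: dict[int, MonthlyNetwork] = {}
    for month in sorted(by_month):
        cells = by_month[month]
        plants = sorted({p for p, _ in cells})
        pollinators = sorted({a for _, a in cells})
        weights = np.zeros((len(plants), len(pollinators)), dtype=np.int64)
        p_idx = {p: i for i, p in enumerate(plants)}
        a_idx = {a: j for j, a in enumerate(pollinators)}
        for (p, a), w in cells.items():
            weights[p_idx[p], a_idx[a]] = w
        networks[month] = MonthlyNetwork(month, plants, pollinators, weights)
    return networks


def aggregate_meta_network(networks: Mapping[int, MonthlyNetwork]) -> MetaNetwork:
    """Integrate monthly networks into the annual meta-network.

    Species sets are unioned and cell weights summed; per-month
    contributions are retained as provenance.
    """
    if not networks:
        raise ValueError("need at least one monthly network")
    plants = sorted({p for net in networks.values() for p in net.plants})
    pollinators = sorted({a for net in networks.values() for a in net.pollinators})
    p_idx = {p: i for i, p in enumerate(plants)}
    a_idx = {a: j for j, a in enumerate(pollinators)}
    weights = np.zeros((len(plants), len(pollinators)), dtype=np.int64)
    provenance: dict[int, np.ndarray] = {}
    for month, net in sorted(networks.items()):
        contrib = np.zeros_like(weights)
        rows = [p_idx[p] for p in net.plants]
        cols = [a_idx[a] for a in net.pollinators]
        contrib[np.ix_(rows, cols)] = net.weights
        provenance[month] = contrib
        weights += contrib
    return MetaNetwork(plants, pollinators, weights, provenance)


# ---------------------------------------------------------------------------
# Network serialization


def write_network_csv(net: MonthlyNetwork | MetaNetwork, path: str | Path) -> None:
    """Write a network as long-form CSV (plant, pollinator, weight)."""
    if isinstance(net, MonthlyNetwork):
        frame = net.to_long_frame()
    else:
        rows, cols = np.nonzero(net.weights)
        frame = pd.DataFrame(
            {
                "plant": [net.plants[i] for i in rows],
                "pollinator": [net.pollinators[j] for j in cols],
                "weight": net.weights[rows, cols],
            }
        )
    frame.to_csv(path, index=False)


def write_network_json(net: MonthlyNetwork | MetaNetwork, path: str | Path) -> None:
    with Path(path).open("w", encoding="utf-8") as fh:
        json.dump(net.to_json_dict(), fh)


def read_network_json(path: str | Path) -> MonthlyNetwork | MetaNetwork:
    with Path(path).open(encoding="utf-8") as fh:
        obj = json.load(fh)
    if "provenance" in obj:
        return MetaNetwork(
            plants=obj["plants"],
            pollinators=obj["pollinators"],
            weights=np.asarray(obj["weights"]),
            provenance={int(m): np.asarray(w) for m, w in obj["provenance"].items()},
        )
    return MonthlyNetwork(
        month=obj["month"],
        plants=obj["plants"],
        pollinators=obj["pollinators"],
        weights=np.asarray(obj["weights"]),
    )
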