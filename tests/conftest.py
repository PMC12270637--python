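import numpy as np
import pytest

from pollnet.data_io import MonthlyNetwork, build_monthly_networks
from pollnet.synthcom import CommunityConfig, simulate_year


@pytest.fixture
def diagonal_2x2():
    """Two exclusive plant-pollinator pairs: maximal specialization."""
    return MonthlyNetwork(1, ["P1", "P2"], ["A1", "A2"], np.array([[3, 0], [0, 3]]))


@pytest.fixture
def bipartite_path():
    """P1–A1–P2–A2–P3: a five-vertex path through plant P2."""
    return MonthlyNetwork(
        1, ["P1", "P2", "P3"], ["A1", "A2"], np.array([[1, 0], [1, 1], [0, 1]])
    )


@pytest.fixture
def two_blocks():
    """Two disconnected complete 2x2 blocks with unit weights."""
    w = np.zeros((4, 4), dtype=int)
    w[:2, :2] = 1
    w[2:, 2:] = 1
    return MonthlyNetwork(
        1, ["P1", "P2", "P3", "P4"], ["A1", "A2", "A3", "A4"], w
    )


def random_network(rng: np.random.Generator, month: int = 1) -> MonthlyNetwork:
    """Small random quantitative network with no empty rows/columns."""
    while True:
        n_p = int(rng.integers(2, 6))
        n_a = int(rng.integers(2, 6))
        w = rng.poisson(1.2, size=(n_p, n_a))
        w = w[w.sum(axis=1) > 0][:, w.sum(axis=0) > 0]
        w = w[:, w.sum(axis=0) > 0]
        if w.size and w.shape[0] >= 1 and w.shape[1] >= 1 and w.sum() > 0:
            break
    plants = [f"P{k}" for k in range(1, w.shape[0] + 1)]
    pols = [f"A{k}" for k in range(1, w.shape[1] + 1)]
    return MonthlyNetwork(month, plants, pols, w)


@pytest.fixture(scope="session")
def paper_year():
    """One paper-scale synthetic year (events, metadata, ledger)."""
    return simulate_year(CommunityConfig(seed=11))


@pytest.fixture(scope="session")
def small_year():
    """A small, fast synthetic year for pipeline-level tests."""
    config = CommunityConfig(
        n_plants=25,
        n_pollinators=25,
        n_blocks=3,
        n_long_flowering=2,
        n_long_active_pollinators=2,
        within_block_rate=1.5,
        between_block_rate=0.15,
        seed=7,
    )
    return simulate_year(config)


@pytest.fixture(scope="session")
def small_networks(small_year):
    events, _, _ = small_year
    return build_monthly_networks(events)
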