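import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from pollnet.data_io import (
    InteractionEvent,
    MonthlyNetwork,
    SpeciesMetadata,
    aggregate_meta_network,
    build_monthly_networks,
    metadata_index,
)
from pollnet.roles import (
    among_module_connectivity,
    betweenness,
    betweenness_all,
    classify_core,
    classify_meta_roles,
    d_extremes,
    d_prime,
    hub_temporal_composition,
    meta_roles,
    monthly_roles,
    within_module_degree_z,
)
from pollnet.synthcom import CommunityConfig, simulate_year

from _oracles import betweenness_oracle, d_extremes_oracle


def _net(weights, month=1):
    w = np.asarray(weights)
    return MonthlyNetwork(
        month,
        [f"P{k}" for k in range(1, w.shape[0] + 1)],
        [f"A{k}" for k in range(1, w.shape[1] + 1)],
        w,
    )


class TestDPrime:
    def test_exclusive_partner_fully_specialized(self, diagonal_2x2):
        assert d_prime(diagonal_2x2, "P1") == pytest.approx(1.0)
        assert d_prime(diagonal_2x2, "P2") == pytest.approx(1.0)

    def test_availability_proportional_is_zero(self):
        net = _net([[4, 2], [2, 1]])
        assert d_prime(net, "P1") == pytest.approx(0.0)

    def test_unknown_species_rejected(self, diagonal_2x2):
        with pytest.raises(KeyError):
            d_prime(diagonal_2x2, "P9")

    def test_extremes_match_enumeration(self):
        rng = np.random.default_rng(12)
        checked = 0
        while checked < 12:
            w = rng.integers(0, 3, size=(3, 3))
            r, c = w.sum(axis=1), w.sum(axis=0)
            if r.min() == 0 or c.min() == 0 or r.max() > 6 or c.max() > 6:
                continue
            for row_total in r:
                assert d_extremes(int(row_total), c) == pytest.approx(
                    d_extremes_oracle(int(row_total), list(c)), abs=1e-10
                )
            checked += 1

    def test_unit_interval(self):
        rng = np.random.default_rng(2)
        for _ in range(10):
            w = rng.poisson(1.5, size=(4, 4)) + np.eye(4, dtype=int)
            net = _net(w)
            for plant in net.plants:
                assert 0.0 <= d_prime(net, plant) <= 1.0


class TestBetweenness:
    def test_path_center(self, bipartite_path):
        raw, std = betweenness(bipartite_path, "P2")
        assert raw == pytest.approx(4.0)
        assert std == pytest.approx(2 * 4 / (4 * 3))

    def test_leaf_is_zero(self, bipartite_path):
        assert betweenness(bipartite_path, "P1") == (0.0, 0.0)

    def test_star_center_attains_one(self):
        net = _net(np.ones((1, 5), dtype=int))
        raw, std = betweenness(net, "P1")
        assert std == pytest.approx(1.0)

    def test_tiny_network_standardization_zero(self):
        net = _net([[1]])
        assert betweenness(net, "P1") == (0.0, 0.0)

    def test_matches_path_counting_oracle(self):
        rng = np.random.default_rng(31)
        for _ in range(8):
            n_p, n_a = int(rng.integers(2, 7)), int(rng.integers(2, 7))
            w = (rng.random((n_p, n_a)) < 0.4).astype(int)
            w = w[w.sum(axis=1) > 0][:, w.sum(axis=0) > 0]
            w = w[:, w.sum(axis=0) > 0]
            if w.size == 0 or w.shape[0] + w.shape[1] > 12:
                continue
            net = _net(w)
            adjacency = {sp: set() for sp in net.plants + net.pollinators}
            for (p, a) in net.links():
                adjacency[p].add(a)
                adjacency[a].add(p)
            table = betweenness_all(net)
            for sp in adjacency:
                assert table[sp][0] == pytest.approx(
                    betweenness_oracle(adjacency, sp), abs=1e-9
                )


class TestClassifyCore:
    def test_exact_threshold_not_core(self):
        from pollnet.roles import SpeciesMonthRole

        role = SpeciesMonthRole(
            month=1, species="P1", d_prime=0.5, betweenness_raw=1.0, betweenness_std=0.25
        )
        assert not role.is_core

    def test_all_peripheral_month_empty_core(self, diagonal_2x2):
        table = classify_core(monthly_roles(diagonal_2x2))
        assert not table["is_core"].any()

    def test_planted_bridge_species_flagged(self):
        # two K2,2 blocks joined only through plant PB
        plants = ["P1", "P2", "P3", "P4", "PB"]
        pols = ["A1", "A2", "A3", "A4"]
        w = np.zeros((5, 4), dtype=int)
        w[0:2, 0:2] = 1
        w[2:4, 2:4] = 1
        w[4, 1] = 1  # bridge into block 1
        w[4, 2] = 1  # bridge into block 2
        net = MonthlyNetwork(1, plants, pols, w)
        table = classify_core(monthly_roles(net))
        assert table.loc[table["is_core"], "species"].tolist() == ["PB"]

    def test_origin_annotation(self, diagonal_2x2):
        metadata = metadata_index(
            [
                SpeciesMetadata(species="P1", guild="plant", origin="native"),
                SpeciesMetadata(species="P2", guild="plant", origin="exotic"),
            ]
        )
        table = classify_core(monthly_roles(diagonal_2x2), metadata)
        assert set(table["origin"]) == {"native", "exotic"}


class TestMetaRoleMetrics:
    def test_uniform_module_degrees_give_zero_z(self, two_blocks):
        partition = {"P1": 0, "P2": 0, "A1": 0, "A2": 0, "P3": 1, "P4": 1, "A3": 1, "A4": 1}
        with pytest.warns(UserWarning):
            assert within_module_degree_z(two_blocks, partition, "P1") == 0.0

    def test_hand_computed_z(self):
        # module {P1, A1, A2, A3}: within-degrees {3, 1, 1, 1}
        net = _net([[1, 1, 1]])
        partition = {"P1": 0, "A1": 0, "A2": 0, "A3": 0}
        z = within_module_degree_z(net, partition, "P1")
        assert z == pytest.approx((3 - 1.5) / np.sqrt(0.75), abs=1e-9)

    def test_z_centering_within_modules(self, small_year):
        from pollnet.modules import detect_modules

        events, _, _ = small_year
        meta = aggregate_meta_network(build_monthly_networks(events))
        part = detect_modules(meta, seed=1, restarts=10)
        roles = meta_roles(meta, part, species=sorted(part.assignment))
        z_by_module = {}
        for role in roles:
            z_by_module.setdefault(part.assignment[role.species], []).append(role.z)
        for zs in z_by_module.values():
            assert abs(np.mean(zs)) < 1e-9

    def test_all_links_within_module_zero_connectivity(self, two_blocks):
        partition = {"P1": 0, "P2": 0, "A1": 0, "A2": 0, "P3": 1, "P4": 1, "A3": 1, "A4": 1}
        assert among_module_connectivity(two_blocks, partition, "P1") == pytest.approx(0.0)

    def test_even_split_two_modules(self):
        net = _net([[1, 1, 1, 1]])
        partition = {"P1": 0, "A1": 0, "A2": 0, "A3": 1, "A4": 1}
        assert among_module_connectivity(net, partition, "P1") == pytest.approx(0.5)

    @pytest.mark.parametrize("n_modules", [2, 3, 4, 6])
    def test_even_spread_closed_form(self, n_modules):
        net = _net(np.ones((1, n_modules), dtype=int))
        partition = {"P1": 0}
        partition.update({f"A{k}": k - 1 for k in range(1, n_modules + 1)})
        c = among_module_connectivity(net, partition, "P1")
        assert c == pytest.approx(1 - 1 / n_modules)


class TestClassifyMetaRoles:
    @pytest.mark.parametrize(
        "z,c,expected",
        [
            (3.0, 0.7, "super_generalist"),
            (3.0, 0.62, "module_hub"),
            (0.0, 0.7, "connector"),
            (0.0, 0.1, "peripheral"),
            (2.5, 0.7, "connector"),  # strict inequality on z
        ],
    )
    def test_reference_points(self, z, c, expected):
        assert classify_meta_roles(z, c) == expected

    @settings(max_examples=200, derandomize=True)
    @given(
        z=st.floats(-5, 10, allow_nan=False),
        c=st.floats(0, 0.999, allow_nan=False),
    )
    def test_plane_is_partitioned(self, z, c):
        roles = {"peripheral", "module_hub", "connector", "super_generalist"}
        assert classify_meta_roles(z, c) in roles


class TestHubTemporalComposition:
    def _metadata(self):
        return metadata_index(
            [
                SpeciesMetadata(species="A1", guild="pollinator", order="Hymenoptera"),
                SpeciesMetadata(species="A2", guild="pollinator", order="Diptera"),
            ]
        )

    def test_single_order_visitor(self):
        events = [
            InteractionEvent(month=m, plant="P1", pollinator="A1", count=m) for m in (1, 2)
        ]
        comp = hub_temporal_composition("P1", events, self._metadata())
        assert comp["Hymenoptera"].tolist() == [1, 2]
        assert comp["Diptera"].sum() == 0

    def test_monthly_sums_match_marginals(self, small_year):
        events, metadata, _ = small_year
        md_index = metadata_index(metadata)
        networks = build_monthly_networks(events)
        plant = networks[1].plants[0]
        comp = hub_temporal_composition(plant, events, md_index)
        for month, row in comp.iterrows():
            net = networks[month]
            marginal = net.weights[net.plants.index(plant)].sum()
            assert row.sum() == marginal

    def test_long_flowering_generalist_spans_months(self):
        config = CommunityConfig(
            n_plants=12,
            n_pollinators=12,
            n_blocks=1,
            n_long_flowering=1,
            n_long_active_pollinators=4,
            within_block_rate=3.0,
            between_block_rate=0.3,
            seed=19,
        )
        events, metadata, ledger = simulate_year(config)
        hub = next(
            sp for sp, (_, duration) in ledger.phenology.items()
            if sp.startswith("P") and duration >= 9
        )
        comp = hub_temporal_composition(hub, events, metadata_index(metadata))
        assert len(comp) >= 9

    def test_meta_marginal_reconstruction(self, small_year):
        events, metadata, _ = small_year
        md_index = metadata_index(metadata)
        meta = aggregate_meta_network(build_monthly_networks(events))
        plant = meta.plants[0]
        comp = hub_temporal_composition(plant, events, md_index)
        assert comp.values.sum() == meta.weights[meta.plants.index(plant)].sum()
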