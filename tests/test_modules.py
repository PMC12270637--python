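import collections

import numpy as np
import pytest

from pollnet.data_io import MonthlyNetwork, SpeciesMetadata, build_monthly_networks, metadata_index
from pollnet.metrics import barber_modularity
from pollnet.modules import (
    compare_algorithms,
    detect_modules,
    module_composition,
    module_flows,
)
from pollnet.synthcom import planted_blocks_network, planted_fission_fixture

from _oracles import barber_q_oracle


class TestDetectModules:
    @pytest.mark.parametrize("algorithm", ["louvain", "fast_greedy"])
    @pytest.mark.parametrize("seed", [1, 7, 99])
    def test_two_disconnected_blocks_recovered(self, two_blocks, algorithm, seed):
        part = detect_modules(two_blocks, algorithm=algorithm, seed=seed)
        assert part.n_modules == 2
        groups = collections.defaultdict(set)
        for sp, mod in part.assignment.items():
            groups[mod].add(sp)
        assert set(frozenset(g) for g in groups.values()) == {
            frozenset({"P1", "P2", "A1", "A2"}),
            frozenset({"P3", "P4", "A3", "A4"}),
        }

    def test_single_link_single_module(self):
        net = MonthlyNetwork(1, ["P1"], ["A1"], np.array([[2]]))
        part = detect_modules(net, seed=1)
        assert part.n_modules == 1
        assert part.q == pytest.approx(0.0)

    def test_unknown_algorithm_rejected(self, two_blocks):
        with pytest.raises(ValueError, match="unknown algorithm"):
            detect_modules(two_blocks, algorithm="infomap")

    def test_deterministic_given_seed(self):
        net, _ = planted_blocks_network(seed=3)
        a = detect_modules(net, seed=5, restarts=10)
        b = detect_modules(net, seed=5, restarts=10)
        assert a.assignment == b.assignment
        assert a.q == b.q

    def test_reported_q_matches_independent_recompute(self):
        net, _ = planted_blocks_network(seed=2)
        part = detect_modules(net, seed=1, restarts=10)
        assert part.q == pytest.approx(barber_modularity(net, part.assignment), abs=1e-12)
        oracle = barber_q_oracle(
            net.weights,
            [part.assignment[p] for p in net.plants],
            [part.assignment[a] for a in net.pollinators],
        )
        assert part.q == pytest.approx(oracle, abs=1e-12)

    def test_q_at_least_single_module_baseline(self):
        net, _ = planted_blocks_network(seed=4)
        part = detect_modules(net, seed=1, restarts=10)
        assert part.q >= 0.0

    def test_modal_partition_stable_across_seeds(self):
        net, _ = planted_blocks_network(seed=10)
        outcomes = collections.Counter()
        for seed in range(30):
            part = detect_modules(net, seed=seed, restarts=10)
            outcomes[tuple(sorted(part.assignment.items()))] += 1
        assert outcomes.most_common(1)[0][1] / 30 >= 0.8


class TestCompareAlgorithms:
    def test_duplicate_algorithm_rows_identical(self, two_blocks):
        table = compare_algorithms(
            two_blocks, seeds=[1, 2], algorithms=("louvain", "louvain")
        )
        assert table.iloc[0]["best_q"] == table.iloc[1]["best_q"]
        assert table.iloc[0]["mean_q"] == table.iloc[1]["mean_q"]

    def test_louvain_at_least_fast_greedy_on_planted_blocks(self):
        net, _ = planted_blocks_network(seed=6)
        table = compare_algorithms(net, seeds=[1, 2, 3]).set_index("algorithm")
        assert table.loc["louvain", "best_q"] >= table.loc["fast_greedy", "best_q"] - 1e-12

    def test_empty_seed_list_rejected(self, two_blocks):
        with pytest.raises(ValueError):
            compare_algorithms(two_blocks, seeds=[])


class TestModuleFlows:
    def test_identity_assignment_identity_flows(self):
        p = {"P1": 0, "A1": 0, "P2": 1, "A2": 1}
        part1 = _partition("month-1", p)
        part2 = _partition("month-2", p)
        flows = module_flows(part1, part2)
        assert all(f.source[1] == f.target[1] for f in flows)
        assert sum(f.n_species for f in flows) == 4

    def test_species_absent_next_month_contributes_nothing(self):
        part1 = _partition("month-1", {"P1": 0, "A1": 0, "P9": 0})
        part2 = _partition("month-2", {"P1": 0, "A1": 0})
        flows = module_flows(part1, part2)
        assert sum(f.n_species for f in flows) == 2
        assert all("P9" not in f.species for f in flows)

    def test_fission_fixture_two_outflows(self):
        events, info = planted_fission_fixture(seed=1)
        networks = build_monthly_networks(events)
        part1 = detect_modules(networks[1], seed=1)
        part2 = detect_modules(networks[2], seed=1)
        flows = module_flows(part1, part2)
        source = part1.assignment[info["source_block"][0]]
        out = [f for f in flows if f.source == (1, source)]
        assert len(out) == 2
        assert sum(f.n_species for f in out) == len(info["source_block"])

    def test_reversed_months_show_fusion(self):
        events, info = planted_fission_fixture(seed=1)
        networks = build_monthly_networks(events)
        part1 = detect_modules(networks[1], seed=1)
        part2 = detect_modules(networks[2], seed=1)
        flows = module_flows(part2, part1)
        target = part1.assignment[info["source_block"][0]]
        incoming = [f for f in flows if f.target == (1, target)]
        assert len(incoming) == 2

    def test_flow_conservation(self):
        events, _ = planted_fission_fixture(seed=5)
        networks = build_monthly_networks(events)
        part1 = detect_modules(networks[1], seed=1)
        part2 = detect_modules(networks[2], seed=1)
        flows = module_flows(part1, part2)
        shared = set(part1.assignment) & set(part2.assignment)
        for module in set(part1.assignment.values()):
            members = {s for s, m in part1.assignment.items() if m == module}
            outflow = sum(f.n_species for f in flows if f.source == (1, module))
            assert outflow == len(members & shared)


class TestModuleComposition:
    def test_counts_by_origin_and_order(self):
        part = _partition("month-1", {"P1": 0, "P2": 0, "A1": 0, "A2": 0, "A3": 0})
        metadata = metadata_index(
            [
                SpeciesMetadata(species="P1", guild="plant", origin="native"),
                SpeciesMetadata(species="P2", guild="plant", origin="native"),
                SpeciesMetadata(species="A1", guild="pollinator", order="Hymenoptera"),
                SpeciesMetadata(species="A2", guild="pollinator", order="Hymenoptera"),
                SpeciesMetadata(species="A3", guild="pollinator", order="Hymenoptera"),
            ]
        )
        (comp,) = module_composition(part, metadata)
        assert (comp.n_native, comp.n_exotic) == (2, 0)
        assert comp.order_counts["Hymenoptera"] == 3
        assert comp.size == 5

    def test_missing_metadata_names_species(self):
        part = _partition("month-1", {"P1": 0})
        with pytest.raises(KeyError, match="P1"):
            module_composition(part, {})

    def test_sizes_sum_to_partition_size(self, small_year):
        events, metadata, _ = small_year
        networks = build_monthly_networks(events)
        part = detect_modules(networks[1], seed=1)
        comps = module_composition(part, metadata_index(metadata))
        assert sum(c.size for c in comps) == len(part.assignment)

    def test_generator_labels_recovered_exactly(self, small_year):
        events, metadata, ledger = small_year
        networks = build_monthly_networks(events)
        part = detect_modules(networks[1], seed=1)
        comps = module_composition(part, metadata_index(metadata))
        for comp in comps:
            members = part.members(comp.module)
            assert comp.n_native == sum(
                1 for s in members if ledger.origin.get(s) == "native"
            )
            for order, count in comp.order_counts.items():
                assert count == sum(1 for s in members if ledger.order.get(s) == order)


def _partition(network_id, assignment):
    from pollnet.modules import ModulePartition

    return ModulePartition(
        network_id=network_id, assignment=assignment, q=0.0, algorithm="louvain", seed=1
    )
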