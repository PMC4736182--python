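"""Valve-graph routing, volume quantization, actuation programs."""

import itertools

import networkx as nx
import pytest

from chipsyn.chipcompile import (
    ChipGraph,
    CycleConstants,
    RoutingError,
    TransferCommand,
    compile_transfers,
    compile_with_washes,
    contamination_report,
    cycles_for_volume,
    grid_chip,
    replay_program,
    shortest_route,
)


@pytest.fixture(scope="module")
def chip():
    # the physical platform's topology class: a valve array ringed by
    # 16 peripheral macro wells
    return grid_chip(5, 5)


class TestRouting:
    def test_grid_corner_to_corner_hops(self):
        chip = grid_chip(4, 4)
        route = shortest_route(chip, "v0-0", "v3-3")
        assert len(route) == 7  # 6 hops across a 4x4 valve grid
        # independent check: enumerate all simple paths of minimal length
        shortest = min(
            len(p) for p in nx.all_simple_paths(chip.graph, "v0-0", "v3-3", cutoff=7)
        )
        assert len(route) == shortest

    def test_adjacent_nodes_two_node_path(self, chip):
        assert shortest_route(chip, "v0-0", "v0-1") == ("v0-0", "v0-1")

    def test_every_well_pair_routable_and_bfs_minimal(self, chip):
        wells = [n for n, d in chip.graph.nodes(data=True) if d["kind"] == "well"]
        assert len(wells) == 16  # 5x5 valve grid rings 16 peripheral wells
        for a, b in itertools.combinations(wells, 2):
            route = shortest_route(chip, a, b)
            assert len(route) - 1 == nx.shortest_path_length(chip.graph, a, b)
            assert all(chip.graph.has_edge(x, y) for x, y in zip(route, route[1:]))

    def test_deterministic_lexicographic_tie_break(self, chip):
        r1 = shortest_route(chip, "w0", "w7")
        r2 = shortest_route(chip, "w0", "w7")
        assert r1 == r2
        # among equal-length predecessors the smallest id is taken at each step
        for i in range(1, len(r1) - 1):
            u, chosen = r1[i - 1], r1[i]
            d_rest = nx.shortest_path_length(chip.graph, target=r1[-1])
            ties = [
                v for v in chip.graph.neighbors(u) if d_rest[v] == d_rest[u] - 1
            ]
            assert chosen == min(ties)

    def test_disconnected_endpoint_raises(self):
        chip = grid_chip(3, 3)
        chip.graph.add_node("island", kind="well")
        with pytest.raises(RoutingError):
            shortest_route(chip, "w0", "island")


class TestCycles:
    @pytest.mark.parametrize(
        "amount_ul,expected",
        [(0.150, 1), (0.151, 2), (15.0, 100), (0.0001, 1), (1.0, 7)],
    )
    def test_ceiling_quantization(self, amount_ul, expected):
        assert cycles_for_volume(amount_ul) == expected

    def test_never_under_delivers(self):
        for amount in (0.01, 0.149, 0.15, 0.2999, 0.45, 2.0):
            n = cycles_for_volume(amount)
            assert (n - 1) * 150 < amount * 1000 <= n * 150

    def test_custom_cycle_volume(self):
        assert cycles_for_volume(1.0, CycleConstants(cycle_volume_nl=250)) == 4


class TestCompile:
    def test_empty_protocol_empty_program(self, chip):
        program = compile_transfers([], chip)
        assert program.sections == []
        assert program.to_csv().count("\n") == 1  # header only

    def test_single_transfer_replay_conserves_volume(self, chip):
        cmds = [TransferCommand("w0", "w7", 0.45, 120.0)]
        program = compile_transfers(cmds, chip)
        assert program.sections[0].cycles == 3
        volumes = replay_program(program, chip)
        assert volumes["w0"] == -3 * 150
        assert volumes["w7"] == +3 * 150
        assert sum(volumes.values()) == 0

    def test_reagent_name_resolution(self, chip):
        chip.assign_reagent("enzyme_mix", "w3")
        program = compile_transfers(
            [TransferCommand("enzyme_mix", "w8", 15.0, 200.0)], chip
        )
        assert program.sections[0].source == "w3"
        assert program.sections[0].cycles == 100
        assert program.sections[0].reagent == "enzyme_mix"

    def test_unknown_reagent_raises(self, chip):
        with pytest.raises(RoutingError, match="unknown"):
            compile_transfers([TransferCommand("nonsense", "w1", 0.3)], chip)

    def test_program_is_deterministic(self, chip):
        cmds = [
            TransferCommand("w1", "w9", 0.6, 150.0),
            TransferCommand("w2", "w10", 0.3, 100.0),
        ]
        assert (
            compile_transfers(cmds, chip).to_csv()
            == compile_transfers(cmds, chip).to_csv()
        )

    def test_fanout_protocol_all_routed(self, chip):
        # cell wells fanned out to preloaded DNA wells, one section per arrow
        cmds = [
            TransferCommand("w0", f"w{d}", 0.15, 100.0) for d in (5, 6, 7, 8, 9)
        ]
        program = compile_transfers(cmds, chip)
        assert len(program.sections) == 5
        volumes = replay_program(program, chip)
        assert volumes["w0"] == -5 * 150

    def test_every_open_is_closed(self, chip):
        program = compile_transfers([TransferCommand("w0", "w11", 0.45)], chip)
        balance = {}
        for st in program.steps:
            balance[st.valve] = balance.get(st.valve, 0) + (
                1 if st.action == "open" else -1
            )
        assert all(v == 0 for v in balance.values())


class TestContamination:
    def test_disjoint_routes_clean(self):
        chip = grid_chip(4, 4)
        program = compile_transfers(
            [
                TransferCommand("w0", "w1", 0.15, reagent="red"),
                TransferCommand("w6", "w7", 0.15, reagent="blue"),
            ],
            chip,
        )
        assert contamination_report(program) == []

    def test_shared_segment_reported(self):
        chip = grid_chip(4, 4)
        r1 = shortest_route(chip, "w0", "w7")
        r2 = shortest_route(chip, "w1", "w7")
        shared = set(zip(r1, r1[1:])) & set(zip(r2, r2[1:]))
        program = compile_transfers(
            [
                TransferCommand("w0", "w7", 0.15, reagent="red"),
                TransferCommand("w1", "w7", 0.15, reagent="blue"),
            ],
            chip,
        )
        report = contamination_report(program)
        assert {tuple(sorted(e)) for e in shared} == {r["edge"] for r in report}
        assert all(r["previous_reagent"] == "red" for r in report)

    def test_auto_wash_clears_report(self):
        chip = grid_chip(4, 4, wash_well=True)
        cmds = [
            TransferCommand("w0", "w7", 0.15, reagent="red"),
            TransferCommand("w1", "w7", 0.15, reagent="blue"),
        ]
        assert contamination_report(compile_transfers(cmds, chip)) != []
        washed = compile_with_washes(cmds, chip)
        assert contamination_report(washed) == []
        assert any(sec.reagent == "wash" for sec in washed.sections)


class TestConfig:
    def test_yaml_roundtrip(self):
        chip = grid_chip(3, 4, wash_well=True)
        chip.assign_reagent("buffer", "w0")
        text = chip.to_config()
        loaded = ChipGraph.from_config(text)
        assert set(loaded.graph.nodes) == set(chip.graph.nodes)
        assert set(map(frozenset, loaded.graph.edges)) == set(
            map(frozenset, chip.graph.edges)
        )
        assert loaded.reagents == chip.reagents
        assert loaded.wash_well == "wash"

    def test_disconnected_config_rejected(self):
        text = """
nodes:
  a: {kind: well}
  b: {kind: well}
edges: []
"""
        with pytest.raises(ValueError):
            ChipGraph.from_config(text)
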