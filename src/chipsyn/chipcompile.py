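"""Microvalve-array transfer compilation.

The chip is an undirected graph: input/output wells and valve junctions
are nodes, channels are edges. A transfer statement (Source, Destination,
Amount, Method) is compiled into a minimum-hop route, a cycle count (each
peristaltic cycle moves one fixed 150 nL quantum, so requested volumes
are rounded up to whole cycles), and a valve actuation schedule: a
three-valve traveling wave walked along the route once per cycle. The
actuation dwell per step is the Method's per-valve time, settable once
per reagent and overridable per command. Compilation is deterministic;
identical inputs give byte-identical programs.
"""

from __future__ import annotations

import io
import math
from collections import deque
from dataclasses import dataclass, field

import networkx as nx
import yaml

__all__ = [
    "ChipGraph",
    "TransferCommand",
    "ActuationStep",
    "ProgramSection",
    "ActuationProgram",
    "CycleConstants",
    "RoutingError",
    "shortest_route",
    "cycles_for_volume",
    "compile_transfers",
    "replay_program",
    "contamination_report",
    "grid_chip",
]

WAVE_WIDTH = 3  # valves simultaneously engaged in the peristaltic wave


class RoutingError(RuntimeError):
    pass


@dataclass(frozen=True)
class CycleConstants:
    cycle_volume_nl: float = 150.0


@dataclass
class ChipGraph:
    """Undirected well/valve graph with a reagent location map."""

    graph: nx.Graph = field(default_factory=nx.Graph)
    reagents: dict[str, str] = field(default_factory=dict)  # reagent -> node id
    constants: CycleConstants = field(default_factory=CycleConstants)
    wash_well: str | None = None
    reagent_dwell_ms: dict[str, float] = field(default_factory=dict)

    def add_well(self, node_id: str, **attrs) -> None:
        self.graph.add_node(node_id, kind="well", **attrs)

    def add_valve(self, node_id: str, **attrs) -> None:
        self.graph.add_node(node_id, kind="valve", **attrs)

    def add_channel(self, a: str, b: str) -> None:
        self.graph.add_edge(a, b)

    def assign_reagent(self, reagent: str, node_id: str) -> None:
        if node_id not in self.graph:
            raise KeyError(f"unknown node {node_id}")
        self.reagents[reagent] = node_id

    def resolve(self, endpoint: str) -> str:
        """Resolve a node id or reagent name to a node id."""
        if endpoint in self.graph:
            return endpoint
        if endpoint in self.reagents:
            return self.reagents[endpoint]
        raise RoutingError(f"unknown node or reagent '{endpoint}'")

    def validate(self) -> None:
        if self.graph.number_of_nodes() and not nx.is_connected(self.graph):
            raise ValueError("chip graph is not connected")
        for n, d in self.graph.nodes(data=True):
            if d.get("kind") == "well" and self.graph.degree(n) < 1:
                raise ValueError(f"well {n} has no channel")

    @classmethod
    def from_config(cls, text: str) -> "ChipGraph":
        """Load a chip from a YAML/JSON config.

        Keys: ``nodes`` (id -> {kind, x, y}), ``edges`` (list of pairs),
        ``reagents`` (name -> node), ``cycle_volume_nl``, ``wash_well``,
        ``reagent_dwell_ms`` (name -> per-step dwell).
        """
        cfg = yaml.safe_load(text)
        chip = cls(constants=CycleConstants(float(cfg.get("cycle_volume_nl", 150.0))))
        for nid, attrs in cfg.get("nodes", {}).items():
            attrs = attrs or {}
            kind = attrs.pop("kind", "valve")
            chip.graph.add_node(str(nid), kind=kind, **attrs)
        for a, b in cfg.get("edges", []):
            chip.graph.add_edge(str(a), str(b))
        for reagent, nid in (cfg.get("reagents") or {}).items():
            chip.assign_reagent(reagent, str(nid))
        chip.wash_well = cfg.get("wash_well")
        chip.reagent_dwell_ms = {
            k: float(v) for k, v in (cfg.get("reagent_dwell_ms") or {}).items()
        }
        chip.validate()
        return chip

    def to_config(self) -> str:
        cfg = {
            "cycle_volume_nl": self.constants.cycle_volume_nl,
            "nodes": {
                n: {"kind": d.get("kind", "valve"), **{k: v for k, v in d.items() if k != "kind"}}
                for n, d in sorted(self.graph.nodes(data=True))
            },
            "edges": sorted([sorted(e) for e in self.graph.edges()]),
            "reagents": dict(sorted(self.reagents.items())),
        }
        if self.wash_well:
            cfg["wash_well"] = self.wash_well
        if self.reagent_dwell_ms:
            cfg["reagent_dwell_ms"] = dict(sorted(self.reagent_dwell_ms.items()))
        return yaml.safe_dump(cfg, sort_keys=False)


@dataclass(frozen=True)
class TransferCommand:
    source: str  # node id or reagent name
    destination: str
    amount_ul: float
    method_ms: float | None = None  # None: use the reagent's default dwell
    reagent: str | None = None

    def __post_init__(self) -> None:
        if self.amount_ul <= 0:
            raise ValueError("transfer amount must be positive")
        if self.source == self.destination:
            raise ValueError("source and destination must differ")


@dataclass(frozen=True)
class ActuationStep:
    valve: str
    action: str  # 'open' | 'close'
    dwell_ms: float


@dataclass
class ProgramSection:
    source: str
    destination: str
    reagent: str
    route: tuple[str, ...]
    cycles: int
    steps: tuple[ActuationStep, ...]


@dataclass
class ActuationProgram:
    sections: list[ProgramSection] = field(default_factory=list)
    constants: CycleConstants = field(default_factory=CycleConstants)

    @property
    def steps(self) -> list[ActuationStep]:
        return [s for sec in self.sections for s in sec.steps]

    def to_csv(self) -> str:
        buf = io.StringIO()
        buf.write("section,reagent,valve,action,dwell_ms\n")
        for i, sec in enumerate(self.sections):
            for st in sec.steps:
                buf.write(f"{i},{sec.reagent},{st.valve},{st.action},{st.dwell_ms:g}\n")
        return buf.getvalue()

    def route_log(self) -> str:
        lines = []
        for sec in self.sections:
            lines.append(
                f"{sec.reagent}: {sec.source} -> {sec.destination} "
                f"[{' > '.join(sec.route)}] x{sec.cycles} cycles"
            )
        return "\n".join(lines)


def shortest_route(chip: ChipGraph, source: str, destination: str) -> tuple[str, ...]:
    """Minimum-hop path by breadth-first search, lexicographic tie-break.

    Determinism: among equally short paths, the one that is lexicographically
    smallest by node id, step by step from the source, is returned.
    """
    g = chip.graph
    src, dst = chip.resolve(source), chip.resolve(destination)
    if src == dst:
        return (src,)
    dist = {src: 0}
    q = deque([src])
    while q:
        u = q.popleft()
        for v in sorted(g.neighbors(u)):
            if v not in dist:
                dist[v] = dist[u] + 1
                q.append(v)
    if dst not in dist:
        raise RoutingError(f"no path from {src} to {dst}")
    # walk forward greedily: always the lexicographically smallest neighbor
    # one step closer to the destination (dist to dst via reverse BFS)
    rdist = {dst: 0}
    q = deque([dst])
    while q:
        u = q.popleft()
        for v in sorted(g.neighbors(u)):
            if v not in rdist:
                rdist[v] = rdist[u] + 1
                q.append(v)
    path = [src]
    while path[-1] != dst:
        u = path[-1]
        nxt = min(
            v for v in g.neighbors(u) if rdist.get(v, math.inf) == rdist[u] - 1
        )
        path.append(nxt)
    return tuple(path)


def cycles_for_volume(amount_ul: float, constants: CycleConstants | None = None) -> int:
    """Cycles needed to deliver at least ``amount_ul``; never under-delivers."""
    constants = constants or CycleConstants()
    if amount_ul <= 0:
        raise ValueError("amount must be positive")
    return math.ceil(round(amount_ul * 1000.0 / constants.cycle_volume_nl, 9))


def _wave_steps(route: tuple[str, ...], dwell_ms: float) -> list[ActuationStep]:
    """One peristaltic cycle: a WAVE_WIDTH-valve wave walked along the route."""
    steps = []
    for i, node in enumerate(route):
        if i >= WAVE_WIDTH:
            steps.append(ActuationStep(route[i - WAVE_WIDTH], "close", dwell_ms))
        steps.append(ActuationStep(node, "open", dwell_ms))
    for node in route[-WAVE_WIDTH:]:
        steps.append(ActuationStep(node, "close", dwell_ms))
    return steps


def compile_transfers(
    protocol: list[TransferCommand], chip: ChipGraph
) -> ActuationProgram:
    """Compile transfer statements into a valve actuation program."""
    program = ActuationProgram(constants=chip.constants)
    for cmd in protocol:
        route = shortest_route(chip, cmd.source, cmd.destination)
        cycles = cycles_for_volume(cmd.amount_ul, chip.constants)
        reagent = cmd.reagent or _infer_reagent(chip, cmd.source)
        dwell = (
            cmd.method_ms
            if cmd.method_ms is not None
            else chip.reagent_dwell_ms.get(reagent, 100.0)
        )
        steps = tuple(
            st for _ in range(cycles) for st in _wave_steps(route, dwell)
        )
        program.sections.append(
            ProgramSection(
                source=route[0],
                destination=route[-1],
                reagent=reagent,
                route=route,
                cycles=cycles,
                steps=steps,
            )
        )
    return program


def _infer_reagent(chip: ChipGraph, source: str) -> str:
    if source in chip.reagents:
        return source
    for reagent, nid in chip.reagents.items():
        if nid == source:
            return reagent
    return source


def replay_program(program: ActuationProgram, chip: ChipGraph) -> dict[str, float]:
    """Replay a program on a virtual chip; return per-node volume change (nL).

    Validates that every section's route exists edge by edge, that the
    open/close schedule is a well-formed traveling wave (every open
    matched by a close, never more than WAVE_WIDTH valves open), and
    accounts one cycle volume per completed wave.
    """
    volumes: dict[str, float] = {n: 0.0 for n in chip.graph.nodes}
    qv = program.constants.cycle_volume_nl
    for sec in program.sections:
        for a, b in zip(sec.route, sec.route[1:]):
            if not chip.graph.has_edge(a, b):
                raise RoutingError(f"route uses missing channel {a}-{b}")
        open_now: set[str] = set()
        opened_order: list[str] = []
        waves = 0
        for st in sec.steps:
            if st.action == "open":
                if st.valve in open_now:
                    raise RoutingError(f"valve {st.valve} opened twice")
                open_now.add(st.valve)
                opened_order.append(st.valve)
                if len(open_now) > WAVE_WIDTH:
                    raise RoutingError("more than WAVE_WIDTH valves open")
            else:
                if st.valve not in open_now:
                    raise RoutingError(f"valve {st.valve} closed while shut")
                open_now.remove(st.valve)
            if not open_now and opened_order:
                if tuple(opened_order) != sec.route:
                    raise RoutingError("wave did not traverse the declared route")
                waves += 1
                opened_order = []
        if open_now:
            raise RoutingError("program left valves open")
        if waves != sec.cycles:
            raise RoutingError(
                f"section declares {sec.cycles} cycles but replays {waves}"
            )
        moved = waves * qv
        volumes[sec.route[0]] -= moved
        volumes[sec.route[-1]] += moved
    return volumes


def contamination_report(
    program: ActuationProgram,
) -> list[dict]:
    """Channel segments reused by transfers of different reagents, in order.

    A segment is an undirected channel edge. Each record names the edge,
    the reagent that last wet it, and the reagent now routed through it.
    Wash sections (reagent 'wash') clear prior residue.
    """
    last_reagent: dict[tuple[str, str], str] = {}
    report: list[dict] = []
    for i, sec in enumerate(program.sections):
        for a, b in zip(sec.route, sec.route[1:]):
            edge = tuple(sorted((a, b)))
            prev = last_reagent.get(edge)
            if (
                prev is not None
                and sec.reagent != "wash"  # the flush itself is the remedy
                and prev != sec.reagent
                and prev != "wash"
            ):
                report.append(
                    {
                        "section": i,
                        "edge": edge,
                        "previous_reagent": prev,
                        "reagent": sec.reagent,
                    }
                )
            last_reagent[edge] = sec.reagent
    return report


def insert_washes(
    protocol: list[TransferCommand], chip: ChipGraph
) -> list[TransferCommand]:
    """Insert buffer flushes so no transfer runs through another reagent's residue.

    Requires ``chip.wash_well``. Before any command whose route shares a
    channel previously wetted by a different reagent, a wash transfer is
    inserted that routes buffer from the wash well through the upcoming
    pathway (wash well -> source -> destination), clearing it.
    """
    if chip.wash_well is None:
        raise RoutingError("no wash well designated on this chip")
    out: list[TransferCommand] = []
    last_reagent: dict[tuple[str, str], str] = {}
    for cmd in protocol:
        route = shortest_route(chip, cmd.source, cmd.destination)
        reagent = cmd.reagent or _infer_reagent(chip, cmd.source)
        dirty = any(
            last_reagent.get(tuple(sorted(e))) not in (None, reagent, "wash")
            for e in zip(route, route[1:])
        )
        if dirty:
            out.append(
                TransferCommand(
                    source=chip.wash_well,
                    destination=cmd.destination,
                    amount_ul=chip.constants.cycle_volume_nl / 1000.0,
                    method_ms=cmd.method_ms,
                    reagent="wash",
                )
            )
            wash_route = _via_route(chip, chip.wash_well, cmd.source, cmd.destination)
            for e in zip(wash_route, wash_route[1:]):
                last_reagent[tuple(sorted(e))] = "wash"
        out.append(cmd)
        for e in zip(route, route[1:]):
            last_reagent[tuple(sorted(e))] = reagent
    return out


def _via_route(chip: ChipGraph, a: str, via: str, b: str) -> tuple[str, ...]:
    first = shortest_route(chip, a, via)
    second = shortest_route(chip, via, b)
    return first + second[1:]


def compile_with_washes(
    protocol: list[TransferCommand], chip: ChipGraph
) -> ActuationProgram:
    """Compile with automatic wash insertion; wash sections route through the
    pathway they are protecting."""
    expanded = insert_washes(protocol, chip)
    program = ActuationProgram(constants=chip.constants)
    i = 0
    while i < len(expanded):
        cmd = expanded[i]
        if cmd.reagent == "wash" and i + 1 < len(expanded):
            nxt = expanded[i + 1]
            route = _via_route(chip, cmd.source, nxt.source, nxt.destination)
            cycles = cycles_for_volume(cmd.amount_ul, chip.constants)
            dwell = cmd.method_ms if cmd.method_ms is not None else 100.0
            steps = tuple(
                st for _ in range(cycles) for st in _wave_steps(route, dwell)
            )
            program.sections.append(
                ProgramSection(route[0], route[-1], "wash", route, cycles, steps)
            )
        else:
            program.sections.extend(compile_transfers([cmd], chip).sections)
        i += 1
    return program


def grid_chip(
    rows: int,
    cols: int,
    *,
    cycle_volume_nl: float = 150.0,
    wash_well: bool = False,
) -> ChipGraph:
    """Rectangular valve grid with one peripheral well per boundary valve.

    The physical platform's topology class: a rows x cols array of
    microvalves, macro wells fanned around the perimeter, one channel
    from each well to its nearest boundary valve.
    """
    chip = ChipGraph(constants=CycleConstants(cycle_volume_nl))
    for r in range(rows):
        for c in range(cols):
            chip.add_valve(f"v{r}-{c}", x=c, y=r)
    for r in range(rows):
        for c in range(cols):
            if c + 1 < cols:
                chip.add_channel(f"v{r}-{c}", f"v{r}-{c+1}")
            if r + 1 < rows:
                chip.add_channel(f"v{r}-{c}", f"v{r+1}-{c}")
    w = 0
    for r in range(rows):
        for c in (0, cols - 1):
            chip.add_well(f"w{w}")
            chip.add_channel(f"w{w}", f"v{r}-{c}")
            w += 1
    for c in range(1, cols - 1):
        for r in (0, rows - 1):
            chip.add_well(f"w{w}")
            chip.add_channel(f"w{w}", f"v{r}-{c}")
            w += 1
    if wash_well:
        chip.add_well("wash")
        chip.add_channel("wash", "v0-0")
        chip.wash_well = "wash"
    chip.validate()
    return chip
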