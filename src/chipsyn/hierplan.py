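"""Recursive division of targets into binary assembly trees.

A target longer than the synthesis threshold is split into two children
that physically share a junction overlap: with split position p and
overlap length v (both in nucleotides), the left child is S[1..p+v], the
right child S[p+1..L], and the shared overlap S[p+1..p+v]. Sibling
lengths therefore sum to the parent length plus v. Recursion continues
until every leaf is short enough to order as a synthetic oligo, or is an
anchored natural fragment used whole.

Division points are searched outward from the sequence center. Candidates
are ranked first by the total number of leaves the resulting subtrees
will need (symmetric, near-center splits minimize the number of synthesis
reactions, which is the planner's primary economy), then by the junction
overlap's mispriming score against the children's flanks, then by center
proximity, smaller overlap, and smaller split position. The ranking is
fully deterministic; planning uses no randomness.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterator, Sequence

import numpy as np

from .sequence import clean
from .similarity import DivisionScoreTable, division_score

__all__ = [
    "DivisionParams",
    "Division",
    "AssemblyNode",
    "AssemblyTree",
    "PlanningError",
    "choose_division",
    "build_tree",
    "tree_to_dot",
    "min_leaf_count",
]


class PlanningError(RuntimeError):
    """No feasible division / planning failure, with the offending context."""


@dataclass(frozen=True)
class DivisionParams:
    """Tunables of the division search.

    synthesis_threshold: longest directly synthesizable leaf (nt).
    min_overlap / max_overlap: junction overlap length bounds (nt).
    match_score: per-base weight of the mispriming score.
    tie_radius_frac: half-width of the center-outward search window as a
        fraction of node length, used for nodes longer than
        ``exhaustive_limit``; shorter nodes are scanned exhaustively.
    """

    synthesis_threshold: int = 130
    min_overlap: int = 20
    max_overlap: int = 45
    match_score: float = 1.0
    tie_radius_frac: float = 0.05
    exhaustive_limit: int = 600

    def __post_init__(self) -> None:
        if not (0 < self.min_overlap <= self.max_overlap < self.synthesis_threshold):
            raise ValueError(
                "need 0 < min_overlap <= max_overlap < synthesis_threshold, got "
                f"{self.min_overlap}/{self.max_overlap}/{self.synthesis_threshold}"
            )
        if self.synthesis_threshold < 2:
            raise ValueError("synthesis_threshold must be >= 2")

    def tie_radius(self, length: int) -> int:
        return max(1, int(round(length * self.tie_radius_frac)))


@dataclass(frozen=True)
class Division:
    """A chosen split: p = last base of the left flank (1-based), v = overlap length."""

    split_index: int
    overlap_len: int
    score: float

    def child_spans(self, length: int) -> tuple[tuple[int, int], tuple[int, int]]:
        """1-based inclusive (start, end) of the two children within the parent."""
        p, v = self.split_index, self.overlap_len
        return (1, p + v), (p + 1, length)


def _candidate_positions(length: int, params: DivisionParams) -> Iterator[tuple[int, int, int]]:
    """Yield (p, v, center_offset) candidates for a node of ``length``."""
    center = length // 2
    if length <= params.exhaustive_limit:
        lo, hi = 1, length - 1
    else:
        r = params.tie_radius(length)
        lo, hi = max(1, center - r), min(length - 1, center + r)
    for p in range(lo, hi + 1):
        off = abs(p - center)
        for v in range(params.min_overlap, params.max_overlap + 1):
            if p + v <= length - 1:
                yield p, v, off


class _LeafCounter:
    """Minimal leaf counts by node length, via a vectorized DP.

    f(L) = 1 for L <= threshold, else min over candidate (p, v) of
    f(p+v) + f(L-p). The DP always applies the center-outward candidate
    rule (tie radius at every length, no exhaustive widening): the
    planner's economy is defined by symmetric division, and letting the
    estimate chase lopsided splits would reward chain-shaped trees.
    Memoized per parameter set.
    """

    def __init__(self, params: DivisionParams):
        self.params = params
        self._f = np.ones(params.synthesis_threshold + 1, dtype=np.int64)
        self._f[0] = 0

    def __call__(self, length: int) -> int:
        if length < len(self._f):
            return int(self._f[length])
        params = self.params
        f = self._f
        old = len(f)
        f = np.concatenate([f, np.zeros(length + 1 - old, dtype=np.int64)])
        center_of = lambda L: L // 2
        for L in range(old, length + 1):
            if L <= params.synthesis_threshold:
                f[L] = 1
                continue
            r = params.tie_radius(L)
            c = center_of(L)
            lo, hi = max(1, c - r), min(L - 1, c + r)
            best = None
            for v in range(params.min_overlap, params.max_overlap + 1):
                hi_v = min(hi, L - 1 - v)
                if hi_v < lo:
                    continue
                ps = np.arange(lo, hi_v + 1)
                totals = f[ps + v] + f[L - ps]
                m = int(totals.min())
                if best is None or m < best:
                    best = m
            f[L] = best if best is not None else np.iinfo(np.int64).max // 4
        self._f = f
        return int(f[length])


_leaf_counters: dict[DivisionParams, _LeafCounter] = {}


def min_leaf_count(length: int, params: DivisionParams) -> int:
    """Fewest leaves any tree under ``params`` can reach for this length."""
    counter = _leaf_counters.get(params)
    if counter is None:
        counter = _leaf_counters[params] = _LeafCounter(params)
    return counter(length)


def _span_fits(span: tuple[int, int], lo: int, hi: int) -> bool:
    return lo <= span[0] and span[1] <= hi


def _noncutting(p: int, v: int, length: int, spans) -> bool:
    return all(
        _span_fits((a, b), 1, p + v) or _span_fits((a, b), p + 1, length)
        for a, b, _ in spans
    )


def choose_division(
    sequence: str,
    params: DivisionParams | None = None,
    anchored_spans: Sequence[tuple[int, int, str]] = (),
) -> Division:
    """Pick the best (split, overlap) pair for one oversized node.

    With anchored natural-fragment spans present, candidates are restricted
    to splits aligned with the longest span's edges so the fragment is
    peeled out whole; no division may cut through any span.
    """
    params = params or DivisionParams()
    L = len(sequence)
    if L <= params.synthesis_threshold:
        raise PlanningError(f"sequence of length {L} needs no division")
    center = L // 2
    leafcount = lambda p, v: (
        min_leaf_count(p + v, params) + min_leaf_count(L - p, params)
    )

    if anchored_spans:
        primary = max(anchored_spans, key=lambda s: (s[1] - s[0], -s[0]))
        a, b, _name = primary
        cands: list[tuple[int, int, int]] = []
        for v in range(params.min_overlap, params.max_overlap + 1):
            p = b - v  # left child ends exactly at the span's right edge
            if 1 <= p and p + v <= L - 1 and _noncutting(p, v, L, anchored_spans):
                cands.append((p, v, abs(p - center)))
            p = a - 1  # right child starts exactly at the span's left edge
            if 1 <= p and p + v <= L - 1 and _noncutting(p, v, L, anchored_spans):
                cands.append((p, v, abs(p - center)))
        if not cands:
            raise PlanningError(
                f"cannot divide {L} nt node without cutting natural fragment "
                f"'{_name}' at {a}-{b}"
            )
        best = None
        for p, v, off in cands:
            sc = division_score(
                sequence[p : p + v], sequence[:p], sequence[p + v :], params.match_score
            )
            key = (leafcount(p, v), sc, off, v, p)
            if best is None or key < best[0]:
                best = (key, p, v)
        return Division(best[1], best[2], best[0][1])

    table = (
        DivisionScoreTable(sequence, params.min_overlap, params.max_overlap, params.match_score)
        if L <= params.exhaustive_limit
        else None
    )
    best = None
    for p, v, off in _candidate_positions(L, params):
        lc = leafcount(p, v)
        if best is not None and lc > best[0][0]:
            continue
        if table is not None:
            sc = table.score(p, v)
        else:
            sc = division_score(
                sequence[p : p + v], sequence[:p], sequence[p + v :], params.match_score
            )
        key = (lc, sc, off, v, p)
        if best is None or key < best[0]:
            best = (key, p, v)
    if best is None:
        raise PlanningError(f"no feasible division for {L} nt node under {params}")
    return Division(best[1], best[2], best[0][1])


@dataclass
class AssemblyNode:
    id: str
    sequence: str
    kind: str  # 'leaf' | 'reaction' | 'natural_fragment'
    children: tuple[str, str] | tuple = ()
    division: Division | None = None
    forward_primer: "object | None" = None
    reverse_primer: "object | None" = None
    natural_name: str | None = None

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass
class AssemblyTree:
    root: str
    nodes: dict[str, AssemblyNode] = field(default_factory=dict)

    @property
    def leaf_count(self) -> int:
        return sum(1 for n in self.nodes.values() if n.kind != "reaction")

    @property
    def reaction_count(self) -> int:
        return sum(1 for n in self.nodes.values() if n.kind == "reaction")

    def node(self, node_id: str) -> AssemblyNode:
        return self.nodes[node_id]

    def leaves(self) -> list[AssemblyNode]:
        """Leaves in left-to-right order along the target."""
        out: list[AssemblyNode] = []

        def walk(nid: str) -> None:
            n = self.nodes[nid]
            if n.kind == "reaction":
                walk(n.children[0])
                walk(n.children[1])
            else:
                out.append(n)

        walk(self.root)
        return out

    def reactions(self) -> list[AssemblyNode]:
        return [n for n in self.nodes.values() if n.kind == "reaction"]

    def depth(self) -> int:
        def d(nid: str) -> int:
            n = self.nodes[nid]
            if n.kind != "reaction":
                return 0
            return 1 + max(d(c) for c in n.children)

        return d(self.root)

    def to_json(self) -> str:
        def node_dict(n: AssemblyNode) -> dict:
            d: dict = {
                "id": n.id,
                "kind": n.kind,
                "length": n.length,
                "sequence": n.sequence,
            }
            if n.children:
                d["children"] = list(n.children)
            if n.division:
                d["division"] = {
                    "split_index": n.division.split_index,
                    "overlap_len": n.division.overlap_len,
                    "score": n.division.score,
                }
            if n.natural_name:
                d["natural_name"] = n.natural_name
            for attr, key in (
                ("forward_primer", "forward_primer"),
                ("reverse_primer", "reverse_primer"),
            ):
                p = getattr(n, attr)
                if p is not None:
                    d[key] = {
                        "name": p.name,
                        "sequence": p.sequence,
                        "inherited": p.inherited,
                    }
            return d

        return json.dumps(
            {
                "root": self.root,
                "leaf_count": self.leaf_count,
                "reaction_count": self.reaction_count,
                "nodes": [node_dict(self.nodes[k]) for k in sorted(self.nodes)],
            },
            indent=2,
        )


def build_tree(
    target: str,
    params: DivisionParams | None = None,
    anchored_spans: Sequence[tuple[int, int, str]] = (),
    tree_id: str = "target",
) -> AssemblyTree:
    """Recursively divide ``target`` into an assembly tree.

    ``anchored_spans`` are 1-based inclusive (start, end, name) coordinates
    of natural fragments that must come out as whole leaves; they are
    exempt from the synthesis threshold.
    """
    params = params or DivisionParams()
    target = clean(target, context=tree_id)
    if not target:
        raise PlanningError("empty target")
    tree = AssemblyTree(root=f"{tree_id}/1")
    counter = [0]

    def build(seq: str, spans: Sequence[tuple[int, int, str]]) -> str:
        counter[0] += 1
        nid = f"{tree_id}/{counter[0]}"
        whole = next((s for s in spans if s[0] == 1 and s[1] == len(seq)), None)
        if whole is not None:
            tree.nodes[nid] = AssemblyNode(
                nid, seq, "natural_fragment", natural_name=whole[2]
            )
            return nid
        if len(seq) <= params.synthesis_threshold and not spans:
            tree.nodes[nid] = AssemblyNode(nid, seq, "leaf")
            return nid
        if len(seq) <= params.synthesis_threshold and spans:
            # A strictly interior span in an already-synthesizable node is
            # pointless to honor; synthesize the leaf directly.
            tree.nodes[nid] = AssemblyNode(nid, seq, "leaf")
            return nid
        try:
            div = choose_division(seq, params, spans)
        except PlanningError as exc:
            raise PlanningError(f"{tree_id}: {exc}") from exc
        p, v = div.split_index, div.overlap_len
        (l_lo, l_hi), (r_lo, r_hi) = div.child_spans(len(seq))
        left_seq = seq[l_lo - 1 : l_hi]
        right_seq = seq[r_lo - 1 : r_hi]
        left_spans, right_spans = [], []
        for a, b, name in spans:
            if _span_fits((a, b), l_lo, l_hi):
                left_spans.append((a, b, name))
            elif _span_fits((a, b), r_lo, r_hi):
                right_spans.append((a - p, b - p, name))
            else:  # choose_division guarantees non-cutting
                raise AssertionError(f"division cut through span {name}")
        node = AssemblyNode(nid, seq, "reaction", division=div)
        tree.nodes[nid] = node
        left_id = build(left_seq, left_spans)
        right_id = build(right_seq, right_spans)
        node.children = (left_id, right_id)
        return nid

    root_id = build(target, list(anchored_spans))
    tree.root = root_id
    return tree


def tree_to_dot(tree: AssemblyTree) -> str:
    """Render the construction tree as a Graphviz digraph.

    Reaction nodes are ellipses, synthetic oligo leaves boxes, natural
    fragments shaded boxes; labels carry the node id and length.
    """
    lines = ["digraph assembly {", '  node [fontname="Helvetica"];']
    for nid in sorted(tree.nodes):
        n = tree.nodes[nid]
        label = f"{nid}\\n{n.length} nt"
        if n.kind == "reaction":
            attrs = f'label="{label}" shape=ellipse'
        elif n.kind == "natural_fragment":
            attrs = f'label="{label}\\n{n.natural_name}" shape=box style=filled fillcolor=lightgrey'
        else:
            attrs = f'label="{label}" shape=box'
        lines.append(f'  "{nid}" [{attrs}];')
    for nid in sorted(tree.nodes):
        n = tree.nodes[nid]
        for child in n.children:
            lines.append(f'  "{nid}" -> "{child}";')
    lines.append("}")
    return "\n".join(lines)
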