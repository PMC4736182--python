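"""Sequence reuse across combinatorial libraries and natural fragments.

Variants of a combinatorial library share long identical blocks (a common
coding region behind variable promoters, a common backbone, ...). Any
block shared by two or more targets need only be synthesized once and
used as an intermediate in every member's assembly. Sharing here is
exact: a fragment can serve several assemblies unchanged only if it is a
perfect substring of each of them, so detection is maximal exact common
substrings rather than alignment.

Natural fragments -- DNA the user already has in the freezer -- are
anchored the same way: each must be an exact substring of a target, and
the division planner then peels it out as a whole leaf.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .hierplan import AssemblyTree, DivisionParams, build_tree
from .sequence import clean

__all__ = [
    "NaturalFragment",
    "SharedIntermediate",
    "ProtocolPlan",
    "find_shared_intermediates",
    "anchor_naturals",
    "plan_library",
]


@dataclass(frozen=True)
class NaturalFragment:
    name: str
    sequence: str

    def __post_init__(self) -> None:
        object.__setattr__(self, "sequence", clean(self.sequence, context=self.name))
        if not self.sequence:
            raise ValueError(f"natural fragment {self.name} is empty")


@dataclass
class SharedIntermediate:
    sequence: str
    members: dict[str, tuple[int, int]]  # target id -> 1-based inclusive anchor

    @property
    def length(self) -> int:
        return len(self.sequence)


def _overlaps(a: tuple[int, int], b: tuple[int, int]) -> bool:
    return not (a[1] < b[0] or b[1] < a[0])


def find_shared_intermediates(
    targets: list[tuple[str, str]], min_share: int
) -> list[SharedIntermediate]:
    """Maximal exact blocks of length >= ``min_share`` shared across targets.

    Search is widest-membership-first, then longest: a block reused by
    four variants saves three syntheses, so membership outranks a chance
    one-base extension that only a pair of targets happens to share.
    Claimed spans are masked per target, so reported blocks never overlap
    within a target; each block records one anchor per member (leftmost
    unmasked occurrence).
    """
    if len(targets) < 2:
        return []
    seqs = dict(targets)
    used: dict[str, list[tuple[int, int]]] = {tid: [] for tid, _ in targets}
    found: list[SharedIntermediate] = []

    def anchors_of(block: str) -> dict[str, tuple[int, int]]:
        """Leftmost unmasked occurrence of block per target."""
        hits: dict[str, tuple[int, int]] = {}
        for tid, seq in seqs.items():
            start = seq.find(block)
            while start != -1:
                span = (start + 1, start + len(block))
                if not any(_overlaps(span, u) for u in used[tid]):
                    hits[tid] = span
                    break
                start = seq.find(block, start + 1)
        return hits

    def best_block_of_len(k: int, min_members: int) -> str | None:
        """Lexicographically smallest length-k substring unmasked in >=
        ``min_members`` distinct targets, or None."""
        members: dict[str, set[str]] = {}
        for tid, seq in seqs.items():
            mask = used[tid]
            for start in range(len(seq) - k + 1):
                span = (start + 1, start + k)
                if any(_overlaps(span, u) for u in mask):
                    continue
                members.setdefault(seq[start : start + k], set()).add(tid)
        qualifying = [b for b, tids in members.items() if len(tids) >= min_members]
        return min(qualifying) if qualifying else None

    max_len = max(len(s) for s in seqs.values())
    for m in range(len(targets), 1, -1):
        while True:
            if best_block_of_len(min_share, m) is None:
                break
            lo, hi, best_len = min_share, max_len, min_share
            while lo <= hi:
                mid = (lo + hi) // 2
                if best_block_of_len(mid, m) is not None:
                    best_len = mid
                    lo = mid + 1
                else:
                    hi = mid - 1
            block = best_block_of_len(best_len, m)
            assert block is not None
            anchors = anchors_of(block)
            for tid, span in anchors.items():
                used[tid].append(span)
            found.append(SharedIntermediate(block, anchors))
    return found


def anchor_naturals(
    target: str, naturals: list[NaturalFragment]
) -> tuple[list[tuple[int, int, str]], list[str]]:
    """Exact-match anchors of each natural fragment in ``target``.

    Returns (anchored spans, rejected names). A fragment absent from the
    target is rejected (reported, not fatal). A fragment with several
    occurrences is anchored at the occurrence whose midpoint is nearest
    the target center, which is where the division search wants freedom
    least; anchors may not overlap an earlier (longer) fragment's span.
    """
    anchored: list[tuple[int, int, str]] = []
    rejected: list[str] = []
    center = (len(target) + 1) / 2
    for nat in sorted(naturals, key=lambda n: (-len(n.sequence), n.name)):
        spans: list[tuple[int, int]] = []
        start = target.find(nat.sequence)
        while start != -1:
            spans.append((start + 1, start + len(nat.sequence)))
            start = target.find(nat.sequence, start + 1)
        spans = [
            s for s in spans if not any(_overlaps(s, (a, b)) for a, b, _ in anchored)
        ]
        if not spans:
            rejected.append(nat.name)
            continue
        best = min(spans, key=lambda s: abs((s[0] + s[1]) / 2 - center))
        anchored.append((best[0], best[1], nat.name))
    return anchored, rejected


@dataclass
class ProtocolPlan:
    trees: dict[str, AssemblyTree] = field(default_factory=dict)
    shared: list[SharedIntermediate] = field(default_factory=list)
    rejected_naturals: dict[str, list[str]] = field(default_factory=dict)

    @property
    def total_reactions(self) -> int:
        """Unique synthesis reactions across the plan (shared products counted once)."""
        return len(
            {
                n.sequence
                for t in self.trees.values()
                for n in t.nodes.values()
                if n.kind == "reaction"
            }
        )

    @property
    def total_unique_leaves(self) -> int:
        return len(
            {
                n.sequence
                for t in self.trees.values()
                for n in t.nodes.values()
                if n.kind != "reaction"
            }
        )

    @property
    def independent_reactions(self) -> int:
        """Reaction count if every target were built in isolation."""
        return sum(t.reaction_count for t in self.trees.values())


def plan_library(
    targets: list[tuple[str, str]],
    params: DivisionParams | None = None,
    naturals: list[NaturalFragment] | None = None,
    min_share: int | None = None,
) -> ProtocolPlan:
    """Plan assembly trees for a whole target set with sharing.

    Shared blocks (and user naturals) are anchored as protected spans, so
    every member target's tree isolates the identical intermediate, which
    then appears once in the plan's unique-reaction accounting.
    """
    params = params or DivisionParams()
    naturals = naturals or []
    if min_share is None:
        min_share = 2 * params.min_overlap
    shared = find_shared_intermediates(targets, min_share) if len(targets) > 1 else []
    plan = ProtocolPlan(shared=shared)
    for tid, seq in targets:
        anchored, rejected = anchor_naturals(seq, naturals)
        if rejected:
            plan.rejected_naturals[tid] = rejected
        occupied = [(a, b) for a, b, _ in anchored]
        for si in shared:
            span = si.members.get(tid)
            # a shared block below the synthesis threshold is just a leaf;
            # protecting it would constrain divisions for no reuse benefit
            if span is None or si.length <= params.synthesis_threshold:
                continue
            if any(_overlaps(span, o) for o in occupied):
                continue
            anchored.append((span[0], span[1], f"shared:{span[0]}-{span[1]}"))
            occupied.append(span)
        tree = build_tree(seq, params, anchored_spans=anchored, tree_id=tid)
        # shared blocks are synthesizable intermediates, not stored naturals:
        # expand any oversized 'natural' marked shared into its own subtree
        _expand_shared(tree, params)
        plan.trees[tid] = tree
    return plan


def _expand_shared(tree: AssemblyTree, params: DivisionParams) -> None:
    """Replace shared-block pseudo-natural leaves by real subtrees."""
    for nid in list(tree.nodes):
        n = tree.nodes[nid]
        if (
            n.kind == "natural_fragment"
            and n.natural_name
            and n.natural_name.startswith("shared:")
            and n.length > params.synthesis_threshold
        ):
            sub = build_tree(n.sequence, params, tree_id=f"{nid}s")
            root = sub.nodes[sub.root]
            n.kind = root.kind
            n.division = root.division
            n.children = root.children
            n.natural_name = None
            for cid, cnode in sub.nodes.items():
                if cid != sub.root:
                    tree.nodes[cid] = cnode
        elif (
            n.kind == "natural_fragment"
            and n.natural_name
            and n.natural_name.startswith("shared:")
        ):
            n.kind = "leaf"
            n.natural_name = None
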