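"""In-silico assembly: overlap extension, Gibson circles, Golden Gate ligation.

Double-stranded fragments are represented by their sense strand. Two
fragments join when a terminal stretch of one exactly equals a terminal
stretch of the other (the shared overlap through which they prime each
other); the product is the merge over the longest such overlap. Junction
detection is exact-match only -- enzymatic infidelity is out of scope --
and ambiguity (two equally long maximal junctions) is an error rather
than an arbitrary choice, because a well-planned protocol never produces
one and silent disambiguation would hide planner bugs.

Circular products (Gibson, Golden Gate) compare equal under rotation and
strand flip; they are canonicalized to the lexicographically minimal
rotation over both strands.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .hierplan import AssemblyTree
from .sequence import clean, reverse_complement

__all__ = [
    "Fragment",
    "StickyFragment",
    "CircularProduct",
    "AssemblyError",
    "overlap_extend",
    "simulate_ihdc_step",
    "simulate_tree",
    "gibson_circularize",
    "goldengate_ligate",
    "enumerate_goldengate_library",
]


class AssemblyError(RuntimeError):
    """A junction could not be formed, or was ambiguous."""


@dataclass(frozen=True)
class Fragment:
    id: str
    sequence: str
    provenance: str = "leaf"  # 'leaf' | 'product' | 'natural_fragment'

    def __post_init__(self) -> None:
        object.__setattr__(self, "sequence", clean(self.sequence, context=self.id))

    def __len__(self) -> int:
        return len(self.sequence)


def _terminal_overlaps(a: str, b: str, min_overlap: int) -> list[int]:
    """All lengths v >= min_overlap with suffix(a, v) == prefix(b, v), longest first."""
    out = []
    for v in range(min(len(a), len(b)), min_overlap - 1, -1):
        if a[-v:] == b[:v]:
            out.append(v)
    return out


def overlap_extend(a: Fragment, b: Fragment, min_overlap: int = 15) -> Fragment:
    """Merge two fragments over their longest terminal overlap.

    ``b`` may anneal in either orientation; the sense-strand suffix of
    ``a`` must equal the (possibly reverse-complemented) prefix of ``b``.
    Product length is len(a) + len(b) - overlap.
    """
    candidates: list[tuple[int, str]] = []
    for oriented, tag in ((b.sequence, "+"), (reverse_complement(b.sequence), "-")):
        ovs = _terminal_overlaps(a.sequence, oriented, min_overlap)
        if ovs:
            candidates.append((ovs[0], oriented))
    if not candidates:
        raise AssemblyError(
            f"no junction of >= {min_overlap} nt between {a.id} and {b.id}"
        )
    best = max(v for v, _ in candidates)
    winners = {seq for v, seq in candidates if v == best}
    if len(winners) > 1:
        raise AssemblyError(f"ambiguous junction between {a.id} and {b.id}")
    (oriented,) = winners
    merged = a.sequence + oriented[best:]
    return Fragment(f"{a.id}+{b.id}", merged, provenance="product")


def simulate_ihdc_step(
    a: Fragment,
    b: Fragment,
    forward_primer_seq: str,
    reverse_primer_seq: str,
    min_overlap: int = 15,
) -> Fragment:
    """One isothermal elongation step: merge, then validate amplification primers.

    The forward primer must be a literal prefix of the merged product and
    the reverse primer the reverse complement of a literal suffix;
    amplification itself is modeled as identity on sequence.
    """
    product = overlap_extend(a, b, min_overlap)
    if not product.sequence.startswith(forward_primer_seq):
        raise AssemblyError(
            f"forward primer does not prime product {product.id}"
        )
    if not product.sequence.endswith(reverse_complement(reverse_primer_seq)):
        raise AssemblyError(
            f"reverse primer does not prime product {product.id}"
        )
    return product


def simulate_tree(tree: AssemblyTree, min_overlap: int | None = None) -> Fragment:
    """Fold a construction tree bottom-up with overlap extension.

    Reproducing the root sequence byte-for-byte from the leaves is the
    planner's central correctness property.
    """

    def fold(nid: str) -> Fragment:
        n = tree.nodes[nid]
        if n.kind != "reaction":
            return Fragment(nid, n.sequence, provenance=n.kind)
        left = fold(n.children[0])
        right = fold(n.children[1])
        v = n.division.overlap_len if n.division else 15
        mo = min_overlap if min_overlap is not None else v
        if n.forward_primer is not None and n.reverse_primer is not None:
            return simulate_ihdc_step(
                left, right, n.forward_primer.sequence, n.reverse_primer.sequence, mo
            )
        return overlap_extend(left, right, mo)

    return fold(tree.root)


def _rotations_min(seq: str) -> str:
    doubled = seq + seq
    return min(doubled[i : i + len(seq)] for i in range(len(seq)))


def canonical_rotation(seq: str) -> str:
    """Lexicographically minimal rotation over both strands."""
    return min(_rotations_min(seq), _rotations_min(reverse_complement(seq)))


@dataclass(frozen=True)
class CircularProduct:
    sequence: str  # canonical rotation
    junctions: tuple[tuple[str, str, int], ...] = ()  # (upstream id, downstream id, homology)

    def __post_init__(self) -> None:
        object.__setattr__(self, "sequence", canonical_rotation(self.sequence))

    def __len__(self) -> int:
        return len(self.sequence)

    def __eq__(self, other) -> bool:
        return isinstance(other, CircularProduct) and self.sequence == other.sequence

    def __hash__(self) -> int:
        return hash(self.sequence)


def gibson_circularize(
    fragments: list[Fragment], min_homology: int = 15
) -> CircularProduct:
    """Assemble fragments into the unique circle their terminal homologies dictate.

    Every fragment must be used exactly once; fragments may enter in
    either orientation. A single fragment with identical termini
    self-circularizes. Ambiguity (two distinct circles) and incomplete
    chains are errors.
    """
    if not fragments:
        raise AssemblyError("no fragments to circularize")
    if len(fragments) == 1:
        f = fragments[0]
        ovs = _terminal_overlaps(f.sequence, f.sequence, min_homology)
        real = [v for v in ovs if v < len(f.sequence)]
        if not real:
            raise AssemblyError(f"{f.id}: no terminal homology for self-circularization")
        v = real[0]
        return CircularProduct(f.sequence[v:], ((f.id, f.id, v),))

    # oriented copies: (fragment index, orientation) -> sense sequence
    n = len(fragments)
    oriented = {}
    for i, f in enumerate(fragments):
        oriented[(i, "+")] = f.sequence
        oriented[(i, "-")] = reverse_complement(f.sequence)

    def junction(x: str, y: str) -> int | None:
        ovs = _terminal_overlaps(x, y, min_homology)
        return ovs[0] if ovs else None

    circles: list[list[tuple[int, str]]] = []

    def search(path: list[tuple[int, str]], usedmask: int) -> None:
        if len(path) == n:
            if junction(oriented[path[-1]], oriented[path[0]]) is not None:
                circles.append(path)
            return
        last_seq = oriented[path[-1]]
        for key, seq in oriented.items():
            if usedmask & (1 << key[0]):
                continue
            if junction(last_seq, seq) is not None:
                search(path + [key], usedmask | (1 << key[0]))

    # anchor fragment 0 in + orientation: rotation/flip symmetry removal
    # (a circle needing 0 in '-' is recovered as the flipped traversal)
    search([(0, "+")], 1)

    def circle_seq(path: list[tuple[int, str]]) -> tuple[str, tuple]:
        seqs = [oriented[key] for key in path]
        homs = [junction(seqs[k], seqs[(k + 1) % n]) for k in range(n)]
        out = "".join(s[: len(s) - homs[k]] for k, s in enumerate(seqs))
        juncs = tuple(
            (fragments[path[k][0]].id, fragments[path[(k + 1) % n][0]].id, homs[k])
            for k in range(n)
        )
        return out, juncs

    products = {}
    for path in circles:
        seq, juncs = circle_seq(path)
        products[canonical_rotation(seq)] = (seq, juncs)
    if not products:
        raise AssemblyError(
            "no circularization: fragments do not chain into a single circle"
        )
    if len(products) > 1:
        raise AssemblyError(f"ambiguous assembly: {len(products)} distinct circles")
    seq, juncs = next(iter(products.values()))
    return CircularProduct(seq, juncs)


@dataclass(frozen=True)
class StickyFragment:
    """A Type-IIS digested fragment: 4-nt single-stranded ends flank a core.

    Overhangs are written as the 4-nt top-strand junction sequence; two
    ends ligate when their junction strings are identical (the two
    single strands are then exact Watson-Crick partners).
    """

    name: str
    core: str
    left_overhang: str
    right_overhang: str

    def __post_init__(self) -> None:
        for ov in (self.left_overhang, self.right_overhang):
            if len(ov) != 4:
                raise ValueError(f"{self.name}: overhangs must be exactly 4 nt")
        object.__setattr__(self, "core", clean(self.core, context=self.name))
        object.__setattr__(self, "left_overhang", clean(self.left_overhang, context=self.name))
        object.__setattr__(self, "right_overhang", clean(self.right_overhang, context=self.name))

    @property
    def top_strand(self) -> str:
        return self.left_overhang + self.core + self.right_overhang


def goldengate_ligate(
    promoter: StickyFragment, bcd: StickyFragment, backbone: StickyFragment
) -> CircularProduct:
    """Ligate three sticky-ended fragments into a circle.

    The overhang set must dictate exactly one cyclic arrangement
    (promoter - bcd - backbone in the intended design); incompatible or
    ambiguous overhangs are errors.
    """
    frags = [promoter, bcd, backbone]
    orders: list[list[StickyFragment]] = []
    import itertools

    for perm in itertools.permutations(frags[1:]):
        order = [frags[0], *perm]
        if all(
            order[k].right_overhang == order[(k + 1) % 3].left_overhang
            for k in range(3)
        ):
            orders.append(order)
    if not orders:
        raise AssemblyError(
            "incompatible overhangs: no cyclic arrangement ligates "
            f"({promoter.name}, {bcd.name}, {backbone.name})"
        )
    seqs = {
        canonical_rotation(
            "".join(f.left_overhang + f.core for f in order)
        ): order
        for order in orders
    }
    if len(seqs) > 1:
        raise AssemblyError("ambiguous overhang set: multiple distinct circles")
    seq, order = next(iter(seqs.items()))
    juncs = tuple(
        (order[k].name, order[(k + 1) % 3].name, 4) for k in range(3)
    )
    return CircularProduct(seq, juncs)


def enumerate_goldengate_library(
    promoters: list[StickyFragment],
    bcds: list[StickyFragment],
    backbone: StickyFragment,
) -> dict[tuple[str, str], CircularProduct]:
    """All promoter x BCD circular products over a shared backbone."""
    out: dict[tuple[str, str], CircularProduct] = {}
    for prom in promoters:
        for bcd in bcds:
            out[(prom.name, bcd.name)] = goldengate_ligate(prom, bcd, backbone)
    return out
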