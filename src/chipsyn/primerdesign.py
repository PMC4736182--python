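"""Amplification primer selection and inheritance for assembly trees.

Every synthesis reaction is amplified by one forward and one reverse
primer. A forward primer is a literal prefix of the reaction product; a
reverse primer is the reverse complement of a literal suffix. Candidates
are screened by 3' terminal specificity (a polymerase extends only a
perfectly annealed 3' end, so a candidate whose terminal k-mer recurs
anywhere else on either strand of the template is discarded) and ranked
by their ungapped off-target similarity to the template, intended site
excluded.

Children share their outer end with the parent product, so the child on
the left end of a parent inherits the parent's forward primer and the
right child its reverse primer; only the junction-facing primer of each
child must be picked fresh. Primer names follow the
``<target>_Prm_<n>_<F|R>`` convention, numbered by the leaf index at the
corresponding end of the reaction's span.
"""

from __future__ import annotations

from dataclasses import dataclass

from .hierplan import AssemblyNode, AssemblyTree, PlanningError
from .sequence import reverse_complement
from .similarity import offtarget_score

__all__ = [
    "PrimerParams",
    "Primer",
    "screen_three_prime",
    "pick_primer",
    "pick_primers",
    "inherit_primers",
    "primer_table",
]


@dataclass(frozen=True)
class PrimerParams:
    min_len: int = 18
    max_len: int = 45
    three_prime_k: int = 8
    max_offtarget_score: float | None = None

    def __post_init__(self) -> None:
        if not (self.min_len >= self.three_prime_k >= 1):
            raise ValueError("need min_len >= three_prime_k >= 1")
        if self.max_len < self.min_len:
            raise ValueError("need max_len >= min_len")


@dataclass(frozen=True)
class Primer:
    name: str
    sequence: str
    orientation: str  # 'forward' | 'reverse'
    node_id: str
    inherited: bool = False

    def __len__(self) -> int:
        return len(self.sequence)


def _kmer_sites(kmer: str, template: str) -> set[tuple[int, int]]:
    """1-based inclusive sense intervals where ``kmer`` occurs, either strand."""
    sites: set[tuple[int, int]] = set()
    k = len(kmer)
    start = template.find(kmer)
    while start != -1:
        sites.add((start + 1, start + k))
        start = template.find(kmer, start + 1)
    rc = reverse_complement(template)
    L = len(template)
    start = rc.find(kmer)
    while start != -1:
        # position j on the reverse strand maps to sense interval [L-j-k+1, L-j]
        sites.add((L - start - k + 1, L - start))
        start = rc.find(kmer, start + 1)
    return sites


def screen_three_prime(
    candidate_seq: str,
    orientation: str,
    template: str,
    params: PrimerParams,
) -> bool:
    """True iff the candidate's 3' terminal k-mer is unique to its site.

    The intended site of a forward primer is the template prefix; of a
    reverse primer, the template suffix (where its reverse complement
    lies). Any other exact occurrence of the terminal k-mer, on either
    strand, is a competing extension site and discards the candidate.
    """
    k = params.three_prime_k
    kmer = candidate_seq[-k:]
    n = len(candidate_seq)
    if orientation == "forward":
        intended = (n - k + 1, n)
    else:
        # reverse primer's 3' end anneals at sense position len(T)-n+1..len(T)-n+k
        intended = (len(template) - n + 1, len(template) - n + k)
    sites = _kmer_sites(kmer, template)
    return sites <= {intended}


def pick_primer(
    template: str,
    orientation: str,
    params: PrimerParams,
    *,
    node_id: str = "node",
    name: str = "primer",
) -> Primer:
    """Choose one primer of the given orientation for ``template``.

    Iterates candidate lengths from shortest to longest; candidates
    failing the 3' screen (or exceeding ``max_offtarget_score``, when set)
    are discarded; the survivor with the lowest off-target similarity
    wins, ties going to the shorter primer.
    """
    # Work on the strand where the candidate is a literal prefix.
    strand = template if orientation == "forward" else reverse_complement(template)
    best: tuple[float, Primer] | None = None
    for n in range(params.min_len, min(params.max_len, len(template)) + 1):
        cand = strand[:n]
        if not screen_three_prime(cand, "forward", strand, params):
            continue
        score = offtarget_score(cand, strand, exclude_sense_offset=0)
        if params.max_offtarget_score is not None and score > params.max_offtarget_score:
            continue
        if best is None or score < best[0]:
            best = (score, Primer(name, cand, orientation, node_id))
    if best is None:
        raise PlanningError(
            f"all {orientation} primer candidates discarded for node {node_id}"
        )
    return best[1]


def pick_primers(
    node: AssemblyNode, params: PrimerParams | None = None
) -> tuple[Primer, Primer]:
    """Fresh forward and reverse primers for a reaction node."""
    params = params or PrimerParams()
    fwd = pick_primer(
        node.sequence, "forward", params, node_id=node.id, name=f"{node.id}_F"
    )
    rev = pick_primer(
        node.sequence, "reverse", params, node_id=node.id, name=f"{node.id}_R"
    )
    return fwd, rev


def _leaf_span_index(tree: AssemblyTree) -> dict[str, tuple[int, int]]:
    """Map node id -> (first leaf number, last leaf number), 1-based."""
    spans: dict[str, tuple[int, int]] = {}
    counter = [0]

    def walk(nid: str) -> tuple[int, int]:
        n = tree.nodes[nid]
        if n.kind != "reaction":
            counter[0] += 1
            spans[nid] = (counter[0], counter[0])
            return spans[nid]
        a = walk(n.children[0])
        b = walk(n.children[1])
        spans[nid] = (a[0], b[1])
        return spans[nid]

    walk(tree.root)
    return spans


def inherit_primers(
    tree: AssemblyTree,
    params: PrimerParams | None = None,
    name_prefix: str = "target",
) -> AssemblyTree:
    """Assign primers to every reaction node, reusing outer primers downward.

    The root reaction gets two fresh primers. Walking toward the leaves,
    each left child reaction inherits its parent's forward primer (they
    share a left end) and picks a fresh reverse primer; symmetrically for
    right children. Inherited primers are flagged. Single-leaf trees get
    no primers.
    """
    params = params or PrimerParams()
    if tree.nodes[tree.root].kind != "reaction":
        return tree
    spans = _leaf_span_index(tree)

    def name(nid: str, orientation: str) -> str:
        lo, hi = spans[nid]
        n = lo if orientation == "forward" else hi
        suffix = "F" if orientation == "forward" else "R"
        return f"{name_prefix}_Prm_{n}_{suffix}"

    def assign(nid: str, fwd: Primer | None, rev: Primer | None) -> None:
        node = tree.nodes[nid]
        if node.kind != "reaction":
            return
        if fwd is None:
            fwd = pick_primer(
                node.sequence, "forward", params, node_id=nid, name=name(nid, "forward")
            )
        else:
            if not node.sequence.startswith(fwd.sequence):
                raise AssertionError(
                    f"inherited forward primer {fwd.name} is not a prefix of {nid}"
                )
            fwd = Primer(fwd.name, fwd.sequence, "forward", nid, inherited=True)
        if rev is None:
            rev = pick_primer(
                node.sequence, "reverse", params, node_id=nid, name=name(nid, "reverse")
            )
        else:
            if not node.sequence.endswith(reverse_complement(rev.sequence)):
                raise AssertionError(
                    f"inherited reverse primer {rev.name} does not close {nid}"
                )
            rev = Primer(rev.name, rev.sequence, "reverse", nid, inherited=True)
        node.forward_primer = fwd
        node.reverse_primer = rev
        assign(node.children[0], fwd, None)
        assign(node.children[1], None, rev)

    assign(tree.root, None, None)
    return tree


def primer_table(tree: AssemblyTree) -> list[dict]:
    """Flat records (name, node, orientation, length, inherited) for CSV export."""
    rows = []
    for nid in sorted(tree.nodes):
        n = tree.nodes[nid]
        for p in (n.forward_primer, n.reverse_primer):
            if p is not None:
                rows.append(
                    {
                        "name": p.name,
                        "node": nid,
                        "orientation": p.orientation,
                        "length": len(p),
                        "inherited": p.inherited,
                        "sequence": p.sequence,
                    }
                )
    return rows
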