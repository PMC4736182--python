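"""Canonical DNA sequence handling.

Sequences are plain Python strings over the unambiguous alphabet {A,C,G,T},
uppercase. All user-facing coordinates are 1-based and inclusive at both
ends, matching how molecular biologists index oligos.
"""

from __future__ import annotations

from typing import Iterable

ALPHABET = frozenset("ACGT")

_COMPLEMENT = str.maketrans("ACGT", "TGCA")


class SequenceError(ValueError):
    """Raised for malformed nucleotide strings or out-of-range coordinates."""


def clean(raw: str, *, context: str = "sequence") -> str:
    """Uppercase ``raw`` and validate it against the unambiguous DNA alphabet.

    IUPAC ambiguity codes are rejected: the division and primer algorithms
    score exact base identity and have no meaningful semantics for N/R/Y/...
    """
    seq = raw.strip().upper()
    bad = set(seq) - ALPHABET
    if bad:
        raise SequenceError(
            f"{context}: non-ACGT characters {sorted(bad)!r} in sequence"
        )
    return seq


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)


def subsequence(seq: str, start: int, end: int, *, context: str = "slice") -> str:
    """1-based inclusive subsequence ``seq[start..end]``."""
    if not (1 <= start <= end <= len(seq)):
        raise SequenceError(
            f"{context}: indices {start}-{end} out of range for length {len(seq)}"
        )
    return seq[start - 1 : end]


def splice(seq: str, start: int, end: int, replacement: str) -> str:
    """Replace the 1-based inclusive span ``start..end`` with ``replacement``.

    The replacement may differ in length from the excised span; downstream
    coordinates refer to the new sequence.
    """
    if not (1 <= start <= end <= len(seq)):
        raise SequenceError(
            f"mutation: indices {start}-{end} out of range for length {len(seq)}"
        )
    out = seq[: start - 1] + replacement + seq[end:]
    if not out:
        raise SequenceError("mutation produced an empty part")
    return out


def write_fasta(path, records: Iterable[tuple[str, str]]) -> None:
    """Write ``(id, sequence)`` pairs as FASTA via Biopython."""
    from Bio import SeqIO
    from Bio.Seq import Seq
    from Bio.SeqRecord import SeqRecord

    recs = [SeqRecord(Seq(s), id=name, description="") for name, s in records]
    SeqIO.write(recs, str(path), "fasta")


def read_fasta(path) -> list[tuple[str, str]]:
    """Read FASTA into ``(id, cleaned sequence)`` pairs via Biopython."""
    from Bio import SeqIO

    return [
        (rec.id, clean(str(rec.seq), context=rec.id))
        for rec in SeqIO.parse(str(path), "fasta")
    ]
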