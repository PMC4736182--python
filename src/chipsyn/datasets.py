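"""Bundled demonstration data for the platform's reference builds and assays.

These are the oligo and primer sets of the demonstration gfp (754 bp) and
rfp constructs, and the well-intensity / calibration tables from the
platform's phenotype-screening and isopentenol (MBTH) assay runs. They
serve as worked examples and test inputs; all are small enough to live as
source constants.

Oligos alternate strands: odd-numbered entries are written as the sense
(top) strand, even-numbered entries as the reverse (bottom) strand, which
is how overlap-extension oligos are ordered on the bench. ``as_fragments``
reorients everything to sense-strand representation.
"""

from __future__ import annotations

from .asmsim import Fragment
from .sequence import reverse_complement

__all__ = [
    "GFP_OLIGOS",
    "GFP_PRIMERS",
    "RFP_OLIGOS",
    "RFP_PRIMERS",
    "INDUCED_BRIGHTNESS",
    "UNINDUCED_BRIGHTNESS",
    "ONCHIP_CALIBRATION",
    "OFFCHIP_CALIBRATION",
    "ONCHIP_ASSAY",
    "OFFCHIP_ASSAY",
    "ONCHIP_CURVE",
    "OFFCHIP_CURVE",
    "ONCHIP_BRIGHTNESS_FACTOR",
    "as_fragments",
    "gfp_target",
]

GFP_OLIGOS: dict[str, str] = {
    "gfp_Olig_1": "TTAAGAAGGAGATATAGATATGAGCAAAGGAGAAGAACTTTTCACTGGAGTTGTCCCAATTCTTGTTGAATTAGATGGTGATGTTAATGGGCACAAATTTTCTGTCCGTGGAGAGGGTGAAGGTGATGC",
    "gfp_Olig_2": "CATAGGTCAGAGTAGTGACAAGTGTTGGCCACGGAACAGGTAGTTTTCCAGTAGTGCAAATAAATTTAAGGGTGAGTTTTCCGTTTGTAGCATCACCTTCACCCTCTCCACGGACAGAAAATTTGTGCC",
    "gfp_Olig_3": "CCTGTTCCGTGGCCAACACTTGTCACTACTCTGACCTATGGTGTTCAATGCTTTTCCCGTTATCCGGATCACATGAAACGGCATGACTTTTTCAAGAGTGCCATGCCCGAAGGTTATGTACAGGAACGC",
    "gfp_Olig_4": "CTTTAACTCGATACGATTAACAAGGGTATCACCTTCAAACTTGACTTCAGCACGCGTCTTGTAGGTCCCGTCATCTTTGAAAGATATAGTGCGTTCCTGTACATAACCTTCGGGCATGGCACTCTTGAAA",
    "gfp_Olig_5": "GTTTGAAGGTGATACCCTTGTTAATCGTATCGAGTTAAAGGGTATTGATTTTAAAGAAGATGGAAACATTCTTGGACACAAACTCGAGTACAACTTTAACTCACACAATGTATACATCACGGCAGACAA",
    "gfp_Olig_6": "TATTTTGTTGATAATGGTCTGCTAGTTGAACGGAACCATCTTCAACGTTGTGGCGAATTTTGAAGTTAGCTTTGATTCCATTCTTTTGTTTGTCTGCCGTGATGTATACATTGTGTGAGTTAAAGTTGT",
    "gfp_Olig_7": "GATGGTTCCGTTCAACTAGCAGACCATTATCAACAAAATACTCCAATTGGCGATGGCCCTGTCCTTTTACCAGACAACCATTACCTGTCGACACAATCTGTCCTTTCGAAAGATCCCAACGAAAAGCGT",
    "gfp_Olig_8": "CCCGGGCAGGAATTCGATTTATTTGTAGAGCTCATCCATGCCATGTGTAATCCCAGCAGCAGTTACAAACTCAAGAAGGACCATGTGGTCACGCTTTTCGTTGGGATCTTTCGAAAGGACAGATTGTGTC",
}

GFP_PRIMERS: dict[str, str] = {
    "gfp_Prm_1_F": "TTAAGAAGGAGATATAGATATGAGCAAAGGAGAAGAAC",
    "gfp_Prm_2_R": "CATAGGTCAGAGTAGTGACAAGTGTTGGCCACGGAACAGGTAGT",
    "gfp_Prm_3_F": "CCTGTTCCGTGGCCAACACTTGTCACTACTCTGACCTA",
    "gfp_Prm_4_R": "CTTTAACTCGATACGATTAACAAGGGTATCACCTTCAAAC",
    "gfp_Prm_5_F": "GTTTGAAGGTGATACCCTTGTTAATCGTATCGAGTTAA",
    "gfp_Prm_6_R": "TATTTTGTTGATAATGGTCTGCTAGTTGAACGGAACCA",
    "gfp_Prm_7_F": "GATGGTTCCGTTCAACTAGCAGACCATTATCAACAAAATACTCCA",
    "gfp_Prm_8_R": "CCCGGGCAGGAATTCGATTTATTTGTAGAGCTCATCCAT",
}

RFP_OLIGOS: dict[str, str] = {
    "rfp_Olig_1": "ATGGCGAGTAGCGAAGACGTTATCAAAGAGTTCATGCGTTTCAAAGTTCGTATGGAAGGTTCCGTTAACGGTCACGAGTTCGAAATCGAAGGTGAAGGTGAAGGTCGTCCGTACGAAGGTACCCAGACCGCTAAACTGAAAGTTACCAAAGGTGGTCCGCTGCCGTTCGCTTGGGACATCCTGTCCCCGCAGTTCCAGT",
    "rfp_Olig_2": "TAGATGAACTCACCGTCTTGCAGGGAGGAGTCCTGGGTAACGGTAACAACACCACCGTCTTCGAAGTTCATAACACGTTCCCATTTGAAACCTTCCGGGAAGGACAGTTTCAGGTAGTCCGGGATGTCAGCCGGGTGTTTAACGTAAGCTTTGGAACCGTACTGGAACTGCGGGGACAGGATGTCCCAAGCGAACGGCAG",
    "rfp_Olig_3": "TTACCCAGGACTCCTCCCTGCAAGACGGTGAGTTCATCTACAAAGTTAAACTGCGTGGTACCAACTTCCCGTCCGACGGTCCGGTTATGCAGAAAAAAACCATGGGTTGGGAAGCTTCCACCGAACGTATGTACCCGGAAGACGGTGCTCTGAAAGGTGAAATCAAAATGCGTCTGAAACTGAAAGACGGTGGTCACTA",
    "rfp_Olig_4": "TTAAGCACCGGTGGAGTGACGACCTTCAGCACGTTCGTACTGTTCAACGATGGTGTAGTCTTCGTTGTGGGAGGTGATGTCCAGTTTGATGTCGGTTTTGTAAGCACCCGGCAGCTGAACCGGTTTTTTAGCCATGTAGGTGGTTTTAACTTCAGCGTCGTAGTGACCACCGTCTTTCAGTTTCAGACGCATTTTGATTT",
}

RFP_PRIMERS: dict[str, str] = {
    "rfp_Prm_1_F_int": "TTAAGAAGGAGATATAGATATGGCGAGTAGCGAAGACGTTATCAAAGAGTTCATGCG",
    "rfp_Prm_2_R": "TAGATGAACTCACCGTCTTGCAGGGAGGAGTCCTGGGTAACG",
    "rfp_Prm_3_F": "TTACCCAGGACTCCTCCCTGCAAGACGGTGAGTTCATC",
    "rfp_Prm_4_R_int": "CCCGGGCAGGAATTCGATTTAAGCACCGGTGGAGTGACGACCTTCAGCACGTTCGT",
}

# Phenotype screening: per-well green-channel brightness, induced vs not.
INDUCED_BRIGHTNESS: dict[int, float] = {
    1: 0.3527, 3: 0.3623, 5: 0.3003, 7: 0.3047, 9: 0.3138, 11: 0.3220,
}
UNINDUCED_BRIGHTNESS: dict[int, float] = {
    2: 0.0298, 4: 0.0433, 6: 0.0273, 8: 0.0421, 10: 0.0394, 12: 0.0445,
}

# MBTH isopentenol assay calibration series (standards 3.9 - 125 mg/L by
# two-fold dilution): (measurement, mg/L). The measurement is the raw well
# intensity on-chip (the curve's predictor is 1 - intensity) and the OD620
# absorbance off-chip (used as-is).
ONCHIP_CALIBRATION: list[tuple[float, float]] = [
    (0.0682, 3.91),
    (0.0287, 7.81),
    (0.0162, 15.6),
    (0.0086, 31.0),
    (0.0043, 63.0),
    (0.0035, 130.0),
]
OFFCHIP_CALIBRATION: list[tuple[float, float]] = [
    (0.052, 3.9),
    (0.101, 7.81),
    (0.188, 15.6),
    (0.296, 31.3),
    (0.412, 62.5),
    (0.487, 125.0),
]

# Assay results: IPTG (uM) -> (measurement, reported isopentenol mg/L)
ONCHIP_ASSAY: dict[float, tuple[float, float]] = {
    0.01: (0.2028, 0.0178),
    0.05: (0.1011, 1.911),
    0.1: (0.0575, 14.2),
    0.2: (0.0437, 26.8),
    0.5: (0.0155, 97.8),
    1.0: (0.0077, 140.0),
}
OFFCHIP_ASSAY: dict[float, tuple[float, float]] = {
    0.01: (0.014, 3.6),
    0.05: (0.079, 5.9),
    0.1: (0.127, 8.45),
    0.2: (0.179, 12.5),
    0.5: (0.456, 98.1),
    1.0: (0.506, 142.0),
}

# Published curve coefficients: conc = a * exp(b * predictor)
ONCHIP_CURVE = ("onchip", 6e-19, 45.972)
OFFCHIP_CURVE = ("offchip", 3.2809, 7.4512)
ONCHIP_BRIGHTNESS_FACTOR = 3.6


def as_fragments(oligos: dict[str, str]) -> list[Fragment]:
    """Sense-strand fragments in bench order (even entries reverse-complemented)."""
    out = []
    for i, (name, seq) in enumerate(sorted(oligos.items()), start=1):
        sense = seq if i % 2 == 1 else reverse_complement(seq)
        out.append(Fragment(name, sense))
    return out


def gfp_target() -> str:
    """The 754 bp demonstration construct, reassembled from its oligo set."""
    from .asmsim import overlap_extend

    frags = as_fragments(GFP_OLIGOS)
    acc = frags[0]
    for f in frags[1:]:
        acc = overlap_extend(acc, f, 15)
    return acc.sequence
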