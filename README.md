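# chipsyn

Design, verify, and compile DNA construction for a programmable
microfluidic synthetic-biology platform.

`chipsyn` is aimed at synthetic biologists automating gene synthesis and
assembly on 2D microvalve-array devices. It covers the computational
side of the workflow end to end:

- **Design.** A small scripting language declares named DNA parts
  (literals, concatenation, 1-based inclusive slices, in-place
  mutation) and a `targets` list, which is how combinatorial libraries
  such as a 4-promoter × 4-BCD-GFP set (16 variants) are written down.
- **Hierarchical planning.** Each target longer than the synthesis
  threshold is recursively divided into two children that share a
  junction overlap, until every leaf is a synthesizable oligo. For a
  split at position *p* with overlap length *v*, the children are
  S[1..p+v] and S[p+1..L], so |left| + |right| = L + v. Candidate
  junctions are ranked by (subtree leaf count, mispriming score,
  center distance, v, p), where the mispriming score of an overlap O
  against a flank F is

      score(O, F) = max over ungapped alignments, both strands,
                    of the number of positional base matches,

  i.e. the best competing annealing site the junction could find.
  Amplification primers are chosen per reaction (forward = product
  prefix, reverse = reverse complement of the suffix), screened by 3′
  terminal k-mer uniqueness on both strands, and inherited from parent
  to the child that shares the corresponding end.
- **Reuse.** Exact blocks shared across library variants, and natural
  fragments the user already has in storage, are anchored and peeled
  out as whole intermediates synthesized once.
- **Verification.** An in-silico assembler folds each tree bottom-up by
  overlap extension (the isothermal reaction takes two overlapping
  dsDNA fragments and produces the elongated product) and checks the
  root byte-for-byte; it also models Gibson circularization via
  terminal homologies and Golden-Gate ligation of 4-nt sticky ends.
- **Compilation.** The chip is an undirected graph of wells and valves;
  transfers (Source, Destination, Amount, Method) are routed by
  minimum-hop BFS and quantized into 150 nL peristaltic cycles
  (`cycles = ceil(amount/150 nL)`; delivery never undershoots), emitted
  as a deterministic valve open/close schedule with per-reagent dwell
  times, plus cross-contamination reporting and automatic buffer
  washes.
- **Quantification.** Well intensities are means of the green channel
  over fixed 21×21 pixel windows; induction is the ratio of group means
  in linear space; colorimetric assays use exponential calibration
  curves `conc = a·e^{b·x}` fit by least squares of ln(conc) on the
  predictor (x = 1 − intensity on-chip, x = OD620 off-chip).

## Worked example

Plan and verify the bundled 754 bp gfp demonstration construct:

```sh
$ python -c "from chipsyn import datasets; from pathlib import Path; \
    Path('gfp.dna').write_text(f'gfp = \"{datasets.gfp_target()}\"\ntargets = gfp\n')"
$ chipsyn plan gfp.dna --out plan
{
  "targets": 1,
  "total_reactions": 7,
  "independent_reactions": 7,
  "total_unique_leaves": 8,
  "shared_intermediates": 0,
  "rejected_naturals": {}
}
$ chipsyn simulate plan
{
  "gfp": {
    "status": "match",
    "length": 754
  }
}
```

At the default 130 nt synthesis threshold with 20–45 nt overlaps the
754 nt target decomposes into 8 oligos joined by 7 synthesis reactions
over 3 levels (quarters, halves, full length), and refolding the tree by
overlap extension reproduces the target exactly (`match`). The plan
directory also holds the tree JSON, a Graphviz DOT forest, the leaf
oligos as FASTA, and the primer table (8 distinct primers named
`gfp_Prm_1_F` … `gfp_Prm_8_R`, one forward/reverse pair per junction
edge).

Quantify the bundled induction screen and calibration series:

```sh
$ chipsyn quantify readings.csv
{
  "induced_mean": 0.326,
  "uninduced_mean": 0.0377,
  "fold": 8.64
}
$ chipsyn fit-cal cal.csv --form offchip
{
  "form": "offchip",
  "a": 3.275258640621645,
  "b": 7.455969909899906,
  "rms_residual": 0.13038028291365975
}
```

The induced wells average 0.326 versus 0.0377 uninduced — an ≈8.6-fold
induction — and the six-point OD620 standard series fits
`conc ≈ 3.28·e^{7.456·OD}` mg/L.

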