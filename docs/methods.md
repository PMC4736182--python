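# Methods

This note documents the models and algorithms behind `chipsyn`, the
assumptions they make, the parameters that matter, and the choices made
where the design was genuinely open.

## Sequence model and the part language

DNA is represented by its sense strand as an uppercase string over
{A,C,G,T}. IUPAC ambiguity codes are rejected: every downstream
algorithm (junction scoring, 3′ screening, exact sharing) is defined on
base identity and has no meaningful semantics for degenerate positions.
All user-facing coordinates are 1-based and inclusive at both ends —
`Seq1[5-10]` selects six nucleotides.

The part language executes statements in declaration order with purely
functional semantics. A mutation statement `Q([3-4] = "TT")` rebinds `Q`
from that line onward; parts already derived from the old value keep it.
This was an open choice (rebind versus shadow copy); declaration-order
rebinding was picked because it is the least surprising reading of an
imperative-looking script and makes every script a straight-line
program, trivially acyclic. Mutation replacements may differ in length
from the excised span; coordinates in later statements refer to the new
sequence. Lines starting with `#` are comments.

## Junction scoring

When a target is divided, the two children share a junction overlap
through which they prime each other during isothermal extension. A bad
junction is one whose sequence can also anneal elsewhere. The score of
a candidate overlap O against a flank F is the maximum, over all
ungapped alignments of O with a full-length window of F on either
strand, of the number of positional base matches (weighted by
`match_score`, default 1 per base). The shorter string slides inside the
longer, so overhanging alignments are never credited. The reverse-strand
term scores the reverse complement of O against F's sense
representation, which counts Watson–Crick pairings with the bottom
strand.

One scoring engine serves both the division planner (overlap vs. the
children's non-overlap flanks) and primer selection (candidate vs.
template, intended site excluded). This is a match-count model, not a
thermodynamic one: no nearest-neighbor ΔG, no melting temperature. The
flank comparison is overlap-vs-flank rather than flank-vs-flank —
mispriming of the junction is the shared failure mode of
overlap-extension and Gibson chemistry, and the formulation is
exhaustively checkable against a brute-force oracle, which the test
suite does.

For an exhaustive candidate scan the naive cost is O(L³) per node; a
vectorized table computes all (p, v) scores in O(v_max·L²) using running
diagonal (sense) and anti-diagonal (reverse-strand) sums of the
base-identity matrices. The table is exact; the few edge candidates
whose flank is shorter than the overlap fall back to the reference
scorer, and tests assert table/reference equality over every candidate.

## Division search

Parameters: `synthesis_threshold` (130 nt default — longest directly
synthesizable oligo), `min_overlap`/`max_overlap` (20/45 nt), and a
center search window. Nodes up to `exhaustive_limit` (600 nt) are
scanned over every split position; longer nodes over a window of
±`tie_radius_frac` (5%) of node length around the center.

Candidates (p, v) are ranked lexicographically by:

1. **subtree leaf count** — f(|left|) + f(|right|), where f is a
   length-only dynamic program giving the fewest leaves a centered
   recursion needs; fewer leaves means fewer synthesis reactions, the
   planner's primary economy;
2. **mispriming score** of the junction (lower is safer);
3. **center distance** |p − L/2| (symmetric trees);
4. smaller v, then smaller p (pure determinism — planning uses no RNG).

The leaf-count DP deliberately applies the centered candidate rule at
every length, including lengths where the score scan is exhaustive.
Minimizing leaves globally would reward chain-shaped trees (e.g. a
754 nt target can be covered by 7 leaves as a lopsided tree), but a
chain of depth n−1 serializes the bench work that a balanced tree of
depth log₂(n) parallelizes; the symmetric discipline yields the
8-leaf, 7-reaction, 3-level decomposition for a 754 nt target at the
default parameters. The 5% tie radius was likewise chosen because it
enforces near-symmetric division; a 10% window already admits the
lopsided plans the discipline exists to avoid.

Both children strictly shorten (p ≥ 1, p+v ≤ L−1), so recursion
terminates; every leaf is ≤ threshold unless it is a natural fragment.

## Shared intermediates and natural fragments

Sharing is exact: a fragment can serve several assemblies unchanged only
if it is a perfect substring of each target, so detection is maximal
exact common substrings (length ≥ `min_share`, default 2× min overlap)
rather than alignment. The search is widest-membership-first, then
longest: a block reused by four variants saves three syntheses, whereas
a chance one-base extension that only one pair of targets happens to
share would otherwise be claimed first and split the member set.
Claimed spans are masked per target, so reported blocks never overlap
within a target.

Natural fragments must match exactly ("true subsequences"); absent
fragments are rejected with a report, not an error. When a fragment has
several occurrences, the anchor nearest the target center is used —
that is where the division search has the least freedom. Anchored spans
constrain division: no split may cut through a span, and candidates are
aligned to the span's edges so the fragment is peeled out as one whole
leaf (exempt from the synthesis threshold). Shared blocks longer than
the threshold are expanded into their own subtrees; since planning is
deterministic on sequence, identical blocks yield identical subtrees
and the plan counts each unique reaction product once.

## Primer design

Forward primers are literal prefixes of the reaction product, reverse
primers reverse complements of literal suffixes; lengths 18–45 nt with
a 3′ window of k = 8. A candidate is discarded if its 3′-terminal k-mer
occurs anywhere else on either strand of the template — polymerase
extension requires a perfectly annealed 3′ end, so exact k-mer
duplication is the discard rule (an optional `max_offtarget_score`
threshold can additionally discard on total similarity; by default
ranking alone decides). Survivors are ranked by the off-target
similarity score with the intended site excluded; ties go to the
shorter primer. Melting-temperature balancing is deliberately not used;
selection is purely score-driven.

Children share their outer end with the parent product, so the left
child inherits the parent's forward primer and the right child its
reverse primer (flagged `inherited`); only junction-facing primers are
picked fresh. A perfect tree of 8 leaves therefore needs exactly 8
distinct primers, one forward per odd leaf edge and one reverse per
even, named `<target>_Prm_<leaf>_<F|R>`.

## Assembly simulation

Fragments are sense-strand dsDNA; bench oligo sets alternate strands,
so even-numbered oligos are reverse-complemented on load. Overlap
extension merges two fragments over their longest terminal exact
overlap (≥ `min_overlap`), orienting the second fragment as needed;
the product length is |A| + |B| − v. Junction detection is exact-match
only — enzymatic error is out of scope — and ambiguity (two equally
long maximal junctions, or both orientations valid) is an error rather
than a choice, because a sound plan never produces one and silent
disambiguation would mask planner bugs. Amplification is modeled as
identity on sequence after validating that the forward primer is a
prefix and the reverse primer closes the suffix.

The package's central correctness property is the round trip: folding
any planned tree bottom-up with overlap extension reproduces the root
target byte-for-byte. The suite asserts this on 200 seeded targets of
150–500 nt (sizes chosen to keep the default run fast while covering
1–3 division levels) and on the bundled 754 nt construct.

Gibson assembly finds the unique cyclic order in which terminal
homologies (≥ `min_homology`, either orientation) chain all fragments
into one circle; a single fragment with identical termini
self-circularizes. Circle length equals Σ|fragments| − Σ homologies.
Circular products are canonicalized to the lexicographically minimal
rotation over both strands, so equality is rotation- and
flip-invariant. Golden-Gate fragments carry 4-nt overhangs written as
the top-strand junction string; two ends ligate iff their junction
strings are equal (the standard overhang-specification convention — the
two single strands are then exact Watson–Crick partners), and the
overhang set must dictate exactly one cyclic arrangement.

## Chip compilation

The chip is an undirected graph (wells and valve junctions are nodes,
channels edges) loaded from a YAML config; a generator ships for the
physical platform's topology class, a rectangular valve grid ringed by
peripheral wells (5×5 valves gives the 16-well layout). Routing is
minimum-hop BFS with a lexicographic tie-break at every step, so
programs are byte-identical across runs. Volumes are quantized to the
platform's 150 nL transfer cycle, `cycles = ceil(amount·1000/150)` —
delivery may overshoot by at most one cycle but never undershoots.

Peristalsis is modeled as a three-valve traveling wave walked along the
route once per cycle (the standard actuation pattern for monolithic
membrane valves): the wave opens the next valve, closing the valve
three behind, so at most three are open at once and every open is
matched by a close. The per-step dwell is the Method's actuation time,
definable once per reagent (viscous reagents need longer dwells) and
overridable per command. A virtual replay validates programs
independently: route edges must exist, the schedule must be a
well-formed wave, and accounting moves exactly cycles × 150 nL from
source to destination.

Transfers of different reagents that reuse a channel segment are listed
by the contamination report in program order. When a wash well is
designated, buffer flushes are inserted automatically before any
conflicting transfer; the wash routes from the wash well through the
upcoming pathway (wash → source → destination), which clears exactly
the segments the next transfer will use. Scheduling is strictly
sequential, matching the single-pump device.

## Quantification

Well intensity is the arithmetic mean of the green channel over a
21×21 pixel window centered on the well (441 pixels), scaled to [0, 1]
(8-bit images divided by 255). Induction fold is the ratio of group
means in linear space — no log transform — and is invariant to global
intensity scaling.

Calibration curves have the form conc = a·e^{b·x} with x = 1 − I for
on-chip images (darker developed color ⇒ more analyte, so predictions
strictly decrease in intensity when b > 0) and x = OD620 off-chip. The
fit is unweighted least squares of ln(conc) on x — the everyday
"exponential trendline" — requiring ≥ 3 points, positive
concentrations, and non-degenerate predictors; residuals are reported
in ln space. A multiplicative brightness factor compensates global
image exposure; it is an imaging artifact, never baked into a fitted
curve, applied only at prediction time (1 by default).

## Synthetic fixtures

All test randomness flows through seeded `numpy` generators. The
fixture module emulates: uniform random DNA (no composition bias —
planted exact repeats and shared blocks are the only structure, with
ground-truth coordinates returned alongside); combinatorial part
scripts; valve-grid chip configs; and chip images idealized as flat-top
disks (radius 15 px, Gaussian shoulder σ = 2 px) of known peak
amplitude plus additive Gaussian noise. The disk radius covers the
corners of the 21×21 sampling window, so a centered window's mean
recovers the amplitude exactly up to noise. Real images differ in ways
the fixed-window arithmetic does not see (vignetting, compression,
reflections, well auto-location); passing tests validate the
measurement math and calibration algebra, not image segmentation,
which is out of scope.

## Known limitations

- Scores are match counts, not hybridization free energies; two
  junctions with equal counts but different GC content tie.
- Sharing is exact; synonymous-codon or near-identical reuse is not
  detected.
- The assembler has no misassembly probability or kinetics; it verifies
  plans, it does not predict yields.
- The chip compiler assumes lossless, leak-free valves and does not
  model pressure or mixing dynamics.
- Combinatorial targets must be written out (or generated) as an
  explicit list; the language has no cross-product operator.
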