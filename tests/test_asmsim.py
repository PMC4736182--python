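"""In-silico assembly: overlap extension, Gibson circles, Golden Gate."""

import pytest

from chipsyn import datasets
from chipsyn.asmsim import (
    AssemblyError,
    CircularProduct,
    Fragment,
    StickyFragment,
    canonical_rotation,
    enumerate_goldengate_library,
    gibson_circularize,
    goldengate_ligate,
    overlap_extend,
    simulate_ihdc_step,
    simulate_tree,
)
from chipsyn.fixtures import random_dna
from chipsyn.sequence import reverse_complement


class TestOverlapExtend:
    def test_constructed_overlap_merges(self, rng):
        x, o, y = random_dna(rng, 80), random_dna(rng, 38), random_dna(rng, 80)
        a, b = Fragment("A", x + o), Fragment("B", o + y)
        product = overlap_extend(a, b, 15)
        assert product.sequence == x + o + y
        assert len(product) == len(a) + len(b) - 38

    def test_antisense_partner_is_oriented(self, rng):
        x, o, y = random_dna(rng, 80), random_dna(rng, 30), random_dna(rng, 80)
        a = Fragment("A", x + o)
        b = Fragment("B", reverse_complement(o + y))
        assert overlap_extend(a, b, 15).sequence == x + o + y

    def test_no_junction_raises(self, rng):
        a, b = Fragment("A", random_dna(rng, 100)), Fragment("B", random_dna(rng, 100))
        with pytest.raises(AssemblyError, match="no junction"):
            overlap_extend(a, b, 15)

    def test_associative_on_unique_chain(self, rng):
        o1, o2 = random_dna(rng, 25), random_dna(rng, 25)
        x, y, z = random_dna(rng, 60), random_dna(rng, 60), random_dna(rng, 60)
        a = Fragment("A", x + o1)
        b = Fragment("B", o1 + y + o2)
        c = Fragment("C", o2 + z)
        left = overlap_extend(overlap_extend(a, b, 15), c, 15)
        right = overlap_extend(a, overlap_extend(b, c, 15), 15)
        assert left.sequence == right.sequence == x + o1 + y + o2 + z

    def test_gfp_oligos_assemble_to_754(self):
        frags = datasets.as_fragments(datasets.GFP_OLIGOS)
        quarters = [
            overlap_extend(frags[i], frags[i + 1], 15) for i in (0, 2, 4, 6)
        ]
        halves = [
            overlap_extend(quarters[0], quarters[1], 15),
            overlap_extend(quarters[2], quarters[3], 15),
        ]
        full = overlap_extend(halves[0], halves[1], 15)
        assert len(full) == 754

    def test_rfp_oligos_chain_into_single_product(self):
        frags = datasets.as_fragments(datasets.RFP_OLIGOS)
        half1 = overlap_extend(frags[0], frags[1], 15)
        half2 = overlap_extend(frags[2], frags[3], 15)
        full = overlap_extend(half1, half2, 15)
        for f in frags:
            assert full.sequence.count(f.sequence) == 1


class TestIhdcStep:
    def test_valid_quarter_fragment_with_printed_primers(self):
        frags = datasets.as_fragments(datasets.GFP_OLIGOS)
        product = simulate_ihdc_step(
            frags[0],
            frags[1],
            datasets.GFP_PRIMERS["gfp_Prm_1_F"],
            datasets.GFP_PRIMERS["gfp_Prm_2_R"],
            15,
        )
        assert len(product) == 218

    def test_truncated_forward_primer_still_primes(self):
        frags = datasets.as_fragments(datasets.GFP_OLIGOS)
        p1 = datasets.GFP_PRIMERS["gfp_Prm_1_F"][:20]
        product = simulate_ihdc_step(
            frags[0], frags[1], p1, datasets.GFP_PRIMERS["gfp_Prm_2_R"], 15
        )
        assert product.sequence.startswith(p1)

    def test_internal_mismatch_rejected(self):
        frags = datasets.as_fragments(datasets.GFP_OLIGOS)
        p1 = list(datasets.GFP_PRIMERS["gfp_Prm_1_F"])
        p1[10] = "A" if p1[10] != "A" else "C"
        with pytest.raises(AssemblyError, match="forward primer"):
            simulate_ihdc_step(
                frags[0], frags[1], "".join(p1), datasets.GFP_PRIMERS["gfp_Prm_2_R"], 15
            )


class TestCircularization:
    def test_two_fragment_circle_length(self, rng):
        o1, o2 = random_dna(rng, 40), random_dna(rng, 40)
        core, gfp = random_dna(rng, 300), random_dna(rng, 200)
        vector = Fragment("V", o2 + core + o1)
        insert = Fragment("I", o1 + gfp + o2)
        circle = gibson_circularize([vector, insert], 15)
        assert len(circle) == len(vector) + len(insert) - 80
        assert len(circle.junctions) == 2

    def test_self_circularization(self, rng):
        o = random_dna(rng, 20)
        f = Fragment("F", o + random_dna(rng, 200) + o)
        circle = gibson_circularize([f], 15)
        assert len(circle) == len(f) - 20

    def test_three_fragment_circle_with_mid_gene_junction(self, rng):
        # two gene halves overlapping mid-gene, plus a vector flanking both
        ov, og1, og2 = random_dna(rng, 30), random_dna(rng, 30), random_dna(rng, 30)
        half1 = Fragment("H1", og1 + random_dna(rng, 150) + ov)
        half2 = Fragment("H2", ov + random_dna(rng, 150) + og2)
        vector = Fragment("V", og2 + random_dna(rng, 250) + og1)
        circle = gibson_circularize([half1, half2, vector], 15)
        assert len(circle) == sum(map(len, (half1, half2, vector))) - 90
        assert len(circle.junctions) == 3

    def test_rotation_and_flip_invariance(self, rng):
        seq = random_dna(rng, 120)
        rotated = seq[50:] + seq[:50]
        flipped = reverse_complement(rotated)
        assert canonical_rotation(seq) == canonical_rotation(rotated)
        assert CircularProduct(seq) == CircularProduct(flipped)

    def test_disconnected_fragment_fails(self, rng):
        o = random_dna(rng, 30)
        a = Fragment("A", o + random_dna(rng, 100) + o)  # self-closing
        b = Fragment("B", random_dna(rng, 100))
        with pytest.raises(AssemblyError):
            gibson_circularize([a, b], 15)


def _library_parts(rng, n=4):
    # junction overhangs: backbone-J1-promoter, promoter-J2-bcd, bcd-J3-backbone
    j1, j2, j3 = "CATG", "GGAC", "TCCA"
    proms = [
        StickyFragment(f"prom{i}", random_dna(rng, 50), j1, j2) for i in range(n)
    ]
    bcds = [
        StickyFragment(f"bcd{j}", random_dna(rng, 150), j2, j3) for j in range(n)
    ]
    backbone = StickyFragment("p4001", random_dna(rng, 400), j3, j1)
    return proms, bcds, backbone


class TestGoldenGate:
    def test_ligation_order_follows_overhangs(self, rng):
        proms, bcds, backbone = _library_parts(rng)
        circle = goldengate_ligate(proms[0], bcds[0], backbone)
        linear = "CATG" + proms[0].core + "GGAC" + bcds[0].core + "TCCA" + backbone.core
        assert circle == CircularProduct(linear)

    def test_incompatible_overhang_rejected(self, rng):
        proms, bcds, backbone = _library_parts(rng)
        bad = StickyFragment("bad", proms[0].core, "AAAA", "TTTT")
        with pytest.raises(AssemblyError, match="incompatible"):
            goldengate_ligate(bad, bcds[0], backbone)

    def test_sixteen_variant_library(self, rng):
        proms, bcds, backbone = _library_parts(rng)
        lib = enumerate_goldengate_library(proms, bcds, backbone)
        assert len(lib) == 16
        assert len(set(lib.values())) == 16

    def test_batched_runs_equal_single_run(self, rng):
        proms, bcds, backbone = _library_parts(rng)
        full = enumerate_goldengate_library(proms, bcds, backbone)
        batch1 = enumerate_goldengate_library(proms[:2], bcds, backbone)
        batch2 = enumerate_goldengate_library(proms[2:], bcds, backbone)
        assert set(full.values()) == set(batch1.values()) | set(batch2.values())


class TestTreeRoundTrip:
    @pytest.mark.parametrize("seed", range(6))
    def test_fold_reproduces_target(self, seed):
        from chipsyn.hierplan import DivisionParams, build_tree

        params = DivisionParams(synthesis_threshold=70, min_overlap=10, max_overlap=18)
        target = random_dna(seed, 180 + 60 * seed)
        tree = build_tree(target, params)
        assert simulate_tree(tree).sequence == target

    def test_corrupted_leaf_detected(self, gfp_target, default_division):
        from chipsyn.hierplan import build_tree

        tree = build_tree(gfp_target, default_division)
        leaf = tree.leaves()[2]
        seq = list(leaf.sequence)
        mid = len(seq) // 2
        seq[mid] = "A" if seq[mid] != "A" else "C"
        leaf.sequence = "".join(seq)
        try:
            product = simulate_tree(tree)
            assert product.sequence != gfp_target
        except AssemblyError:
            pass  # a junction-adjacent corruption can break the overlap itself
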