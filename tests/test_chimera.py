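import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mitoscreen import (annotate_segments, compare_flanking,
                        longest_exact_match, overall_identity)
from mitoscreen.seqs import revcomp

from conftest import random_dna
from oracles import longest_common_substring

dna = st.text(alphabet="ACGT", min_size=1, max_size=80)


class TestOverallIdentity:
    def test_identical_sequences_are_100(self, rng):
        seq = random_dna(rng, 250)
        assert overall_identity(seq, seq, "nt") == 100.0

    def test_planted_substitution_count_sets_identity(self, rng):
        seq = random_dna(rng, 100)
        positions = rng.choice(100, size=10, replace=False)
        mutated = list(seq)
        for p in positions:
            mutated[p] = {"A": "C", "C": "G", "G": "T", "T": "A"}[mutated[p]]
        assert overall_identity(seq, "".join(mutated), "nt") == 90.0

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(a=dna, b=dna)
    def test_symmetric_and_100_iff_equal(self, a, b):
        ab = overall_identity(a, b, "nt")
        assert ab == overall_identity(b, a, "nt")
        if a == b:
            assert ab == 100.0
        # near-100 rounding can only reach 100 for equal-length near-copies
        if ab == 100.0 and len(a) == len(b):
            assert sum(x != y for x, y in zip(a, b)) <= len(a) / 200

    def test_amino_acid_mode_and_alphabet_check(self):
        assert overall_identity("MKLVVF", "MKLVVF", "aa") == 100.0
        with pytest.raises(ValueError):
            overall_identity("MKLVVF", "MKLVVF", "nt")


class TestAnnotateSegments:
    def test_query_equal_to_library_gene(self, rng):
        gene = random_dna(rng, 600)
        segs = annotate_segments(gene, {"geneA": gene, "geneB": random_dna(rng, 500)})
        assert len(segs) == 1
        seg = segs[0]
        assert seg.donor_id == "geneA"
        assert seg.identity_pct == 100.0
        assert seg.query_end - seg.query_start + 1 >= 0.95 * len(gene)

    def test_three_fragment_chimera_recovered(self, rng):
        genes = {f"g{i}": random_dna(rng, 700) for i in range(3)}
        frags, truth = [], []
        cursor = 1
        for i, (name, seq) in enumerate(genes.items()):
            frag = seq[100:100 + 180]
            if i == 1:  # plant ~6% divergence in the middle fragment
                frag = list(frag)
                for p in rng.choice(180, size=11, replace=False):
                    frag[p] = {"A": "C", "C": "G", "G": "T", "T": "A"}[frag[p]]
                frag = "".join(frag)
            linker = random_dna(rng, 40)
            frags.extend([frag, linker])
            truth.append((name, cursor, cursor + 179,
                          100.0 if i != 1 else 100 * (180 - 11) / 180))
            cursor += 180 + 40
        query = "".join(frags)
        segs = annotate_segments(query, genes, min_seg_len=50)
        assert [s.donor_id for s in segs] == ["g0", "g1", "g2"]
        for seg, (name, q_lo, q_hi, ident) in zip(segs, truth):
            assert abs(seg.query_start - q_lo) <= 5
            assert abs(seg.query_end - q_hi) <= 5
            assert abs(seg.identity_pct - ident) <= 1.0

    def test_exact_tiling_matches_greedy_on_clean_chimera(self, rng):
        genes = {"a": random_dna(rng, 500), "b": random_dna(rng, 500)}
        query = genes["a"][:200] + random_dna(rng, 30) + genes["b"][200:430]
        greedy = annotate_segments(query, genes, method="greedy")
        exact = annotate_segments(query, genes, method="exact")
        assert [(s.donor_id, s.query_start, s.query_end) for s in greedy] == \
               [(s.donor_id, s.query_start, s.query_end) for s in exact]

    def test_bundle_chimera_segment_matches_manifest(self, bundle):
        truth = bundle.manifest["chimera"]["donor_segment"]
        segs = annotate_segments(bundle.manifest["chimera_nt"],
                                 bundle.reference.gene_library())
        donor_hits = [s for s in segs if s.donor_id == truth["donor"]]
        assert len(donor_hits) == 1
        seg = donor_hits[0]
        assert abs(seg.query_start - truth["query_nt"][0]) <= 5
        assert abs(seg.query_end - truth["query_nt"][1]) <= 5
        assert abs(seg.identity_pct - truth["identity_pct"]) <= 1.0


class TestLongestExactMatch:
    def test_identical_sequences(self, rng):
        seq = random_dna(rng, 100)
        length, a_iv, b_iv, strand = longest_exact_match(seq, seq)
        assert (length, a_iv, b_iv, strand) == (100, (1, 100), (1, 100), "+")

    def test_planted_block_in_random_pair(self, rng):
        # guard bases stop the planted block extending by chance
        block = random_dna(rng, 48)
        a = random_dna(rng, 499) + "A" + block + "A" + random_dna(rng, 451)
        b = random_dna(rng, 299) + "C" + block + "C" + random_dna(rng, 651)
        length, a_iv, b_iv, strand = longest_exact_match(a, b)
        assert length == 48
        assert a_iv == (501, 548)
        assert b_iv == (301, 348)
        assert strand == "+"

    def test_reverse_strand_block_found(self, rng):
        block = random_dna(rng, 60)
        a = random_dna(rng, 200) + block + random_dna(rng, 200)
        b = random_dna(rng, 100) + revcomp(block) + random_dna(rng, 100)
        length, _, b_iv, strand = longest_exact_match(a, b)
        assert length == 60
        assert strand == "-"
        assert b_iv == (101, 160)

    @pytest.mark.parametrize("seed", range(4))
    def test_matches_naive_dp_oracle(self, seed):
        rng = np.random.default_rng(7_000 + seed)
        a = random_dna(rng, 1_500)
        b = random_dna(rng, 2_000)
        if seed % 2:  # plant a shared block in half the cases
            block = a[400:400 + 37]
            b = b[:900] + block + b[937:]
        assert longest_exact_match(a, b)[0] == longest_common_substring(a, b)

    def test_bundle_cox2_block_is_exactly_48(self, bundle):
        truth = bundle.manifest["chimera"]["exact_block"]
        cox2 = bundle.reference.cds(truth["donor"])
        length, a_iv, b_iv, _ = longest_exact_match(bundle.manifest["chimera_nt"], cox2)
        assert length == truth["length"] == 48
        assert list(a_iv) == truth["query_nt"]
        assert list(b_iv) == truth["donor_nt"]


class TestCompareFlanking:
    def test_identical_regions(self, rng):
        region = random_dna(rng, 300)
        cmp = compare_flanking(region, region, 200)
        assert cmp.identity_pct == 100.0
        assert cmp.differences == []

    def test_planted_substitutions_at_anchored_positions(self, rng):
        ref = random_dna(rng, 203)   # 200 bp upstream + start codon
        query = list(ref)
        planted = {-150: None, -42: None, -7: None}
        for rel in planted:
            idx = 200 + rel  # anchor at position 201
            planted[rel] = (ref[idx], {"A": "C", "C": "G", "G": "T", "T": "A"}[ref[idx]])
            query[idx] = planted[rel][1]
        cmp = compare_flanking("".join(query), ref, 201)
        got = {d.position: (d.ref_base, d.query_base) for d in cmp.differences}
        assert got == planted
        assert all(d.kind == "substitution" for d in cmp.differences)

    def test_bundle_promoter_capture_differences(self, bundle):
        truth = bundle.manifest["promoter"]
        insert = bundle.derivation.insert_seq
        lo, hi = truth["insert_start"] - 1, truth["insert_end"]
        query = insert[lo:hi + 3]             # captured promoter + ATG
        ref = bundle.reference.promoter(truth["source_gene"])
        g = bundle.reference.gene(truth["source_gene"])
        ref_region = ref + bundle.reference.seq[g.start - 1:g.start + 2]
        cmp = compare_flanking(query, ref_region, truth["length"] + 1)
        assert abs(cmp.identity_pct - truth["identity_pct"]) <= 1.0
        positions = sorted(d.position for d in cmp.differences)
        assert positions == sorted(truth["diff_positions_from_start_codon"])
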