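import numpy as np
import pytest

from mitoscreen import (SubstitutionEvent, apply_substitution, digest,
                        insilico_pcr, locate_substitution, probe_fragments)
from mitoscreen.validation import ENZYMES, JunctionMismatchError, gel_size_kbp
from mitoscreen.seqs import revcomp

from conftest import random_dna
from oracles import digest_sites


class TestApplySubstitution:
    def test_replacing_interval_with_itself_is_identity(self, rng):
        backbone = random_dna(rng, 5_000)
        event = SubstitutionEvent("b", 1_001, 2_000, "i",
                                  left_flank=98, right_flank=98)
        assert apply_substitution(backbone, event, backbone[1_000:2_000]) == backbone

    def test_printed_event_arithmetic(self, rng):
        # the Tadukan-type event: a 355,786-bp backbone whose interval
        # 114,769..132,679 (17,911 bp) is substituted by a 6,141-bp
        # insert -> 344,016-bp recombinant
        backbone = random_dna(rng, 355_786)
        event = SubstitutionEvent("subgenome-1", 114_769, 132_679, "contig-6-like",
                                  left_flank=98, right_flank=98)
        assert event.replaced_len == 17_911
        insert = (backbone[114_768:114_768 + 98] + random_dna(rng, 6_141 - 196)
                  + backbone[132_679 - 98:132_679])
        recombinant = apply_substitution(backbone, event, insert)
        assert len(recombinant) == 355_786 - 17_911 + 6_141 == 344_016

    def test_flank_mismatch_names_the_junction(self, rng):
        backbone = random_dna(rng, 2_000)
        event = SubstitutionEvent("b", 501, 1_500, "i", left_flank=98, right_flank=98)
        bad = random_dna(rng, 800)
        with pytest.raises(JunctionMismatchError, match="left junction"):
            apply_substitution(backbone, event, bad)
        half_good = backbone[500:598] + random_dna(rng, 700)
        with pytest.raises(JunctionMismatchError, match="right junction"):
            apply_substitution(backbone, event, half_good)

    def test_locate_substitution_recovers_event(self, rng):
        backbone = random_dna(rng, 30_000)
        s, e = 12_001, 19_000
        insert = backbone[s - 1:s - 1 + 98] + random_dna(rng, 3_000) \
            + backbone[e - 98:e]
        event = SubstitutionEvent("b", s, e, "i", left_flank=98, right_flank=98)
        recombinant = apply_substitution(backbone, event, insert)
        recovered = locate_substitution(backbone, recombinant, 98)
        assert (recovered.start, recovered.end) == (s, e)


class TestDigest:
    def test_no_sites_linear_single_fragment(self, rng):
        seq = random_dna(rng, 1_000)
        while "GGATCC" in seq:
            seq = seq.replace("GGATCC", "GGATCA")
        frags = digest(seq, "BamHI", "linear")
        assert len(frags) == 1
        assert frags[0].length == len(seq)

    def test_single_site_cut_offset_convention(self):
        seq = "A" * 400 + "GGATCC" + "A" * 594
        frags = digest(seq, "BamHI", "linear")
        assert [f.length for f in frags] == [401, 599]
        assert [(f.start, f.end) for f in frags] == [(1, 401), (402, 1000)]

    @pytest.mark.parametrize("enzyme", sorted(ENZYMES))
    def test_random_100kb_matches_naive_site_scan(self, enzyme):
        rng = np.random.default_rng(hash(enzyme) % 2**31)
        seq = random_dna(rng, 100_000)
        frags = digest(seq, enzyme, "linear")
        assert sum(f.length for f in frags) == 100_000
        site, offset = ENZYMES[enzyme]
        cuts = digest_sites(seq, site, offset)
        assert [f.end for f in frags[:-1]] == cuts

    def test_circular_topology_fragment_count_equals_sites(self, rng):
        seq = random_dna(rng, 50_000)
        frags = digest(seq, "SacI", "circular")
        n_sites = len(digest_sites(seq, *ENZYMES["SacI"]))
        assert len(frags) == n_sites
        assert sum(f.length for f in frags) == 50_000

    def test_uncut_circle_flagged(self):
        seq = "A" * 2_000
        frags = digest(seq, "BamHI", "circular")
        assert len(frags) == 1 and frags[0].uncut

    def test_gel_rounding_two_significant_figures(self):
        assert gel_size_kbp(4_812) == 4.8
        assert gel_size_kbp(10_230) == 10.0
        assert gel_size_kbp(969) == 0.97


class TestProbe:
    def test_probe_inside_one_fragment(self):
        seq = "A" * 400 + "GGATCC" + "A" * 594
        frags = probe_fragments(digest(seq, "BamHI"), 100, 200)
        assert [f.probe_hit for f in frags] == [True, False]

    def test_probe_spanning_cut_site_hits_two(self):
        seq = "A" * 400 + "GGATCC" + "A" * 594
        frags = probe_fragments(digest(seq, "BamHI"), 380, 450)
        assert [f.probe_hit for f in frags] == [True, True]


class TestPcr:
    def test_primers_from_region_ends_give_one_product(self, rng):
        template = random_dna(rng, 3_000)
        region = template[1_000:1_500]
        products = insilico_pcr(template, region[:20], revcomp(region[-20:]))
        assert len(products) == 1
        assert (products[0].start, products[0].end) == (1_001, 1_500)
        assert products[0].length == 500

    def test_planted_pair_in_50kb(self, rng):
        template = random_dna(rng, 50_000)
        fwd = template[30_000:30_022]
        rev = revcomp(template[33_978:34_000])
        products = insilico_pcr(template, fwd, rev, max_product=8_000)
        assert [(p.start, p.end, p.length) for p in products] == [(30_001, 34_000, 4_000)]

    def test_orientation_invariance_under_template_revcomp(self, rng):
        template = random_dna(rng, 10_000)
        fwd = template[2_000:2_020]
        rev = revcomp(template[2_480:2_500])
        direct = insilico_pcr(template, fwd, rev)
        mirrored = insilico_pcr(revcomp(template), fwd, rev)
        assert len(direct) == len(mirrored) == 1
        assert direct[0].length == mirrored[0].length == 500
        assert mirrored[0].start == len(template) - direct[0].end + 1

    def test_mismatch_tolerance(self, rng):
        template = random_dna(rng, 5_000)
        fwd = list(template[1_000:1_020])
        fwd[5] = {"A": "C", "C": "G", "G": "T", "T": "A"}[fwd[5]]
        fwd = "".join(fwd)
        rev = revcomp(template[1_580:1_600])
        assert insilico_pcr(template, fwd, rev, max_mismatch=0) == []
        products = insilico_pcr(template, fwd, rev, max_mismatch=1)
        assert [p.length for p in products] == [600]
        assert products[0].mismatches == 1

    def test_linkage_primers_detect_true_junctions_only(self, bundle):
        # primers straddling each true contig junction amplify on the tiled
        # genome; primers from non-adjacent contig ends do not
        genome = bundle.fragmentation.genome
        path = bundle.fragmentation.path
        contigs = bundle.contigs
        from mitoscreen.seqs import revcomp as rc

        def oriented(cid, orient):
            return contigs[cid] if orient == "+" else rc(contigs[cid])

        for (a_id, ao), (b_id, bo) in list(zip(path, path[1:]))[:4]:
            a_seq, b_seq = oriented(a_id, ao), oriented(b_id, bo)
            fwd = a_seq[-300:-280]
            rev = rc(b_seq[280:300])
            products = insilico_pcr(genome, fwd, rev, max_product=1_500)
            assert products, f"no product across junction {a_id}->{b_id}"
        # non-adjacent pair: first contig start, last contig end
        first = oriented(*path[0])
        last = oriented(*path[-1])
        assert insilico_pcr(genome, first[:20], rc(last[-20:]),
                            max_product=8_000) == []
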