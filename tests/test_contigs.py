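import logging

import numpy as np
import pytest

from mitoscreen import (Contig, anchor_end_to_molecule, assemble_master,
                        classify_plasmid_like, detect_contained,
                        find_end_overlaps)
from mitoscreen.contigs import oriented_joins
from mitoscreen.seqs import revcomp

from conftest import random_dna
from oracles import all_walks_min_length

K = 98


def _chain(rng, tile_lens, k=K):
    """Build a genome and the contigs tiling it with k-bp overlaps."""
    genome = random_dna(rng, sum(tile_lens) - k * (len(tile_lens) - 1))
    contigs, pos = [], 0
    for i, ln in enumerate(tile_lens):
        contigs.append(Contig(f"c{i}", genome[pos:pos + ln]))
        pos += ln - k
    return genome, contigs


class TestFindEndOverlaps:
    def test_single_constructed_overlap(self, rng):
        _, (a, b) = _chain(rng, [200, 200])
        linkages = find_end_overlaps([a, b])
        assert len(linkages) == 1
        joins = oriented_joins(linkages)
        assert (("c0", "+"), ("c1", "+")) in joins

    def test_reverse_complement_contig_still_links(self, rng):
        _, (a, b) = _chain(rng, [300, 250])
        flipped = Contig(b.id, revcomp(b.seq))
        joins = oriented_joins(find_end_overlaps([a, flipped]))
        assert (("c0", "+"), ("c1", "-")) in joins

    def test_no_shared_end_gives_empty_list(self, rng):
        a = Contig("a", random_dna(rng, 300))
        b = Contig("b", random_dna(rng, 300))
        assert find_end_overlaps([a, b]) == []

    def test_twin_of_every_linkage_is_derivable(self, rng):
        _, contigs = _chain(rng, [200, 300, 400, 250])
        linkages = find_end_overlaps(contigs)
        joins = oriented_joins(linkages)
        for lk in linkages:
            twin = lk.twin()
            assert (twin.a_node, twin.b_node) in joins

    def test_short_contig_rejected_with_warning(self, rng, caplog):
        _, contigs = _chain(rng, [200, 200])
        short = Contig("tiny", random_dna(rng, 50))
        with caplog.at_level(logging.WARNING):
            linkages = find_end_overlaps(contigs + [short])
        assert any("tiny" in rec.message for rec in caplog.records)
        assert all("tiny" not in (lk.a_id, lk.b_id) for lk in linkages)

    def test_linkage_set_matches_generator_truth(self, bundle):
        contigs = [Contig(cid, seq) for cid, seq in bundle.contigs.items()]
        joins = oriented_joins(find_end_overlaps(contigs))
        assert joins == bundle.fragmentation.joins


class TestAnchorEnd:
    def test_unique_forward_placement_and_extension(self, rng):
        target = random_dna(rng, 50_000)
        planted = 3_517
        pos = 20_000
        # guard base stops the planted prefix extending by chance
        guard = "A" if target[pos + planted] != "A" else "C"
        contig = Contig("c", target[pos:pos + planted] + guard + random_dna(rng, 400))
        placements = anchor_end_to_molecule(contig, "head", target)
        fwd = [p for p in placements if p.orientation == "+"]
        assert len(fwd) == 1
        assert fwd[0].target_start == pos + 1
        assert fwd[0].match_len == planted

    def test_tail_and_reverse_placements(self, rng):
        target = random_dna(rng, 10_000)
        contig = Contig("c", random_dna(rng, 300) + target[5_000:5_200])
        tail = anchor_end_to_molecule(contig, "tail", target)
        assert any(p.orientation == "+" and p.target_start == 5_001
                   and p.match_len == 200 for p in tail)
        flipped = Contig("c", revcomp(contig.seq))
        head = anchor_end_to_molecule(flipped, "head", target)
        assert any(p.orientation == "-" and p.match_len == 200 for p in head)

    def test_unlinked_end_returns_empty(self, rng):
        target = random_dna(rng, 5_000)
        contig = Contig("c", random_dna(rng, 500))
        assert anchor_end_to_molecule(contig, "head", target) == []


class TestPlasmidClassification:
    def test_identical_contig_is_plasmid_like_at_100(self, rng):
        ref = random_dna(rng, 1_500)
        calls = classify_plasmid_like([Contig("p", ref)], {"B1": ref})
        assert calls[0].verdict == "plasmid_like"
        assert calls[0].identity_pct == 100.0

    def test_planted_divergence_matches_identity(self, bundle):
        contigs = [Contig(cid, seq) for cid, seq in bundle.contigs.items()]
        calls = {c.contig_id: c for c in
                 classify_plasmid_like(contigs, bundle.plasmid_refs)}
        for cid, truth in bundle.manifest["plasmid_like"].items():
            assert calls[cid].verdict == "plasmid_like"
            assert calls[cid].ref_id == truth["ref"]
            assert abs(calls[cid].identity_pct - truth["identity_pct"]) <= 0.2
        genomic = [c for c in calls.values()
                   if c.contig_id not in bundle.manifest["plasmid_like"]]
        assert all(c.verdict == "genomic" for c in genomic)

    def test_rotated_circular_copy_still_matches(self, rng):
        ref = random_dna(rng, 2_000)
        rotated = ref[700:] + ref[:700]
        calls = classify_plasmid_like([Contig("p", rotated)], {"B1": ref})
        assert calls[0].verdict == "plasmid_like"
        assert calls[0].identity_pct >= 99.9

    def test_empty_reference_set_gives_genomic(self, rng):
        calls = classify_plasmid_like([Contig("p", random_dna(rng, 500))], {})
        assert calls[0].verdict == "genomic"


class TestContainment:
    def test_no_shared_substring_is_empty(self, rng):
        contigs = [Contig("a", random_dna(rng, 400)),
                   Contig("b", random_dna(rng, 400))]
        assert detect_contained(contigs) == []

    def test_planted_inner_found_in_two_outers(self, rng):
        inner = random_dna(rng, 212)
        out1 = random_dna(rng, 400) + inner + random_dna(rng, 300)
        out2 = random_dna(rng, 100) + revcomp(inner) + random_dna(rng, 600)
        pairs = detect_contained([Contig("inner", inner), Contig("o1", out1),
                                  Contig("o2", out2)])
        found = {(p.inner_id, p.outer_id, p.strand) for p in pairs}
        assert ("inner", "o1", "+") in found
        assert ("inner", "o2", "-") in found
        o1_hit = next(p for p in pairs if p.outer_id == "o1")
        assert (o1_hit.outer_start, o1_hit.outer_end) == (401, 612)

    def test_identical_duplicates_flagged_mutually(self, rng):
        seq = random_dna(rng, 300)
        pairs = detect_contained([Contig("a", seq), Contig("b", seq)])
        assert {(p.inner_id, p.outer_id) for p in pairs} == {("a", "b"), ("b", "a")}
        assert all(p.duplicate for p in pairs)


class TestAssembleMaster:
    def test_two_contig_chain_length(self, rng):
        _, contigs = _chain(rng, [400, 500])
        linkages = find_end_overlaps(contigs)
        result = assemble_master(contigs, linkages)
        assert len(result.subgenomes) == 1
        assert result.subgenomes[0].length == 400 + 500 - K

    def test_length_conservation_along_path(self, bundle):
        contigs = [Contig(cid, seq) for cid, seq in bundle.contigs.items()]
        linkages = find_end_overlaps(contigs)
        exclude = set(bundle.manifest["plasmid_like"])
        result = assemble_master(contigs, linkages, exclude=exclude)
        lengths = {c.id: c.length for c in contigs}
        for sub in result.subgenomes:
            expected = (sum(lengths[cid] for cid, _ in sub.path)
                        - (len(sub.path) - 1) * K)
            assert sub.length == expected

    @pytest.mark.parametrize("n_tiles", [3, 4, 5])
    def test_small_graphs_match_exhaustive_enumeration(self, rng, n_tiles):
        lens = [int(x) for x in rng.integers(250, 600, size=n_tiles)]
        genome, contigs = _chain(rng, lens)
        linkages = find_end_overlaps(contigs)
        result = assemble_master(contigs, linkages)
        oracle_min = all_walks_min_length({c.id: c.seq for c in contigs},
                                          oriented_joins(linkages), K, 2)
        assert len(result.subgenomes) == 1
        assert result.subgenomes[0].length == oracle_min == len(genome)

    def test_repeated_tile_graph_matches_oracle(self, rng):
        # genome A-B-C-B-D: contig B used twice
        k = K
        b = random_dna(rng, 400)
        a = random_dna(rng, 300) + b[:k]
        c = b[-k:] + random_dna(rng, 250) + b[:k]
        d = b[-k:] + random_dna(rng, 350)
        genome = a + b[k:] + c[k:] + b[k:] + d[k:]
        contigs = [Contig(x, s) for x, s in
                   (("a", a), ("b", b), ("c", c), ("d", d))]
        linkages = find_end_overlaps(contigs)
        result = assemble_master(contigs, linkages)
        oracle_min = all_walks_min_length({c_.id: c_.seq for c_ in contigs},
                                          oriented_joins(linkages), k, 2)
        assert result.subgenomes[0].length == oracle_min == len(genome)
        assert result.subgenomes[0].seq in (genome, revcomp(genome))

    def test_unlinked_contig_becomes_own_subgenome(self, rng):
        _, contigs = _chain(rng, [400, 500])
        lone = Contig("lone", random_dna(rng, 5_000))
        result = assemble_master(contigs + [lone], find_end_overlaps(contigs + [lone]))
        assert result.unplaced == ["lone"]
        assert any(s.path == [("lone", "+")] for s in result.subgenomes)

    def test_contained_contig_excluded_but_reported(self, rng):
        genome, contigs = _chain(rng, [600, 700])
        inner = Contig("inner", genome[200:412])
        result = assemble_master(contigs + [inner],
                                 find_end_overlaps(contigs + [inner]))
        assert "inner" in result.excluded
        assert all("inner" not in [c for c, _ in s.path] for s in result.subgenomes)

    def test_circularizable_walk_reported_not_applied(self, rng):
        k = K
        core = random_dna(rng, 1_200)
        a = core[:500]
        b = core[500 - k:900]
        c = core[900 - k:] + core[:k]  # closes the circle back onto a's head
        contigs = [Contig("a", a), Contig("b", b), Contig("c", c)]
        result = assemble_master(contigs, find_end_overlaps(contigs))
        assert len(result.subgenomes) == 1
        assert result.subgenomes[0].topology == "linear"
        assert result.subgenomes[0].circularizable
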