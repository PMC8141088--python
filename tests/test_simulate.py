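import dataclasses
import filecmp
from pathlib import Path

import numpy as np
import pytest

from mitoscreen import (SimConfig, assemble_master, find_end_overlaps,
                        fragment_contigs, generate_reference, simulate,
                        write_bundle)
from mitoscreen.contigs import Contig
from mitoscreen.seqs import gc_fraction, revcomp
from mitoscreen.simulate import derive_cms, emit_panel

from conftest import random_dna


class TestReference:
    def test_same_seed_is_byte_identical(self):
        a = generate_reference(SimConfig(seed=42))
        b = generate_reference(SimConfig(seed=42))
        assert a.seq == b.seq
        assert a.genes == b.genes

    def test_gene_count_and_structure(self):
        ref = generate_reference(SimConfig(seed=3))
        assert len(ref.genes) == 20
        for g in ref.genes:
            cds = ref.cds(g.name)
            assert cds.startswith("ATG")
            assert cds[-3:] in ("TAA", "TAG", "TGA")
            assert len(cds) % 3 == 0
            assert g.promoter_end == g.start - 1

    def test_gc_fraction_within_two_points_of_target(self):
        config = SimConfig(seed=5, gc=0.44)
        ref = generate_reference(config)
        assert abs(gc_fraction(ref.seq) - config.gc) <= 0.02

    def test_infeasible_packing_raises(self):
        with pytest.raises(ValueError, match="infeasible"):
            generate_reference(SimConfig(seed=0, genome_length=20_000))


class TestDeriveCms:
    def test_no_event_keeps_genome_identical(self):
        config = SimConfig(seed=9, no_event=True)
        ref = generate_reference(config)
        derivation = derive_cms(ref, config)
        assert derivation.cms_seq == ref.seq
        assert derivation.event is None

    def test_event_length_bookkeeping(self, bundle):
        event = bundle.manifest["event"]
        assert event["replaced_len"] == event["end"] - event["start"] + 1
        assert event["recombinant_len"] == (len(bundle.reference.seq)
                                            - event["replaced_len"]
                                            + event["insert_len"])
        assert len(bundle.derivation.cms_seq) == event["recombinant_len"]

    def test_cms_differs_from_reference_by_exactly_the_event(self, bundle):
        ref = bundle.reference.seq
        cms = bundle.derivation.cms_seq
        s, e = bundle.manifest["event"]["start"], bundle.manifest["event"]["end"]
        assert cms[:s - 1] == ref[:s - 1]
        assert cms[s - 1 + len(bundle.derivation.insert_seq):] == ref[e:]
        assert cms[s - 1:s - 1 + len(bundle.derivation.insert_seq)] \
            == bundle.derivation.insert_seq

    def test_planted_flanks_shared_with_backbone(self, bundle):
        ref = bundle.reference.seq
        insert = bundle.derivation.insert_seq
        s, e = bundle.manifest["event"]["start"], bundle.manifest["event"]["end"]
        assert insert[:98] == ref[s - 1:s - 1 + 98]
        assert insert[-98:] == ref[e - 98:e]


class TestFragmentation:
    def test_single_contig_request_returns_genome(self, rng):
        genome = random_dna(rng, 10_000)
        frag = fragment_contigs(genome, SimConfig(seed=1, n_contigs=1))
        assert list(frag.contigs.values()) == [genome]

    @pytest.mark.parametrize("seed", range(5))
    def test_roundtrip_without_repeat(self, seed):
        rng = np.random.default_rng(seed)
        genome = random_dna(rng, 50_000)
        config = SimConfig(seed=seed, n_contigs=8, repeat_contig=False,
                           contained_contig=False, min_tile_len=1_000)
        frag = fragment_contigs(genome, config)
        assert frag.genome == genome
        contigs = [Contig(cid, seq) for cid, seq in frag.contigs.items()]
        result = assemble_master(contigs, find_end_overlaps(contigs))
        assert len(result.subgenomes) == 1
        assert result.subgenomes[0].seq in (genome, revcomp(genome))

    def test_repeat_flag_duplicates_one_tile(self, bundle):
        frag = bundle.fragmentation
        assert frag.repeated_id is not None
        occurrences = [cid for cid, _ in frag.path]
        assert occurrences.count(frag.repeated_id) == 2
        assert len(frag.contigs) == len(set(occurrences)) + 1  # + contained

    def test_contained_contig_is_inside_its_host(self, bundle):
        frag = bundle.fragmentation
        info = frag.contained[0]
        inner = frag.contigs[info["id"]]
        host = frag.contigs[info["outer"]]
        assert inner in host or revcomp(inner) in host
        lo, hi = info["genome_start"] - 1, info["genome_end"]
        assert frag.genome[lo:hi] in (inner, revcomp(inner))


class TestPanel:
    def test_empty_panel(self, bundle):
        config = dataclasses.replace(bundle.config, panel_size=0)
        panel, carriers = emit_panel(bundle.reference, config)
        assert panel == {} and carriers == []

    def test_carrier_genomes_contain_verbatim_copy(self, bundle):
        second = bundle.manifest["second_orf"]["nt_seq"]
        carriers = set(bundle.manifest["panel_carriers"])
        assert len(carriers) == 3
        for name, seq in bundle.panel.items():
            assert (second in seq) == (name in carriers)


class TestDeterminism:
    def test_bundles_identical_for_same_config(self):
        a = simulate(SimConfig(seed=11))
        b = simulate(SimConfig(seed=11))
        assert a.manifest == b.manifest
        assert a.derivation.cms_seq == b.derivation.cms_seq
        assert a.contigs == b.contigs
        assert a.panel == b.panel

    def test_written_bundle_is_byte_identical(self, tmp_path):
        config = SimConfig(seed=12, genome_length=100_000)
        p1 = write_bundle(simulate(config), tmp_path / "run1")
        p2 = write_bundle(simulate(config), tmp_path / "run2")
        for key in p1:
            assert filecmp.cmp(p1[key], p2[key], shallow=False), key

    def test_different_seeds_differ(self):
        a = simulate(SimConfig(seed=1))
        b = simulate(SimConfig(seed=2))
        assert a.reference.seq != b.reference.seq
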