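"""Synthetic mitogenome generator with a machine-readable truth manifest.

The generator emulates the data situation behind a CMS candidate-gene
screen, so the whole pipeline runs with no downloads:

* an annotated circular-style progenitor mitogenome (random background at a
  configured GC with non-overlapping ATG-initiated genes, each with a named
  upstream promoter region);
* a derived CMS genome created by substituting one backbone interval
  (flanked by fixed-length shared sequences) for an insert that carries a
  planted chimeric ORF — novel codons, a hydrophobic (transmembrane) block,
  a 48-nt block shared verbatim with the cox2 gene, and a long donor
  segment from an orf288-like gene at a planted identity — placed
  downstream of a captured copy of the rpl5 promoter, plus a second planted
  novel ORF;
* fragmentation of the backbone into contigs sharing exact 98-bp end
  overlaps, optionally with one repeated tile, one contained contig and
  plasmid-like contigs;
* a comparison panel of diverged genomes, some carrying verbatim copies of
  a planted ORF.

Every planted coordinate, identity and linkage is recorded in the manifest,
which is the ground truth the test-suite oracles compare against.  A single
integer seed drives independent named substreams, so identical configs give
byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .io import write_fasta, write_gff3
from .orfs import extract_orfs
from .seqs import STOP_CODONS, revcomp
from .validation import SubstitutionEvent, apply_substitution

BASES = np.frombuffer(b"ACGT", dtype=np.uint8)

SENSE_CODONS = tuple(
    a + b + c
    for a in "ACGT" for b in "ACGT" for c in "ACGT"
    if a + b + c not in STOP_CODONS
)
#: codons for strongly hydrophobic residues (Leu / Ile / Val)
HYDRO_CODONS = ("TTA", "TTG", "CTT", "CTC", "CTA", "CTG",   # Leu
                "ATT", "ATC", "ATA",                         # Ile
                "GTT", "GTC", "GTA", "GTG")                  # Val

GENE_NAMES = (
    "atp1", "atp4", "atp6", "atp8", "atp9", "cob", "cox1", "cox2", "cox3",
    "ccmFn", "ccmC", "nad1", "nad3", "nad4", "nad6", "rpl5", "rps3", "rps7",
    "matR", "orf288",
)

PANEL_NAMES = ("BT-like", "LD-like", "CW-like", "RT98-like", "RT102-like")


@dataclass
class SimConfig:
    """Study-emulating defaults; every length in bp, identities as fractions."""

    seed: int = 0
    genome_length: int = 120_000
    gc: float = 0.44
    n_genes: int = 20
    gene_aa_range: tuple[int, int] = (150, 450)
    promoter_len: int = 200
    overlap_len: int = 98
    # substitution event (the Tadukan-type CMS event scale)
    no_event: bool = False              # emit a CMS genome identical to the reference
    replaced_len: int = 17_911
    insert_len: int = 6_141
    event_start: int | None = None      # 1-based; None = seeded placement
    flank_len: int = 98
    # chimeric ORF recipe
    donor_gene: str = "orf288"
    exact_block_gene: str = "cox2"
    donor_identity: float = 0.94
    orf_aa: int = 312                   # total residues of the chimeric ORF
    tm_block_aa: tuple[int, int] = (29, 55)   # planted hydrophobic interval
    exact_block_codons: tuple[int, int] = (34, 49)  # 48-nt shared block
    donor_from_codon: int = 34          # donor segment = codons 34..orf_aa
    promoter_source: str = "rpl5"
    promoter_identity: float = 0.99
    second_orf_aa: int | None = 115
    # fragmentation
    n_contigs: int = 12
    repeat_contig: bool = True
    contained_contig: bool = True
    contained_len: int = 212
    min_tile_len: int = 2_000
    # plasmid-like molecules
    n_plasmids: int = 3
    plasmid_lengths: tuple[int, ...] = (2_135, 1_548, 969)
    plasmid_divergence: float = 0.01
    # panel
    panel_size: int = 5
    panel_divergence: float = 0.002
    panel_orf_copies: int = 3           # panel genomes carrying the second ORF verbatim
    reference_divergence: float = 0.002  # second screening reference vs progenitor

    @classmethod
    def from_yaml(cls, path) -> "SimConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass(frozen=True)
class Gene:
    name: str
    start: int  # 1-based inclusive, ATG first base
    end: int    # includes stop codon
    strand: str
    promoter_start: int
    promoter_end: int


@dataclass
class ReferenceGenome:
    seq: str
    genes: list[Gene]

    def gene(self, name: str) -> Gene:
        for g in self.genes:
            if g.name == name:
                return g
        raise KeyError(name)

    def cds(self, name: str) -> str:
        g = self.gene(name)
        return self.seq[g.start - 1:g.end]

    def promoter(self, name: str) -> str:
        g = self.gene(name)
        return self.seq[g.promoter_start - 1:g.promoter_end]

    def gene_library(self) -> dict[str, str]:
        return {g.name: self.cds(g.name) for g in self.genes}


def _random_seq(rng: np.random.Generator, n: int, gc: float) -> str:
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return BASES[rng.choice(4, size=n, p=probs)].tobytes().decode()


def _codons(rng: np.random.Generator, n: int, pool=SENSE_CODONS) -> list[str]:
    return [pool[i] for i in rng.integers(0, len(pool), size=n)]


def _mutate(seq: str, n_subs: int, rng: np.random.Generator,
            avoid: set[int] | None = None) -> tuple[str, list[int]]:
    """Plant exactly ``n_subs`` substitutions at distinct seeded positions
    (0-based), skipping ``avoid`` positions; returns (sequence, positions)."""
    avoid = avoid or set()
    out = list(seq)
    positions: list[int] = []
    guard = 0
    while len(positions) < n_subs:
        guard += 1
        if guard > 50 * n_subs + 1000:
            raise RuntimeError("could not place substitutions")
        pos = int(rng.integers(0, len(seq)))
        if pos in avoid or pos in positions:
            continue
        alternatives = [b for b in "ACGT" if b != out[pos]]
        out[pos] = alternatives[int(rng.integers(0, 3))]
        positions.append(pos)
    return "".join(out), sorted(positions)


# ---------------------------------------------------------------------------
# reference genome


def generate_reference(config: SimConfig,
                       rng: np.random.Generator | None = None) -> ReferenceGenome:
    """Random annotated progenitor mitogenome, deterministic under the seed.

    Genes are ATG-initiated, built from sense codons of the universal code
    (so they are real ORFs of the configured lengths), placed without
    overlap, each annotated with an upstream promoter region.  The cox2 and
    orf288-like genes share a planted 48-nt hydrophobic block, mirroring the
    cox2-exon fragment carried by known CMS chimeras.
    """
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence(config.seed).spawn(5)[0])
    L = config.genome_length
    background = _random_seq(rng, L, config.gc)
    n = config.n_genes
    names = [GENE_NAMES[i % len(GENE_NAMES)] + ("" if i < len(GENE_NAMES) else f"_{i}")
             for i in range(n)]

    aa_counts = {name: int(rng.integers(config.gene_aa_range[0],
                                        config.gene_aa_range[1] + 1))
                 for name in names}
    lo_aa, hi_aa = config.exact_block_codons
    block16 = "".join(_codons(rng, hi_aa - lo_aa + 1, HYDRO_CODONS))
    gene_seqs = {}
    for name in names:
        aa = max(aa_counts[name], config.orf_aa + 2 if name == config.donor_gene else 0)
        for _ in range(100):
            codons = _codons(rng, aa - 1)
            if name == config.donor_gene:
                # hydrophobic block with the exact cox2-shared core
                tm_lo, tm_hi = config.tm_block_aa
                hydro = _codons(rng, tm_hi - tm_lo + 1, HYDRO_CODONS)
                for k, ci in enumerate(range(tm_lo, tm_hi + 1)):
                    codons[ci - 2] = hydro[k]       # codons[0] is residue 2
                for k, ci in enumerate(range(lo_aa, hi_aa + 1)):
                    codons[ci - 2] = block16[3 * k:3 * k + 3]
            if name == config.exact_block_gene:
                for k, ci in enumerate(range(10, 10 + (hi_aa - lo_aa + 1))):
                    codons[ci - 2] = block16[3 * k:3 * k + 3]
            seq = "ATG" + "".join(codons) + ("TAA", "TAG", "TGA")[int(rng.integers(0, 3))]
            if name != config.donor_gene:
                break
            # the donor gene seeds the chimera: it must not itself nest a
            # second ORF above the screen threshold (any frame or strand),
            # or the derived chimera would carry an unplanted candidate
            nested = [r for r in extract_orfs(seq, min_aa=70)
                      if not (r.start == 1 and r.end == len(seq) and r.strand == "+")]
            if not nested:
                break
        else:
            raise RuntimeError("could not draw a donor gene free of nested ORFs")
        gene_seqs[name] = seq

    # guard: the shared block must not extend by chance on the cox2 side
    donor_codons = gene_seqs[config.donor_gene]
    left_nb = donor_codons[3 * (lo_aa - 1) - 1]       # base before the block in donor
    right_nb = donor_codons[3 * hi_aa]                # base after the block in donor
    cox = list(gene_seqs[config.exact_block_gene])
    blk0 = 3 * 9  # block starts at codon 10 -> 0-based nt 27
    while cox[blk0 - 1] == left_nb:
        cox[blk0 - 3:blk0] = _codons(rng, 1)[0]
    while cox[blk0 + len(block16)] == right_nb:
        cox[blk0 + len(block16):blk0 + len(block16) + 3] = _codons(rng, 1)[0]
    gene_seqs[config.exact_block_gene] = "".join(cox)

    genome = bytearray(background.encode())
    genes: list[Gene] = []
    block = L // n
    for i, name in enumerate(names):
        seq = gene_seqs[name]
        start_min = i * block + 150 + config.promoter_len
        start_max = (i + 1) * block - len(seq) - 150
        if start_max < start_min:
            raise ValueError("infeasible packing: genes exceed genome")
        start = int(rng.integers(start_min, start_max + 1)) + 1  # 1-based
        genome[start - 1:start - 1 + len(seq)] = seq.encode()
        genes.append(Gene(name, start, start + len(seq) - 1, "+",
                          start - config.promoter_len, start - 1))
    return ReferenceGenome(seq=genome.decode(), genes=genes)


# ---------------------------------------------------------------------------
# CMS derivation


@dataclass
class CmsDerivation:
    cms_seq: str
    insert_seq: str
    event: SubstitutionEvent | None
    chimera: dict | None
    second_orf: dict | None
    promoter: dict | None


def _build_chimeric_orf(reference: ReferenceGenome, config: SimConfig,
                        rng: np.random.Generator) -> tuple[str, dict]:
    """Assemble the planted chimeric ORF and its truth description."""
    donor_cds = reference.cds(config.donor_gene)
    cox_cds = reference.cds(config.exact_block_gene)
    tm_lo, tm_hi = config.tm_block_aa
    lo_aa, hi_aa = config.exact_block_codons
    d0 = config.donor_from_codon

    novel = _codons(rng, d0 - 2)                      # residues 2 .. d0-1
    cox_before = cox_cds[3 * 9 - 1]
    for ci in range(tm_lo, min(tm_hi, d0 - 1) + 1):
        # hydrophobic, but >= 2 bases away from the donor's codon at the
        # same position so local alignment cannot blur the planted
        # breakpoint; codon d0-1 additionally must not extend the exact
        # cox2-shared block by one base
        donor_codon = donor_cds[3 * (ci - 1):3 * ci]
        forbidden_last = cox_before if ci == d0 - 1 else None
        for _ in range(200):
            cand = _codons(rng, 1, HYDRO_CODONS)[0]
            if sum(a != b for a, b in zip(cand, donor_codon)) >= 2 and \
                    (forbidden_last is None or cand[2] != forbidden_last):
                novel[ci - 2] = cand
                break
        else:
            raise RuntimeError("could not draw a divergent hydrophobic codon")

    donor_fragment = donor_cds[3 * (d0 - 1): 3 * config.orf_aa]  # codons d0..orf_aa
    n_subs = int(round((1 - config.donor_identity) * len(donor_fragment)))
    protect = set(range(0, 3 * (tm_hi - d0 + 1)))  # keep TM + exact block pristine
    frag = donor_fragment
    for _ in range(200):
        frag, sub_pos = _mutate(donor_fragment, n_subs, rng, avoid=protect)
        codons = [frag[i:i + 3] for i in range(0, len(frag), 3)]
        if not any(c in STOP_CODONS for c in codons):
            break
    else:
        raise RuntimeError("substitution placement kept producing stop codons")

    stop = ("TAA", "TAG", "TGA")[int(rng.integers(0, 3))]
    orf_nt = "ATG" + "".join(novel) + frag + stop
    assert len(orf_nt) == 3 * (config.orf_aa + 1)

    identity = round(100.0 * (len(donor_fragment) - n_subs) / len(donor_fragment), 2)
    truth = {
        "aa_len": config.orf_aa,
        "nt_len": len(orf_nt),
        "tm_interval_aa": [tm_lo, tm_hi],
        "donor_segment": {
            "donor": config.donor_gene,
            "query_nt": [3 * (d0 - 1) + 1, 3 * config.orf_aa],
            "donor_nt": [3 * (d0 - 1) + 1, 3 * config.orf_aa],
            "identity_pct": identity,
            "n_substitutions": n_subs,
        },
        "exact_block": {
            "donor": config.exact_block_gene,
            "query_nt": [3 * (lo_aa - 1) + 1, 3 * hi_aa],
            "donor_nt": [3 * 9 + 1, 3 * 9 + 3 * (hi_aa - lo_aa + 1)],
            "length": 3 * (hi_aa - lo_aa + 1),
        },
    }
    return orf_nt, truth


def _disrupt_inframe_atgs(promoter_copy: str) -> str:
    """Remove ATGs that are in frame with (and unbroken by a stop before)
    the downstream start codon; scanned backwards from the promoter end."""
    out = list(promoter_copy)
    P = len(out)
    for k in range(1, P // 3 + 1):
        codon = "".join(out[P - 3 * k:P - 3 * k + 3])
        if codon in STOP_CODONS:
            break
        if codon == "ATG":
            out[P - 3 * k + 1] = "C"  # ATG -> ACG (Thr, not a stop)
    return "".join(out)


def _plant_stop(seq: list, p: int, strand: str, free, coding) -> bool:
    """Try to write a stop codon for an ORF of the given strand whose codon
    occupies seq[p:p+3].

    Positions in a ``free`` interval take any stop directly.  Positions in a
    ``coding`` region (a planted ORF) may only change bases that keep every
    overlapped frame-0 codon of that region a sense codon, and never touch
    its protected sub-intervals.
    """
    stops = ("TAA", "TAG", "TGA") if strand == "+" else ("TTA", "CTA", "TCA")
    if any(lo <= p and p + 3 <= hi for lo, hi in free):
        seq[p:p + 3] = stops[0]
        return True
    for lo, hi, protected in coding:
        if not (lo <= p and p + 3 <= hi):
            continue
        if any(q_lo <= p + 2 and p <= q_hi for q_lo, q_hi in protected):
            return False
        current = "".join(seq[p:p + 3])
        for stop in sorted(stops, key=lambda s: sum(a != b for a, b in
                                                    zip(s, current))):
            trial = seq[p:p + 3]
            seq[p:p + 3] = stop
            ok = True
            for ci in range((p - lo) // 3, (p + 2 - lo) // 3 + 1):
                codon = "".join(seq[lo + 3 * ci:lo + 3 * ci + 3])
                if codon in STOP_CODONS:
                    ok = False
                    break
            if ok:
                return True
            seq[p:p + 3] = trial
        return False
    return False


def _break_incidental_orfs(insert: str, planted_spans: set, free, coding,
                           reference) -> str | None:
    """Disrupt every incidental novel ORF of the insert by planting a stop
    codon in the offender's own reading frame.

    The stop goes into spacer sequence (``free``) when the offender reaches
    one, otherwise into a planted ORF's editable codons (``coding``), where
    the edit must keep the planted frame sense.  Returns the repaired
    insert, or None when an offender cannot be disrupted (caller redraws).
    Exact copies of reference sequence are left alone: the screen discards
    them as common.
    """
    seq = list(insert)
    for _ in range(60):
        recs = extract_orfs("".join(seq), min_aa=70, molecule_id="insert")
        offenders = []
        planted_seen = set()
        for rec in recs:
            span = (rec.start, rec.end, rec.strand)
            if span in planted_spans:
                planted_seen.add(span)
                continue
            if rec.nt_seq in reference.seq or revcomp(rec.nt_seq) in reference.seq:
                continue
            offenders.append(rec)
        if not offenders:
            return "".join(seq) if planted_seen == planted_spans else None
        rec = offenders[0]
        placed = False
        lo0 = rec.start - 1
        n_codons = (rec.end - rec.start + 1) // 3
        # scan codon-aligned positions inside-out so the stop lands away
        # from the ORF ends (a stop near an end leaves a long live piece)
        order = sorted(range(1, n_codons - 1),
                       key=lambda c: abs(c - n_codons // 2))
        for ci in order:
            p = lo0 + 3 * ci if rec.strand == "+" else rec.end - 3 * ci - 3
            if _plant_stop(seq, p, rec.strand, free, coding):
                placed = True
                break
        if not placed:
            return None
    return None


def derive_cms(reference: ReferenceGenome, config: SimConfig,
               rng: np.random.Generator | None = None,
               avoid_intervals: tuple[tuple[int, int], ...] = ()) -> CmsDerivation:
    """Create the CMS genome by one substitution event with planted content.

    The insert is [shared 98-bp left flank | spacer | captured promoter |
    chimeric ORF | spacer | second novel ORF | spacer | shared 98-bp right
    flank].  Random spacer/novel sequence is redrawn (bounded retries) if it
    happens to create an extra >= 70-aa ORF absent from the reference, so
    the planted ORFs are exactly the novel ones — the condition the screen
    is meant to detect.
    """
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence(config.seed).spawn(5)[1])
    if config.no_event:
        return CmsDerivation(cms_seq=reference.seq, insert_seq="", event=None,
                             chimera=None, second_orf=None, promoter=None)
    L = len(reference.seq)
    margin = 2_000
    if config.event_start is not None:
        s = config.event_start
    else:
        # the replaced interval must not touch duplicated regions, or the
        # junction flanks would anchor ambiguously on the backbone
        for _ in range(500):
            s = int(rng.integers(margin, L - margin - config.replaced_len))
            if all(hi < s or lo > s + config.replaced_len - 1
                   for lo, hi in avoid_intervals):
                break
        else:
            raise RuntimeError("could not place the substitution event clear "
                               "of the avoid intervals")
    e = s + config.replaced_len - 1
    if not (1 <= s <= e <= L):
        raise ValueError("substitution event does not fit the genome")
    fl = config.flank_len
    left_flank = reference.seq[s - 1:s - 1 + fl]
    right_flank = reference.seq[e - fl:e]

    promoter_ref = reference.promoter(config.promoter_source)
    n_prom_subs = int((1 - config.promoter_identity) * len(promoter_ref))
    promoter_copy, _ = _mutate(promoter_ref, n_prom_subs, rng)
    # the captured promoter sits directly upstream of the planted start
    # codon; an in-frame upstream ATG with no intervening stop would shift
    # the reported ORF start, so any such ATG in the copy is disrupted (and
    # counted as part of the planted divergence)
    promoter_copy = _disrupt_inframe_atgs(promoter_copy)
    prom_pos = [i for i, (a, b) in enumerate(zip(promoter_ref, promoter_copy))
                if a != b]
    n_prom_subs = len(prom_pos)
    # positions relative to the captured ORF's start codon (negative upstream)
    prom_rel_positions = [p - len(promoter_ref) for p in prom_pos]

    for attempt in range(10):
        orf_nt, chimera_truth = _build_chimeric_orf(reference, config, rng)
        second_nt = ""
        if config.second_orf_aa:
            second_nt = ("ATG" + "".join(_codons(rng, config.second_orf_aa - 1))
                         + ("TAA", "TAG", "TGA")[int(rng.integers(0, 3))])
        fixed = fl + 800 + len(promoter_copy) + len(orf_nt) + len(second_nt) + 400 + fl
        sp2 = config.insert_len - fixed
        if sp2 < 50:
            raise ValueError("insert_len too small for the configured recipe")
        parts = [left_flank, _random_seq(rng, 800, config.gc), promoter_copy,
                 orf_nt, _random_seq(rng, sp2, config.gc), second_nt,
                 _random_seq(rng, 400, config.gc), right_flank]
        insert = "".join(parts)
        assert len(insert) == config.insert_len

        # spacer intervals (0-based half-open) may be edited freely to break
        # incidental ORFs; inside the planted ORFs only sense-preserving
        # edits outside the protected blocks are allowed
        lens = [len(p) for p in parts]
        starts = np.concatenate(([0], np.cumsum(lens)))
        free = [(int(starts[i]), int(starts[i + 1])) for i in (1, 4, 6)]
        orf_lo = int(starts[3])      # 0-based start of the chimeric ORF
        sec_lo = int(starts[5])
        orf_hi = orf_lo + len(orf_nt)
        coding = [(orf_lo, orf_hi,
                   [(orf_lo, orf_lo + 2),                      # ATG
                    (orf_lo + 84, orf_lo + 164),               # TM + shared block
                    (orf_hi - 3, orf_hi - 1)])]                # stop
        planted_spans = {(orf_lo + 1, orf_hi, "+")}
        if second_nt:
            sec_hi = sec_lo + len(second_nt)
            coding.append((sec_lo, sec_hi,
                           [(sec_lo, sec_lo + 2), (sec_hi - 3, sec_hi - 1)]))
            planted_spans.add((sec_lo + 1, sec_hi, "+"))

        insert = _break_incidental_orfs(insert, planted_spans, free, coding,
                                        reference)
        if insert is not None:
            break
    else:
        raise RuntimeError("could not realise an insert whose only novel ORFs "
                           "are the planted ones")

    orf_start_in_insert = orf_lo + 1  # 1-based
    second_start_in_insert = sec_lo + 1
    event = SubstitutionEvent("reference", s, e, "insert",
                              left_flank=fl, right_flank=fl)
    cms_seq = apply_substitution(reference.seq, event, insert)

    # ORF-repair edits may have touched the donor-derived region; the truth
    # records the identity actually realised in the emitted sequence
    orf_nt = insert[orf_lo:orf_hi]
    second_nt = insert[sec_lo:sec_lo + len(second_nt)] if second_nt else ""
    donor_cds = reference.cds(config.donor_gene)
    q_lo, q_hi = chimera_truth["donor_segment"]["query_nt"]
    realised = insert[orf_lo + q_lo - 1:orf_lo + q_hi]
    template = donor_cds[q_lo - 1:q_hi]
    n_subs = sum(a != b for a, b in zip(realised, template))
    chimera_truth["donor_segment"]["n_substitutions"] = n_subs
    chimera_truth["donor_segment"]["identity_pct"] = round(
        100.0 * (len(template) - n_subs) / len(template), 2)

    chimera_truth.update({
        "nt_seq": orf_nt,
        "insert_start": orf_start_in_insert,
        "insert_end": orf_start_in_insert + len(orf_nt) - 1,
        "cms_start": s - 1 + orf_start_in_insert,
        "cms_end": s - 1 + orf_start_in_insert + len(orf_nt) - 1,
    })
    second_truth = None
    if second_nt:
        second_truth = {
            "aa_len": config.second_orf_aa,
            "nt_seq": second_nt,
            "insert_start": second_start_in_insert,
            "insert_end": second_start_in_insert + len(second_nt) - 1,
        }
    promoter_truth = {
        "source_gene": config.promoter_source,
        "length": len(promoter_ref),
        "identity_pct": round(100.0 * (len(promoter_ref) - n_prom_subs)
                              / len(promoter_ref), 2),
        "diff_positions_from_start_codon": prom_rel_positions,
        "insert_start": fl + 800 + 1,
        "insert_end": fl + 800 + len(promoter_copy),
    }
    return CmsDerivation(cms_seq=cms_seq, insert_seq=insert, event=event,
                         chimera=chimera_truth, second_orf=second_truth,
                         promoter=promoter_truth)


# ---------------------------------------------------------------------------
# fragmentation into overlap contigs


@dataclass
class Fragmentation:
    genome: str                      # the tiled molecule (rebuilt if a tile repeats)
    contigs: dict[str, str]          # id -> sequence as emitted (random orientation)
    path: list[tuple[str, str]]      # true tiling order with emitted orientation
    joins: set[tuple[tuple[str, str], tuple[str, str]]]
    repeated_id: str | None
    contained: list[dict]
    rebuild: dict | None = None      # replaced/duplicated intervals if a tile repeats


def fragment_contigs(genome: str, config: SimConfig,
                     rng: np.random.Generator | None = None,
                     protect: tuple[tuple[int, int], ...] = ()) -> Fragmentation:
    """Tile a molecule into contigs with exact ``overlap_len``-bp junctions.

    With ``repeat_contig`` one interior tile is duplicated (the molecule is
    rebuilt so the same contig genuinely occurs at two positions; the tile
    that gets overwritten never intersects a ``protect`` interval); with
    ``contained_contig`` an extra contig fully inside another is added.
    Emitted contigs are randomly strand-flipped, as assembler output would
    be; the truth path records the orientations.
    """
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence(config.seed).spawn(5)[2])
    k = config.overlap_len
    n = config.n_contigs
    L = len(genome)
    if n < 1 or L < n * (config.min_tile_len // 2):
        raise ValueError("genome too short for the requested contig count")
    if n == 1:
        contigs = {"contig_01": genome}
        return Fragmentation(genome, contigs, [("contig_01", "+")], set(), None, [])

    for _ in range(200):
        cuts = sorted(int(c) for c in rng.integers(1, L - k, size=n - 1))
        bounds = [0] + cuts + [L - k]
        if all(b - a >= config.min_tile_len for a, b in zip(bounds, bounds[1:])):
            break
    else:
        raise RuntimeError("could not draw tile boundaries with the minimum spacing")

    ids = [f"contig_{i:02d}" for i in range(1, n + 1)]
    rebuild = None
    if config.repeat_contig and n >= 5:
        for _ in range(500):
            j = int(rng.integers(1, n - 3))          # 0-based tile index, interior
            m = int(rng.integers(j + 2, n - 1))      # non-adjacent interior target
            r_lo, r_hi = bounds[m] + 1, bounds[m + 1] + k  # 1-based replaced interval
            if all(hi < r_lo or lo > r_hi for lo, hi in protect):
                break
        else:
            raise RuntimeError("could not choose a repeat target clear of "
                               "protected intervals")
        tile_j = genome[bounds[j]:bounds[j + 1] + k]
        delta = len(tile_j) - (bounds[m + 1] + k - bounds[m])
        genome = genome[:bounds[m]] + tile_j + genome[bounds[m + 1] + k:]
        bounds = bounds[:m + 1] + [b + delta for b in bounds[m + 1:]]
        L = len(genome)
        repeated_id = ids[j]
        ids[m] = ids[j]
        rebuild = {
            "replaced_start": r_lo, "replaced_end": r_hi, "delta": delta,
            "source_interval": [bounds[j] + 1, bounds[j + 1] + k],
            "copy_interval": [bounds[m] + 1, bounds[m] + len(tile_j)],
        }
    else:
        repeated_id = None

    orient = {cid: ("+", "-")[int(rng.integers(0, 2))] for cid in dict.fromkeys(ids)}
    contigs: dict[str, str] = {}
    path: list[tuple[str, str]] = []
    for i, cid in enumerate(ids):
        tile = genome[bounds[i]:bounds[i + 1] + k]
        if cid in contigs:
            assert contigs[cid] in (tile, revcomp(tile))
        else:
            contigs[cid] = tile if orient[cid] == "+" else revcomp(tile)
        path.append((cid, orient[cid]))

    joins: set = set()
    for (a_id, ao), (b_id, bo) in zip(path, path[1:]):
        join = ((a_id, ao), (b_id, bo))
        twin = ((b_id, "-" if bo == "+" else "+"), (a_id, "-" if ao == "+" else "+"))
        joins.add(join)
        joins.add(twin)

    contained: list[dict] = []
    if config.contained_contig and n >= 3:
        host_idx = 1
        host_id = ids[host_idx]
        lo = bounds[host_idx] + 10
        hi = bounds[host_idx + 1] + k - config.contained_len - 10
        pos = int(rng.integers(lo, hi))
        inner = genome[pos:pos + config.contained_len]
        cid = "contig_sub"
        contigs[cid] = inner if rng.integers(0, 2) == 0 else revcomp(inner)
        contained.append({"id": cid, "outer": host_id,
                          "genome_start": pos + 1,
                          "genome_end": pos + config.contained_len})
    return Fragmentation(genome, contigs, path, joins, repeated_id, contained,
                         rebuild)


# ---------------------------------------------------------------------------
# panel + plasmids + full bundle


def _diverged(seq: str, rate: float, rng: np.random.Generator) -> str:
    n = int(rate * len(seq))
    return _mutate(seq, n, rng)[0] if n else seq


def _largest_intergenic_midpoint(reference: ReferenceGenome) -> int:
    """0-based midpoint of the widest gap between annotated regions."""
    marks = sorted((g.promoter_start - 1, g.end) for g in reference.genes)
    gaps = [(0, marks[0][0])]
    for (a_lo, a_hi), (b_lo, b_hi) in zip(marks, marks[1:]):
        gaps.append((a_hi, b_lo))
    gaps.append((marks[-1][1], len(reference.seq)))
    lo, hi = max(gaps, key=lambda g: g[1] - g[0])
    return (lo + hi) // 2


def emit_panel(reference: ReferenceGenome, config: SimConfig,
               rng: np.random.Generator | None = None,
               copy_orf: str = "") -> tuple[dict[str, str], list[str]]:
    """Diverged comparison genomes; the first ``panel_orf_copies`` carry a
    verbatim copy of ``copy_orf`` at a seeded intergenic position."""
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence(config.seed).spawn(5)[3])
    panel: dict[str, str] = {}
    carriers: list[str] = []
    for i in range(config.panel_size):
        name = PANEL_NAMES[i % len(PANEL_NAMES)] + ("" if i < len(PANEL_NAMES) else str(i))
        seq = _diverged(reference.seq, config.panel_divergence, rng)
        if copy_orf and i < config.panel_orf_copies:
            pos = _largest_intergenic_midpoint(reference)
            seq = seq[:pos] + copy_orf + seq[pos:]
            carriers.append(name)
        panel[name] = seq
    return panel, carriers


@dataclass
class SimBundle:
    config: SimConfig
    reference: ReferenceGenome
    screen_references: dict[str, str]
    derivation: CmsDerivation
    fragmentation: Fragmentation
    contigs: dict[str, str]          # tiles + insert + contained + plasmid-like
    plasmid_refs: dict[str, str]
    panel: dict[str, str]
    manifest: dict


def _rebuild_reference(ref0: ReferenceGenome, frag: Fragmentation) -> ReferenceGenome:
    """Reference annotation after a duplicated-tile rebuild: genes inside the
    overwritten interval are dropped, later genes shift by the length delta."""
    if frag.rebuild is None:
        return ReferenceGenome(frag.genome, list(ref0.genes))
    r_lo, r_hi = frag.rebuild["replaced_start"], frag.rebuild["replaced_end"]
    delta = frag.rebuild["delta"]
    genes = []
    for g in ref0.genes:
        if g.end < r_lo and g.promoter_start < r_lo:
            genes.append(g)
        elif g.promoter_start > r_hi:
            genes.append(Gene(g.name, g.start + delta, g.end + delta, g.strand,
                              g.promoter_start + delta, g.promoter_end + delta))
        # genes overlapping the overwritten interval are gone
    return ReferenceGenome(frag.genome, genes)


def simulate(config: SimConfig) -> SimBundle:
    """Run the full generator: reference, CMS genome, contigs, panel, truth.

    The tiled molecule (including any duplicated tile) *is* the progenitor
    backbone: contigs reassemble to exactly the reference, and the CMS genome
    differs from it by exactly the substitution event — the relationship the
    screen is designed to detect.
    """
    streams = [np.random.default_rng(s)
               for s in np.random.SeedSequence(config.seed).spawn(5)]
    rng_ref, rng_cms, rng_frag, rng_panel, rng_extra = streams

    ref0 = generate_reference(config, rng_ref)
    protected = []
    for name in (config.donor_gene, config.exact_block_gene, config.promoter_source):
        g = ref0.gene(name)
        protected.append((g.promoter_start, g.end))
    fragmentation = fragment_contigs(ref0.seq, config, rng_frag,
                                     protect=tuple(protected))
    reference = _rebuild_reference(ref0, fragmentation)
    avoid = ()
    if fragmentation.rebuild is not None:
        avoid = (tuple(fragmentation.rebuild["source_interval"]),
                 tuple(fragmentation.rebuild["copy_interval"]))
    derivation = derive_cms(reference, config, rng_cms, avoid_intervals=avoid)

    contigs = dict(fragmentation.contigs)
    if derivation.event is not None:
        contigs["contig_ins"] = derivation.insert_seq

    plasmid_refs: dict[str, str] = {}
    plasmid_truth: dict[str, dict] = {}
    for i in range(config.n_plasmids):
        name = f"B{(1, 2, 4)[i % 3]}-like" if i < 3 else f"P{i}-like"
        length = config.plasmid_lengths[i % len(config.plasmid_lengths)]
        plasmid_refs[name] = _random_seq(rng_extra, length, config.gc)
        rot = int(rng_extra.integers(0, length))
        doubled = plasmid_refs[name] + plasmid_refs[name]
        copy = doubled[rot:rot + length]
        n_subs = int(config.plasmid_divergence * length)
        copy, _ = _mutate(copy, n_subs, rng_extra)
        cid = f"contig_{name.split('-')[0]}"
        contigs[cid] = copy
        plasmid_truth[cid] = {
            "ref": name,
            "identity_pct": round(100.0 * (length - n_subs) / length, 2),
        }

    second_orf_nt = derivation.second_orf["nt_seq"] if derivation.second_orf else ""
    panel, carriers = emit_panel(reference, config, rng_panel, copy_orf=second_orf_nt)

    screen_refs = {"nipponbare_like": reference.seq}
    if config.reference_divergence:
        screen_refs["wa_maintainer_like"] = _diverged(
            reference.seq, config.reference_divergence, rng_extra)

    manifest = {
        "config": config.to_dict(),
        "genes": [dataclasses.asdict(g) for g in reference.genes],
        "event": None if derivation.event is None else {
            "start": derivation.event.start,
            "end": derivation.event.end,
            "replaced_len": derivation.event.replaced_len,
            "insert_len": len(derivation.insert_seq),
            "flank_len": config.flank_len,
            "recombinant_len": len(derivation.cms_seq),
        },
        "chimera": None if derivation.chimera is None else {
            key: val for key, val in derivation.chimera.items() if key != "nt_seq"},
        "chimera_nt": derivation.chimera["nt_seq"] if derivation.chimera else None,
        "second_orf": derivation.second_orf,
        "promoter": derivation.promoter,
        "fragmentation": {
            "path": [list(step) for step in fragmentation.path],
            "joins": sorted([list(a), list(b)] for a, b in fragmentation.joins),
            "repeated_id": fragmentation.repeated_id,
            "contained": fragmentation.contained,
            "genome_len": len(fragmentation.genome),
        },
        "plasmid_like": plasmid_truth,
        "panel_carriers": carriers,
    }
    return SimBundle(config=config, reference=reference,
                     screen_references=screen_refs, derivation=derivation,
                     fragmentation=fragmentation, contigs=contigs,
                     plasmid_refs=plasmid_refs, panel=panel, manifest=manifest)


def write_bundle(bundle: SimBundle, outdir) -> dict[str, Path]:
    """Emit FASTA/GFF3/JSON artefacts; byte-identical for identical configs."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "reference": outdir / "reference.fasta",
        "reference_gff3": outdir / "reference.gff3",
        "genes": outdir / "genes.fasta",
        "cms": outdir / "cms.fasta",
        "contigs": outdir / "contigs.fasta",
        "plasmids": outdir / "plasmids.fasta",
        "screen_refs": outdir / "screen_references.fasta",
        "truth": outdir / "truth.json",
    }
    write_fasta(paths["reference"], {"reference": bundle.reference.seq})
    feats = []
    for g in bundle.reference.genes:
        feats.append({"type": "CDS", "start": g.start, "end": g.end,
                      "strand": g.strand, "attributes": {"ID": g.name, "Name": g.name}})
        feats.append({"type": "promoter", "start": g.promoter_start,
                      "end": g.promoter_end, "strand": g.strand,
                      "attributes": {"ID": f"{g.name}_promoter", "Parent": g.name}})
    write_gff3(paths["reference_gff3"], "reference", feats)
    write_fasta(paths["genes"], bundle.reference.gene_library())
    write_fasta(paths["cms"], {"cms": bundle.derivation.cms_seq})
    write_fasta(paths["contigs"], bundle.contigs)
    write_fasta(paths["plasmids"], bundle.plasmid_refs)
    write_fasta(paths["screen_refs"], bundle.screen_references)
    panel_dir = outdir / "panel"
    panel_dir.mkdir(exist_ok=True)
    for name, seq in bundle.panel.items():
        p = panel_dir / f"{name}.fasta"
        write_fasta(p, {name: seq})
        paths[f"panel/{name}"] = p
    with open(paths["truth"], "w") as fh:
        json.dump(bundle.manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return paths
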