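"""End-to-end candidate screen: assemble, screen, annotate, predict, validate.

The orchestration mirrors how a CMS candidate gene is actually pinned down:

1. assemble subgenomes from overlap contigs (plasmid-like and contained
   contigs set aside);
2. extract ORFs (>= 70 aa) from every assembled molecule and discard the
   ones >99% identical to the reference mitogenomes;
3. score the survivors across a comparison panel of other CMS cytoplasms;
4. decompose each candidate into donor-gene segments, find exactly shared
   blocks, locate a captured promoter, and predict transmembrane helices;
5. if the candidate molecule's ends anchor inside the main subgenome,
   reconstruct the implied recombinant structure and predict the Southern
   fragments and linkage-PCR products that would validate it.

Every stage's output is persisted; the consolidated JSON report is
deterministic for a given config, so re-runs are byte-identical.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

from . import __version__
from .chimera import annotate_segments, compare_flanking, longest_exact_match
from .contigs import (Contig, anchor_end_to_molecule, as_contigs, assemble_master,
                      classify_plasmid_like, detect_contained, find_end_overlaps)
from .io import read_fasta, read_gff3, write_fasta, write_gff3, write_tsv
from .orfs import extract_orfs, filter_specific, presence_absence
from .seqs import revcomp
from .tm import predict_tm
from .validation import (ENZYMES, SubstitutionEvent, apply_substitution,
                         insilico_pcr, southern_prediction)

logger = logging.getLogger(__name__)


@dataclass
class ScreenConfig:
    """Paths and thresholds of one screen run.

    Threshold defaults are the standard screen settings: 70-aa ORF floor,
    >99% identity discard rule, 98-bp contig end overlaps, 99% plasmid-like
    identity.
    """

    contigs: str = ""
    references: str = ""            # multi-FASTA of screening reference genomes
    gene_library: str = ""          # FASTA, one record per known gene
    plasmid_refs: str | None = None
    panel: str | None = None        # multi-FASTA (one record per panel genome)
    reference_fasta: str | None = None   # for promoter-capture comparison
    reference_gff3: str | None = None
    outdir: str = "screen_out"
    min_orf_aa: int = 70
    common_identity_pct: float = 99.0
    min_coverage: float = 0.95
    overlap_len: int = 98
    plasmid_identity_pct: float = 99.0
    max_copies_per_contig: int = 2
    tm_threshold: float = 1.6
    tm_window: int = 19
    tm_min_len: int = 18
    promoter_window: int = 200
    orf_convention: str = "atg"
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "ScreenConfig":
        import yaml
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)


REPORT_REQUIRED_KEYS = ("tool", "parameters", "assembly", "orf_counts", "candidates")
CANDIDATE_REQUIRED_KEYS = ("name", "molecule", "start", "end", "strand", "aa_len",
                           "specificity", "presence", "unique", "segments",
                           "longest_exact_blocks", "tm_helices")


def validate_report(report: dict) -> None:
    """Light schema check: every consolidated report must carry these keys."""
    for key in REPORT_REQUIRED_KEYS:
        if key not in report:
            raise ValueError(f"report missing required key {key!r}")
    for cand in report["candidates"]:
        for key in CANDIDATE_REQUIRED_KEYS:
            if key not in cand:
                raise ValueError(f"candidate entry missing required key {key!r}")


def run_screen(config: ScreenConfig) -> dict:
    """File-based entry point: read inputs, run the screen, persist outputs."""
    for required in ("contigs", "references", "gene_library"):
        path = getattr(config, required)
        if not path or not Path(path).exists():
            raise FileNotFoundError(f"config.{required} missing or does not exist: {path!r}")
    contigs = read_fasta(config.contigs)
    references = read_fasta(config.references)
    gene_library = read_fasta(config.gene_library)
    plasmid_refs = read_fasta(config.plasmid_refs) if config.plasmid_refs else {}
    panel = read_fasta(config.panel) if config.panel else None
    ref_genome = read_fasta(config.reference_fasta) if config.reference_fasta else None
    ref_feats = read_gff3(config.reference_gff3) if config.reference_gff3 else None

    report = screen_objects(contigs, references, gene_library,
                            plasmid_refs=plasmid_refs, panel=panel,
                            ref_genome=(next(iter(ref_genome.values()))
                                        if ref_genome else None),
                            ref_features=ref_feats, config=config,
                            outdir=Path(config.outdir))
    return report


def screen_objects(contigs: dict[str, str], references: dict[str, str],
                   gene_library: dict[str, str], *,
                   plasmid_refs: dict[str, str] | None = None,
                   panel: dict[str, str] | None = None,
                   ref_genome: str | None = None,
                   ref_features: list[dict] | None = None,
                   config: ScreenConfig | None = None,
                   outdir: Path | None = None) -> dict:
    """In-memory core of the screen; ``outdir=None`` skips persistence."""
    cfg = config or ScreenConfig()
    contig_objs = as_contigs(contigs)

    # --- stage 1: classify, link, assemble -------------------------------
    plasmid_calls = classify_plasmid_like(contig_objs, plasmid_refs or {},
                                          min_identity_pct=cfg.plasmid_identity_pct)
    plasmid_ids = {c.contig_id for c in plasmid_calls if c.verdict == "plasmid_like"}
    containments = detect_contained(contig_objs)
    linkages = find_end_overlaps(contig_objs, overlap_len=cfg.overlap_len)
    asm = assemble_master(contig_objs, linkages,
                          max_copies_per_contig=cfg.max_copies_per_contig,
                          exclude=plasmid_ids)
    logger.info("assembled %d subgenome(s); %d unplaced, %d excluded",
                len(asm.subgenomes), len(asm.unplaced), len(asm.excluded))

    # --- stage 2: ORFs + specificity -------------------------------------
    all_orfs = []
    for sub in asm.subgenomes:
        all_orfs.extend(extract_orfs(sub.seq, min_aa=cfg.min_orf_aa,
                                     molecule_id=sub.id,
                                     convention=cfg.orf_convention))
    from .orfs import assign_names
    all_orfs = assign_names(all_orfs)
    spec_results = filter_specific(all_orfs, references,
                                   identity_threshold_pct=cfg.common_identity_pct,
                                   min_coverage=cfg.min_coverage)
    specific = [r for r in spec_results if r.verdict == "specific"]
    logger.info("%d ORFs extracted; %d specific", len(all_orfs), len(specific))

    # --- stage 3: presence/absence across the panel ----------------------
    if panel:
        specific = presence_absence(specific, panel)
        presence_state = "evaluated"
    else:
        presence_state = "not_evaluated"

    # --- stage 4+5: per-candidate annotation and validation --------------
    subgenome_by_id = {s.id: s for s in asm.subgenomes}
    main = asm.subgenomes[0] if asm.subgenomes else None
    candidates = []
    for result in specific:
        orf = result.orf
        entry = {
            "name": orf.name,
            "molecule": orf.molecule_id,
            "start": orf.start, "end": orf.end, "strand": orf.strand,
            "aa_len": orf.aa_len,
            "specificity": {"per_reference_identity_pct": result.per_reference,
                            "coverage": result.coverage},
            "presence": result.presence if presence_state == "evaluated" else "not_evaluated",
            "unique": result.is_unique if presence_state == "evaluated" else None,
            "segments": [dataclasses.asdict(seg) for seg in
                         annotate_segments(orf.nt_seq, gene_library)],
            "longest_exact_blocks": _exact_blocks(orf.nt_seq, gene_library),
            "tm_helices": [dataclasses.asdict(h) for h in
                           predict_tm(orf.peptide, threshold=cfg.tm_threshold,
                                      min_len=cfg.tm_min_len, window=cfg.tm_window)],
            "promoter_capture": _promoter_capture(orf, subgenome_by_id, ref_genome,
                                                  ref_features, cfg.promoter_window),
        }
        molecule = subgenome_by_id.get(orf.molecule_id)
        if main is not None and molecule is not None and molecule.id != main.id:
            entry["structure_validation"] = _validate_structure(
                molecule.seq, main.seq, cfg.overlap_len)
        candidates.append(entry)

    report = {
        "tool": {"name": "mitoscreen", "version": __version__},
        "parameters": dataclasses.asdict(cfg),
        "assembly": {
            "subgenomes": [{
                "id": s.id, "length": s.length, "topology": s.topology,
                "circularizable": s.circularizable,
                "path": [list(step) for step in s.path],
                "coord_map": [list(step) for step in s.coord_map],
            } for s in asm.subgenomes],
            "unplaced": asm.unplaced,
            "excluded": asm.excluded,
            "alternatives": {k: [[list(s) for s in p] for p in v]
                             for k, v in asm.alternatives.items()},
            "diagnostics": asm.diagnostics,
            "n_linkages": len(linkages),
            "plasmid_calls": [dataclasses.asdict(c) for c in plasmid_calls],
            "containments": [dataclasses.asdict(c) for c in containments],
        },
        "orf_counts": {"total": len(all_orfs), "specific": len(specific)},
        "presence_state": presence_state,
        "candidates": candidates,
    }
    validate_report(report)
    if outdir is not None:
        _persist(report, asm, linkages, plasmid_calls, containments,
                 all_orfs, spec_results, outdir)
    return report


def _exact_blocks(orf_nt: str, gene_library: dict[str, str],
                  min_report: int = 24) -> list[dict]:
    blocks = []
    for donor, seq in gene_library.items():
        length, a_iv, b_iv, strand = longest_exact_match(orf_nt, seq)
        if length >= min_report:
            blocks.append({"donor": donor, "length": length,
                           "query_start": a_iv[0], "query_end": a_iv[1],
                           "donor_start": b_iv[0], "donor_end": b_iv[1],
                           "donor_strand": strand})
    blocks.sort(key=lambda b: (-b["length"], b["donor"]))
    return blocks


def _promoter_capture(orf, subgenome_by_id, ref_genome, ref_features,
                      window: int, min_identity: float = 85.0):
    """Best match of the candidate's upstream region against reference gene
    promoters — evidence that the candidate captured another gene's promoter."""
    if ref_genome is None or not ref_features:
        return None
    molecule = subgenome_by_id.get(orf.molecule_id)
    if molecule is None:
        return None
    seq = molecule.seq
    if orf.strand == "+":
        lo = orf.start - 1 - window
        if lo < 0:
            return None
        query = seq[lo:orf.start + 2]           # window + start codon
    else:
        hi = orf.end + window
        if hi > len(seq):
            return None
        query = revcomp(seq[orf.end - 3:hi])
    anchor = window + 1
    promoters = {}
    cds_start = {f["attributes"].get("ID"): (f["start"], f["end"])
                 for f in ref_features if f["type"] == "CDS"}
    for feat in ref_features:
        if feat["type"] != "promoter":
            continue
        parent = feat["attributes"].get("Parent")
        if parent not in cds_start:
            continue
        g_start = cds_start[parent][0]
        region = ref_genome[feat["start"] - 1:feat["end"]] \
            + ref_genome[g_start - 1:g_start + 2]
        promoters[parent] = region
    best = None
    for gene, region in promoters.items():
        cmp = compare_flanking(query, region, anchor)
        if best is None or cmp.identity_pct > best[1].identity_pct:
            best = (gene, cmp)
    if best is None or best[1].identity_pct < min_identity:
        return None
    gene, cmp = best
    return {
        "source_gene": gene,
        "identity_pct": cmp.identity_pct,
        "differences": [dataclasses.asdict(d) for d in cmp.differences],
    }


def _validate_structure(molecule: str, backbone: str, overlap_len: int) -> dict:
    """Anchor a separate molecule's ends inside the main subgenome and, if it
    implies a substitution event, predict the validating Southern fragments
    and junction-PCR products."""
    mol = Contig("candidate_molecule", molecule)
    head = anchor_end_to_molecule(mol, "head", backbone, overlap_len)
    tail = anchor_end_to_molecule(mol, "tail", backbone, overlap_len)
    out: dict = {
        "head_anchors": [dataclasses.asdict(p) for p in head],
        "tail_anchors": [dataclasses.asdict(p) for p in tail],
    }
    fwd_anchors = [p for p in head if p.orientation == "+"]
    rev_anchors = [p for p in tail if p.orientation == "+"]
    if len(fwd_anchors) != 1 or len(rev_anchors) != 1:
        # the molecule may sit reverse-complemented relative to the backbone
        rc_head = [p for p in tail if p.orientation == "-"]
        rc_tail = [p for p in head if p.orientation == "-"]
        if len(rc_head) == 1 and len(rc_tail) == 1:
            molecule = revcomp(molecule)
            fwd_anchors = [dataclasses.replace(rc_head[0], orientation="+")]
            rev_anchors = [dataclasses.replace(rc_tail[0], orientation="+")]
        else:
            out["event"] = None
            return out
    s, e = fwd_anchors[0].target_start, rev_anchors[0].target_end
    if not (1 <= s < e <= len(backbone)):
        out["event"] = None
        return out
    event = SubstitutionEvent("backbone", s, e, "candidate_molecule",
                              left_flank=overlap_len, right_flank=overlap_len)
    recombinant = apply_substitution(backbone, event, molecule)
    out["event"] = {"start": s, "end": e, "replaced_len": event.replaced_len,
                    "insert_len": len(molecule),
                    "recombinant_len": len(recombinant)}

    # Southern prediction: probes just outside each junction detect one
    # band from each coexisting structure
    probe_margin = 1_000
    shift = len(molecule) - event.replaced_len
    southern = {}
    p1 = (max(1, s - probe_margin), s - 1)
    p2 = (e + 1, min(len(backbone), e + probe_margin))
    for enzyme in ENZYMES:
        southern[enzyme] = {
            "probe_upstream": southern_prediction(backbone, recombinant, enzyme,
                                                  p1, p1),
            "probe_downstream": southern_prediction(
                backbone, recombinant, enzyme, p2, (p2[0] + shift, p2[1] + shift)),
        }
    out["southern"] = southern

    # junction PCR: forward primer on the shared upstream backbone, reverse
    # primer inside the insert (recombinant-specific) or inside the replaced
    # backbone interval (backbone-specific)
    if s > 300 and len(molecule) > 1_000 and event.replaced_len > 1_000:
        fwd = backbone[s - 201:s - 181]
        rev_insert = revcomp(molecule[500:520])
        rev_backbone = revcomp(backbone[s + 499:s + 519])
        pcr = {}
        for label, rev in (("recombinant_junction", rev_insert),
                           ("backbone_structure", rev_backbone)):
            pcr[label] = {
                template: [p.length for p in insilico_pcr(tmpl, fwd, rev,
                                                          max_product=4_000)]
                for template, tmpl in (("backbone", backbone),
                                       ("recombinant", recombinant))
            }
        out["junction_pcr"] = pcr
    return out


def _persist(report, asm, linkages, plasmid_calls, containments,
             all_orfs, spec_results, outdir: Path) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_fasta(outdir / "subgenomes.fasta",
                {s.id: s.seq for s in asm.subgenomes})
    write_tsv(outdir / "linkages.tsv",
              [dataclasses.asdict(lk) for lk in linkages],
              ["a_id", "a_end", "a_orient", "b_id", "b_end", "b_orient",
               "overlap_len", "is_self"])
    write_tsv(outdir / "plasmid_calls.tsv",
              [dataclasses.asdict(c) for c in plasmid_calls],
              ["contig_id", "ref_id", "identity_pct", "verdict"])
    write_tsv(outdir / "containments.tsv",
              [dataclasses.asdict(c) for c in containments],
              ["inner_id", "outer_id", "outer_start", "outer_end", "strand",
               "duplicate"])
    verdict_by_name = {r.orf.name: r.verdict for r in spec_results}
    feats = []
    for orf in all_orfs:
        feats.append({"type": "CDS", "start": orf.start, "end": orf.end,
                      "strand": orf.strand,
                      "attributes": {"ID": f"{orf.molecule_id}:{orf.name}",
                                     "Name": orf.name, "aa_len": orf.aa_len,
                                     "verdict": verdict_by_name.get(orf.name, "")}})
    write_gff3(outdir / "orfs.gff3", "assembly", feats)
    write_tsv(outdir / "specificity.tsv",
              [{"orf": r.orf.name, "molecule": r.orf.molecule_id,
                "verdict": r.verdict, "coverage": r.coverage,
                **{f"identity_{k}": v for k, v in r.per_reference.items()}}
               for r in spec_results],
              ["orf", "molecule", "verdict", "coverage"]
              + [f"identity_{k}" for k in (spec_results[0].per_reference if spec_results else {})])
    presence_rows = []
    for cand in report["candidates"]:
        if isinstance(cand["presence"], dict):
            presence_rows.append({"orf": cand["name"], **cand["presence"],
                                  "unique": cand["unique"]})
    if presence_rows:
        cols = ["orf"] + [k for k in presence_rows[0] if k not in ("orf",)]
        write_tsv(outdir / "presence_matrix.tsv", presence_rows, cols)
    with open(outdir / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
        fh.write("\n")
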