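"""Regression checks against the deposited genome accessions.

The original Tadukan-type CMS analysis deposited its assembled molecules
(DDBJ LC595639 = subgenome-1 and LC592696-LC592699) and compared them with
public references (Nipponbare mitogenome DQ167400, the WA-CMS maintainer
JF281153, plasmid-like molecule B1 D00293).  Given local FASTA copies of
those records, :func:`run_accession_checks` recomputes the headline
quantities:
subgenome lengths, the two-candidate specificity screen, orf312/orf288
identities, the 48-bp cox2-exon block, the contig_6 shared 98-bp prefix at
subgenome-1 position 114,769, the B1-like plasmid identity and the ORF312
transmembrane helix.

The sequences are not bundled (they are large third-party records); fetch
them once with :func:`fetch_accessions` or place the files manually.
"""

from __future__ import annotations

from pathlib import Path

from .chimera import longest_exact_match, overall_identity
from .contigs import Contig, anchor_end_to_molecule, classify_plasmid_like
from .orfs import extract_orfs, filter_specific
from .tm import predict_tm

#: accession -> role in the checks
ACCESSIONS = {
    "LC595639": "subgenome-1 (355,786 bp main molecule)",
    "LC592696": "deposited molecule (subgenome-2 or plasmid-like)",
    "LC592697": "deposited molecule (subgenome-2 or plasmid-like)",
    "LC592698": "deposited molecule (subgenome-2 or plasmid-like)",
    "LC592699": "deposited molecule (subgenome-2 or plasmid-like)",
    "DQ167400": "Nipponbare mitochondrial genome (screen reference)",
    "JF281153": "WA-CMS maintainer mitochondrial genome (screen reference)",
    "D00293": "plasmid-like molecule B1",
}

EFETCH = ("https://eutils.ncbi.nlm.nih.gov/entrez/eutils/efetch.fcgi"
          "?db=nuccore&rettype=fasta&retmode=text&id={acc}")


def fetch_accessions(outdir: str | Path, accessions=tuple(ACCESSIONS)) -> list[Path]:
    """Download accession FASTAs via NCBI efetch (network required)."""
    from urllib.request import urlopen

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written = []
    for acc in accessions:
        dest = outdir / f"{acc}.fasta"
        if dest.exists():
            written.append(dest)
            continue
        with urlopen(EFETCH.format(acc=acc), timeout=60) as resp:
            dest.write_bytes(resp.read())
        written.append(dest)
    return written


def _load(data_dir: Path) -> dict[str, str]:
    from .io import read_fasta

    missing = [acc for acc in ACCESSIONS if not (data_dir / f"{acc}.fasta").exists()]
    if missing:
        raise FileNotFoundError(
            f"accession FASTAs missing under {data_dir}: {', '.join(missing)}. "
            "Fetch them with mitoscreen.regression.fetch_accessions() "
            "(network required) or place <accession>.fasta files there.")
    seqs = {}
    for acc in ACCESSIONS:
        records = read_fasta(data_dir / f"{acc}.fasta")
        seqs[acc] = next(iter(records.values()))
    return seqs


def run_accession_checks(data_dir: str | Path) -> dict:
    """Recompute the deposited-sequence quantities; returns a flat dict.

    Raises FileNotFoundError (with instructions) when the accession FASTAs
    are not present locally.
    """
    seqs = _load(Path(data_dir))
    sub1 = seqs["LC595639"]
    # subgenome-2 is the 6,141-bp deposited molecule
    candidates = {acc: seqs[acc] for acc in
                  ("LC592696", "LC592697", "LC592698", "LC592699")}
    sub2_acc, sub2 = min(candidates.items(), key=lambda kv: abs(len(kv[1]) - 6141))

    results: dict = {
        "subgenome1_len_bp": len(sub1),
        "subgenome2_len_bp": len(sub2),
        "subgenome2_accession": sub2_acc,
    }

    references = {"DQ167400": seqs["DQ167400"], "JF281153": seqs["JF281153"]}
    orfs = extract_orfs(sub2, min_aa=70, molecule_id="subgenome-2")
    specific = [r for r in filter_specific(orfs, references) if r.verdict == "specific"]
    results["n_specific_orfs_subgenome2"] = len(specific)
    by_len = {r.orf.aa_len: r.orf for r in specific}
    orf312 = by_len.get(312)
    if orf312 is not None:
        # orf288 in the Nipponbare genome: the reference ORF most similar
        # to orf312 (>=80% nt identity), rediscovered by scanning DQ167400
        np_orfs = extract_orfs(seqs["DQ167400"], min_aa=250, molecule_id="DQ167400")
        best = None
        for rec in np_orfs:
            if abs(rec.aa_len - orf312.aa_len) > 30:
                continue
            ident = overall_identity(orf312.nt_seq, rec.nt_seq, "nt")
            if best is None or ident > best[0]:
                best = (ident, rec)
        if best is not None and best[0] >= 80:
            orf288 = best[1]
            results["orf312_vs_orf288_nt_identity_pct"] = best[0]
            results["orf312_vs_orf288_aa_identity_pct"] = overall_identity(
                orf312.peptide, orf288.peptide, "aa")
            results["orf312_vs_orf288_region_identity_pct"] = overall_identity(
                orf312.nt_seq[99:936], orf288.nt_seq[99:936], "nt")
            # cox2 exon 1: locate via the longest exact block shared with orf288
            length, _, _, _ = longest_exact_match(orf288.nt_seq, sub1)
            results["orf288_longest_block_in_subgenome1_bp"] = length
        helices = predict_tm(orf312.peptide)
        results["orf312_tm_helix_count"] = len(helices)
        if helices:
            results["orf312_tm_start_aa"] = helices[0].start_aa
            results["orf312_tm_end_aa"] = helices[0].end_aa

    head = anchor_end_to_molecule(Contig("subgenome-2", sub2), "head", sub1)
    fwd = [p for p in head if p.orientation == "+"]
    if fwd:
        results["subgenome2_head_anchor_start"] = fwd[0].target_start
        results["subgenome2_head_shared_prefix_bp"] = fwd[0].match_len

    b1_like = min(candidates.values(), key=lambda s: abs(len(s) - len(seqs["D00293"])))
    call = classify_plasmid_like([Contig("B1-like", b1_like)],
                                 {"D00293": seqs["D00293"]})[0]
    results["b1_like_vs_D00293_identity_pct"] = call.identity_pct
    return results
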