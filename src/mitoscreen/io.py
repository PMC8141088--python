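"""FASTA / GFF3 / TSV input-output helpers.

FASTA goes through Bio.SeqIO; GFF3 is written directly (a handful of CDS and
promoter features; no third-party GFF writer is needed for output-only use).
Sequences are upper-cased on load, as the assembly overlap and ORF logic is
case-sensitive by design.
"""

from __future__ import annotations

import csv
from pathlib import Path
from typing import Iterable, Mapping

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read a (multi-)FASTA into an ordered {id: upper-case sequence} dict."""
    records: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in records:
            raise ValueError(f"duplicate FASTA id {rec.id!r} in {path}")
        records[rec.id] = str(rec.seq).upper()
    return records


def write_fasta(path: str | Path, records: Mapping[str, str], width: int = 70) -> None:
    recs = [SeqRecord(Seq(seq), id=name, description="") for name, seq in records.items()]
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(recs)


def write_gff3(path: str | Path, seqid: str, features: Iterable[dict]) -> None:
    """Write GFF3 features.

    Each feature dict needs: type, start, end (1-based inclusive), strand,
    attributes (dict).  Source column is 'mitoscreen'.
    """
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for feat in features:
            attrs = ";".join(f"{k}={v}" for k, v in feat["attributes"].items())
            fh.write("\t".join([
                seqid,
                "mitoscreen",
                feat["type"],
                str(feat["start"]),
                str(feat["end"]),
                str(feat.get("score", ".")),
                feat.get("strand", "+"),
                str(feat.get("phase", ".")),
                attrs,
            ]) + "\n")


def read_gff3(path: str | Path) -> list[dict]:
    """Read GFF3 features into dicts (seqid, type, start, end, strand,
    attributes).  Covers the subset this package writes."""
    feats = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 9:
                raise ValueError(f"malformed GFF3 line: {line!r}")
            attrs = dict(item.split("=", 1) for item in cols[8].split(";") if item)
            feats.append({
                "seqid": cols[0], "type": cols[2],
                "start": int(cols[3]), "end": int(cols[4]),
                "strand": cols[6], "attributes": attrs,
            })
    return feats


def write_tsv(path: str | Path, rows: Iterable[Mapping], columns: list[str]) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=columns, delimiter="\t",
                                extrasaction="ignore", lineterminator="\n")
        writer.writeheader()
        for row in rows:
            writer.writerow(row)
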