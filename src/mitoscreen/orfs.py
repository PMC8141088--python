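"""Six-frame ORF extraction and the specificity screen.

The screen follows the standard workflow for finding cytoplasmic male
sterility (CMS) candidate genes: extract every open reading frame of at
least 70 codons from the assembled mitochondrial molecules, discard the
"common" ORFs that are >99% identical to an ORF region of reference
mitogenomes (a fertile standard cultivar and a maintainer line), and score
the survivors for presence or absence across a panel of other CMS-type
mitogenomes.  A candidate that is absent from every panel genome is unique
to the studied cytoplasm.

ORFs are ATG-initiated under the universal genetic code (plant mitochondria
use the standard code); per stop-bounded frame segment only the longest
ATG-initiated frame is reported.  A ``stop_to_stop`` convention is available
behind a switch for comparison with annotation tools that use it.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

from Bio.Seq import Seq

from .align import infix_identity
from .seqs import STOP_CODONS, revcomp

MIN_ORF_AA = 70


@dataclass(frozen=True)
class OrfRecord:
    """An open reading frame on an assembled molecule.

    ``start``/``end`` are 1-based inclusive coordinates on the forward
    strand of the molecule; ``nt_seq`` includes the stop codon, so
    ``end - start + 1 == 3 * (aa_len + 1)``.  ``peptide`` starts with M.
    """

    name: str
    molecule_id: str
    start: int
    end: int
    strand: str
    nt_seq: str
    aa_len: int
    peptide: str


def _frame_orfs(oriented: str, frame: int, min_aa: int):
    """Yield (start_codon_index, stop_codon_index) pairs, 0-based codon
    indices on the oriented sequence; Ns break segments (a codon containing
    N is never translated)."""
    n_codons = (len(oriented) - frame) // 3
    first_atg = None
    for ci in range(n_codons):
        codon = oriented[frame + 3 * ci: frame + 3 * ci + 3]
        if "N" in codon:
            first_atg = None
            continue
        if codon in STOP_CODONS:
            if first_atg is not None and ci - first_atg >= min_aa:
                yield first_atg, ci
            first_atg = None
        elif first_atg is None and codon == "ATG":
            first_atg = ci


def extract_orfs(molecule: str, min_aa: int = MIN_ORF_AA,
                 molecule_id: str = "molecule",
                 convention: str = "atg") -> list[OrfRecord]:
    """Scan all six frames of both strands for ORFs of >= ``min_aa`` residues.

    With the default ``atg`` convention an ORF runs from the first ATG of a
    stop-bounded frame segment to its stop codon (nested shorter ATG starts
    suppressed); ``stop_to_stop`` instead reports the whole stop-bounded
    segment regardless of a start codon.  ORFs reaching a sequence end
    without a stop codon are not reported.
    """
    if convention not in ("atg", "stop_to_stop"):
        raise ValueError("convention must be 'atg' or 'stop_to_stop'")
    molecule = molecule.upper()
    length = len(molecule)
    records = []
    for strand in ("+", "-"):
        oriented = molecule if strand == "+" else revcomp(molecule)
        for frame in range(3):
            if convention == "atg":
                pairs = _frame_orfs(oriented, frame, min_aa)
            else:
                pairs = _stop_to_stop(oriented, frame, min_aa)
            for start_ci, stop_ci in pairs:
                lo = frame + 3 * start_ci           # 0-based on oriented
                hi = frame + 3 * (stop_ci + 1)      # exclusive, incl. stop
                nt = oriented[lo:hi]
                if strand == "+":
                    start, end = lo + 1, hi
                else:
                    start, end = length - hi + 1, length - lo
                aa_len = stop_ci - start_ci
                peptide = str(Seq(nt[:-3]).translate())
                records.append(OrfRecord(
                    name="", molecule_id=molecule_id, start=start, end=end,
                    strand=strand, nt_seq=nt, aa_len=aa_len, peptide=peptide))
    records.sort(key=lambda r: (r.start, r.end, r.strand))
    return assign_names(records)


def _stop_to_stop(oriented: str, frame: int, min_aa: int):
    n_codons = (len(oriented) - frame) // 3
    seg_start = None
    for ci in range(n_codons):
        codon = oriented[frame + 3 * ci: frame + 3 * ci + 3]
        if "N" in codon:
            seg_start = None
            continue
        if codon in STOP_CODONS:
            if seg_start is not None and ci - seg_start >= min_aa:
                yield seg_start, ci
            seg_start = ci + 1
        elif seg_start is None:
            seg_start = ci


def name_orf(record: OrfRecord) -> str:
    """Candidate naming convention: 'orf' + predicted amino-acid count."""
    return f"orf{record.aa_len}"


def assign_names(records: list[OrfRecord]) -> list[OrfRecord]:
    """Apply the orf<aa_len> naming rule, disambiguating collisions a/b/c..."""
    by_len: dict[int, list[int]] = {}
    for i, rec in enumerate(records):
        by_len.setdefault(rec.aa_len, []).append(i)
    named = list(records)
    for aa_len, idxs in by_len.items():
        if len(idxs) == 1:
            named[idxs[0]] = replace(records[idxs[0]], name=f"orf{aa_len}")
        else:
            for suffix, i in zip("abcdefghijklmnopqrstuvwxyz", idxs):
                named[i] = replace(records[i], name=f"orf{aa_len}{suffix}")
    return named


# ---------------------------------------------------------------------------
# specificity screen


@dataclass(frozen=True)
class SpecificityResult:
    orf: OrfRecord
    per_reference: dict[str, float]  # best identity_pct per reference
    coverage: float
    verdict: str                     # 'specific' | 'common'
    presence: dict[str, str] | None = None  # genome -> identical|partial|absent

    @property
    def is_unique(self) -> bool:
        """Unique iff no panel genome carries an identical full-length copy."""
        if not self.presence:
            return True
        return all(call != "identical" for call in self.presence.values())


def _best_screen_identity(orf_nt: str, genome: str) -> float:
    hit = infix_identity(orf_nt, genome)
    return hit.identity_pct if hit else 0.0


def filter_specific(orfs: list[OrfRecord], reference_genomes: dict[str, str],
                    identity_threshold_pct: float = 99.0,
                    min_coverage: float = 0.95) -> list[SpecificityResult]:
    """Discard ORFs >identity_threshold_pct identical to a reference region.

    Each whole ORF is aligned semi-globally into every reference genome
    (both strands); the full query is consumed, so coverage is 1.0, above any
    sensible ``min_coverage`` floor.  An ORF is 'common' when its best hit
    exceeds the threshold (strictly more than 99% by default), otherwise
    'specific'.
    """
    if not reference_genomes:
        raise ValueError("reference genome set must be non-empty")
    results = []
    for orf in orfs:
        per_ref = {name: round(_best_screen_identity(orf.nt_seq, genome), 2)
                   for name, genome in reference_genomes.items()}
        best = max(per_ref.values())
        coverage = 1.0
        verdict = ("common" if best > identity_threshold_pct and coverage >= min_coverage
                   else "specific")
        results.append(SpecificityResult(orf, per_ref, coverage, verdict))
    return results


def presence_absence(specific_orfs: list[OrfRecord] | list[SpecificityResult],
                     panel: dict[str, str],
                     identical_threshold_pct: float = 100.0,
                     partial_identity_pct: float = 80.0) -> list[SpecificityResult]:
    """Score candidate ORFs across a panel of comparison mitogenomes.

    'identical' means an exact full-length copy of the ORF exists on either
    strand (at the default 100% threshold this is an exact substring match);
    'partial' means at least half the ORF aligns at >= ``partial_identity_pct``
    identity; otherwise 'absent'.  With an empty panel every ORF is unique.
    """
    results = []
    for item in specific_orfs:
        if isinstance(item, SpecificityResult):
            orf, base = item.orf, item
        else:
            orf, base = item, SpecificityResult(item, {}, 1.0, "specific")
        presence: dict[str, str] = {}
        for name, genome in panel.items():
            presence[name] = _presence_call(orf.nt_seq, genome,
                                            identical_threshold_pct,
                                            partial_identity_pct)
        results.append(replace(base, presence=presence))
    return results


def _presence_call(orf_nt: str, genome: str, identical_pct: float,
                   partial_pct: float) -> str:
    if identical_pct >= 100.0:
        if orf_nt in genome or revcomp(orf_nt) in genome:
            return "identical"
    else:
        if _best_screen_identity(orf_nt, genome) >= identical_pct:
            return "identical"
    # partial: >= partial_pct identity over >= 50% of the ORF, probed with
    # the whole ORF and with each half as semi-global queries
    half = len(orf_nt) // 2
    probes = [orf_nt, orf_nt[:half], orf_nt[half:]] if half >= 30 else [orf_nt]
    if any(_best_screen_identity(p, genome) >= partial_pct for p in probes):
        return "partial"
    return "absent"
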