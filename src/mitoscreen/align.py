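"""Shared pairwise-alignment helpers.

Two engines are used behind the module surfaces:

* :class:`Bio.Align.PairwiseAligner` for global/local affine-gap alignments
  where per-column bookkeeping (identity over alignment columns, per-position
  differences) is needed.  Nucleotide scoring is match +2 / mismatch -3 /
  gap open -5 / gap extend -2; amino acids use BLOSUM62 with open -11 /
  extend -1.
* ``edlib`` in semi-global ("HW"/infix) mode for screening a whole query
  against a large reference, where only an edit-distance-style identity is
  required and speed matters.

Percent identity is always matches / alignment columns, with gap columns
counted in the denominator.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import edlib
from Bio import Align
from Bio.Align import substitution_matrices

from .seqs import revcomp

NT_SCORING = dict(match_score=2.0, mismatch_score=-3.0,
                  open_gap_score=-5.0, extend_gap_score=-2.0)


def nt_aligner(mode: str = "global") -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = mode
    for key, val in NT_SCORING.items():
        setattr(aligner, key, val)
    return aligner


def aa_aligner(mode: str = "global") -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = mode
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -11.0
    aligner.extend_gap_score = -1.0
    return aligner


def alignment_identity(alignment, include_terminal_gaps: bool = True) -> float:
    """Percent identity of a Biopython alignment: matches / columns * 100.

    For local alignments the unaligned flanks are outside the alignment and
    never counted; ``include_terminal_gaps`` only matters for global mode.
    """
    counts = alignment.counts()
    gaps = counts.gaps
    if not include_terminal_gaps:
        gaps -= counts.left_gaps + counts.right_gaps
    columns = counts.identities + counts.mismatches + gaps
    if columns == 0:
        return 0.0
    return 100.0 * counts.identities / columns


_CIGAR_RE = re.compile(r"(\d+)([=XIDM])")


@dataclass(frozen=True)
class InfixHit:
    """Best semi-global placement of a whole query inside a target."""

    identity_pct: float
    target_start: int  # 0-based
    target_end: int    # 0-based exclusive
    strand: str        # '+' or '-'
    edit_distance: int


def _cigar_identity(cigar: str) -> float:
    matches = columns = 0
    for num, op in _CIGAR_RE.findall(cigar):
        n = int(num)
        columns += n
        if op == "=":
            matches += n
    return 100.0 * matches / columns if columns else 0.0


def infix_identity(query: str, target: str, both_strands: bool = True) -> InfixHit | None:
    """Align the whole query inside ``target`` (edlib HW mode), best strand.

    Returns the best-identity placement, or None for empty inputs.  The whole
    query is always consumed, so query coverage is 1.0 by construction.
    """
    if not query or not target or len(query) > 2 * len(target) + 64:
        # hopeless placements are not worth an alignment; treat as no hit
        if not query or not target:
            return None
    best: InfixHit | None = None
    strands = ("+", "-") if both_strands else ("+",)
    for strand in strands:
        q = query if strand == "+" else revcomp(query)
        res = edlib.align(q, target, mode="HW", task="path")
        if res["editDistance"] < 0 or not res["locations"]:
            continue
        ident = _cigar_identity(res["cigar"])
        start, end = res["locations"][0]
        hit = InfixHit(ident, start, end + 1, strand, res["editDistance"])
        if best is None or hit.identity_pct > best.identity_pct:
            best = hit
    return best
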