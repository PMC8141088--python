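"""Chimeric-ORF decomposition and flanking-region comparison.

CMS-associated mitochondrial ORFs are typically chimeras: fragments of
known mitochondrial genes stitched together with sequence of unknown
origin, placed downstream of a captured promoter.  This module maps a
candidate ORF back onto a library of known genes (local alignments tiled
along the query), finds the longest exactly shared block (e.g. a
cox2-exon-derived fragment), computes overall nucleotide/peptide identities
to a related gene, and compares the candidate's upstream/intergenic region
against the homologous region of a reference, reporting every difference at
its position relative to the start codon (negative positions upstream).
"""

from __future__ import annotations

from dataclasses import dataclass

from .align import aa_aligner, alignment_identity, nt_aligner
from .seqs import revcomp


@dataclass(frozen=True)
class ChimeraSegment:
    """A donor-gene fragment mapped onto a candidate ORF."""

    query_start: int   # 1-based inclusive, on the ORF
    query_end: int
    donor_id: str
    donor_start: int   # 1-based inclusive, on the donor gene (forward strand)
    donor_end: int
    donor_strand: str
    identity_pct: float
    aligned_len: int
    score: float


@dataclass(frozen=True)
class FlankDifference:
    position: int      # relative to start codon: +1 = A of ATG, -1 = first base upstream
    kind: str          # substitution | insertion | deletion
    ref_base: str
    query_base: str


@dataclass(frozen=True)
class FlankComparison:
    identity_pct: float
    differences: list[FlankDifference]


def overall_identity(a: str, b: str, alphabet: str = "nt") -> float:
    """Global affine-gap percent identity, gap columns in the denominator.

    Reported to the nearest integer percent, matching how identities between
    candidate and donor genes are conventionally quoted.
    """
    if not a or not b:
        raise ValueError("sequences must be non-empty")
    if alphabet == "nt":
        aligner = nt_aligner("global")
        ok = set("ACGTN")
        if not (set(a.upper()) <= ok and set(b.upper()) <= ok):
            raise ValueError("non-nucleotide characters in nt-mode input")
        a, b = a.upper(), b.upper()
    elif alphabet == "aa":
        aligner = aa_aligner("global")
    else:
        raise ValueError("alphabet must be 'nt' or 'aa'")
    return float(round(alignment_identity(aligner.align(a, b)[0])))


# ---------------------------------------------------------------------------
# segment annotation


def _local_hits(query: str, donor_id: str, donor_seq: str, min_len: int,
                min_identity: float, max_rounds: int = 6):
    """Best local alignments of query vs one donor (both strands), found by
    iterative masking of the already-claimed query interval."""
    aligner = nt_aligner("local")
    hits = []
    for strand in ("+", "-"):
        target = donor_seq if strand == "+" else revcomp(donor_seq)
        masked = query
        for _ in range(max_rounds):
            if len(masked.replace("X", "")) < min_len:
                break
            alignments = aligner.align(masked, target)
            if alignments.score <= 0:
                break
            aln = alignments[0]
            q0, q1 = int(aln.aligned[0][0][0]), int(aln.aligned[0][-1][1])
            t0, t1 = int(aln.aligned[1][0][0]), int(aln.aligned[1][-1][1])
            ident = alignment_identity(aln)
            span = q1 - q0
            if span >= min_len and ident >= min_identity:
                if strand == "+":
                    d_start, d_end = t0 + 1, t1
                else:
                    d_start, d_end = len(donor_seq) - t1 + 1, len(donor_seq) - t0
                hits.append(ChimeraSegment(
                    query_start=q0 + 1, query_end=q1, donor_id=donor_id,
                    donor_start=d_start, donor_end=d_end, donor_strand=strand,
                    identity_pct=round(ident, 2), aligned_len=span,
                    score=float(aln.score)))
            elif span < min_len:
                break
            masked = masked[:q0] + "X" * span + masked[q1:]
    return hits


def annotate_segments(orf_nt: str, gene_library: dict[str, str],
                      min_seg_len: int = 50, min_identity_pct: float = 70.0,
                      overlap_slack: int = 10,
                      method: str = "greedy") -> list[ChimeraSegment]:
    """Decompose a candidate ORF into donor-gene segments.

    All local alignments passing the length/identity thresholds are collected
    per donor (both strands) and tiled along the query: greedily by alignment
    score (default), or by exact weighted-interval scheduling
    (``method='exact'``) for audit.  Accepted segments may overlap on the
    query by at most ``overlap_slack`` bp; output is in query order.
    """
    if not gene_library:
        raise ValueError("gene library must be non-empty")
    orf_nt = orf_nt.upper()
    candidates: list[ChimeraSegment] = []
    for donor_id, donor_seq in gene_library.items():
        candidates.extend(_local_hits(orf_nt, donor_id, donor_seq.upper(),
                                      min_seg_len, min_identity_pct))
    if method == "greedy":
        chosen: list[ChimeraSegment] = []
        for seg in sorted(candidates, key=lambda s: (-s.score, s.query_start, s.donor_id)):
            if all(_query_overlap(seg, other) <= overlap_slack for other in chosen):
                chosen.append(seg)
    elif method == "exact":
        chosen = _exact_tiling(candidates, overlap_slack)
    else:
        raise ValueError("method must be 'greedy' or 'exact'")
    return sorted(chosen, key=lambda s: (s.query_start, s.query_end))


def _query_overlap(a: ChimeraSegment, b: ChimeraSegment) -> int:
    return min(a.query_end, b.query_end) - max(a.query_start, b.query_start) + 1


def _exact_tiling(candidates: list[ChimeraSegment], slack: int) -> list[ChimeraSegment]:
    """Weighted interval scheduling maximising total score, allowing pairwise
    query overlap up to ``slack`` bp (intervals shrunk by slack/2 per side)."""
    segs = sorted(candidates, key=lambda s: s.query_end)
    n = len(segs)
    best: list[tuple[float, list[ChimeraSegment]]] = [(0.0, [])] * (n + 1)
    for i, seg in enumerate(segs, start=1):
        # latest j whose (end - slack) < this start
        take_score, take_set = seg.score, [seg]
        j = i - 1
        while j > 0 and segs[j - 1].query_end - slack >= seg.query_start:
            j -= 1
        take_score += best[j][0]
        take_set = best[j][1] + [seg]
        best[i] = max(best[i - 1], (take_score, take_set), key=lambda t: t[0])
    return best[n][1]


# ---------------------------------------------------------------------------
# longest exact shared block


def longest_exact_match(a: str, b: str) -> tuple[int, tuple[int, int], tuple[int, int], str]:
    """Longest common substring of ``a`` and ``b`` (b on both strands).

    Returns (length, (a_start, a_end), (b_start, b_end), b_strand), 1-based
    inclusive intervals on the forward strands; ties broken by the smallest
    a-interval start (forward b strand preferred on further ties).  Length 0
    means no shared base.
    """
    if not a or not b:
        raise ValueError("sequences must be non-empty")
    a, b = a.upper(), b.upper()

    def hit_at(length: int):
        if length == 0:
            return None
        bs = {b[i:i + length] for i in range(len(b) - length + 1)}
        rb = revcomp(b)
        rbs = {rb[i:i + length] for i in range(len(rb) - length + 1)}
        for i in range(len(a) - length + 1):
            word = a[i:i + length]
            if word in bs:
                j = b.find(word)
                return length, (i + 1, i + length), (j + 1, j + length), "+"
            if word in rbs:
                j = rb.find(word)
                # map interval from reverse strand back to forward b
                start = len(b) - (j + length) + 1
                return length, (i + 1, i + length), (start, start + length - 1), "-"
        return None

    lo, hi = 0, min(len(a), len(b))
    best = None
    while lo < hi:
        mid = (lo + hi + 1) // 2
        hit = hit_at(mid)
        if hit:
            lo = mid
        else:
            hi = mid - 1
    if lo:
        best = hit_at(lo)
    return best if best else (0, (0, 0), (0, 0), "+")


# ---------------------------------------------------------------------------
# flanking / promoter comparison


def compare_flanking(query_region: str, ref_region: str,
                     query_anchor: int) -> FlankComparison:
    """Globally align a candidate's flanking region against a reference region
    and report each difference relative to the start codon.

    ``query_anchor`` is the 1-based position of the first base of the start
    codon within ``query_region``; bases at or after it get positive
    positions (+1 = the A of ATG), bases before it negative positions
    (-1 = the base immediately upstream).  There is no position 0.
    """
    if not query_region or not ref_region:
        raise ValueError("regions must be non-empty")
    if not (1 <= query_anchor <= len(query_region)):
        raise ValueError("anchor must lie inside the query region")
    aligner = nt_aligner("global")
    aln = aligner.align(query_region.upper(), ref_region.upper())[0]
    identity = alignment_identity(aln)

    def rel(qpos: int) -> int:  # qpos 1-based on query
        return qpos - query_anchor + 1 if qpos >= query_anchor else qpos - query_anchor

    differences: list[FlankDifference] = []
    q_idx = t_idx = 0
    for (q0, q1), (t0, t1) in _alignment_columns(aln):
        if q1 > q0 and t1 > t0:  # aligned block
            for off in range(q1 - q0):
                qb = query_region[q0 + off].upper()
                tb = ref_region[t0 + off].upper()
                if qb != tb:
                    differences.append(FlankDifference(rel(q0 + off + 1),
                                                       "substitution", tb, qb))
        elif q1 > q0:  # insertion in query relative to reference
            differences.append(FlankDifference(rel(q0 + 1), "insertion", "-",
                                               query_region[q0:q1].upper()))
        else:          # deletion from query relative to reference
            anchor_pos = q0 if q0 >= 1 else 1
            differences.append(FlankDifference(rel(anchor_pos), "deletion",
                                               ref_region[t0:t1].upper(), "-"))
    return FlankComparison(identity_pct=round(identity, 2), differences=differences)


def _alignment_columns(aln):
    """Yield ((q0,q1),(t0,t1)) runs covering the whole alignment, including
    gap runs between the aligned blocks."""
    q_blocks, t_blocks = aln.aligned
    prev_q = prev_t = None
    for (q0, q1), (t0, t1) in zip(q_blocks, t_blocks):
        q0, q1, t0, t1 = int(q0), int(q1), int(t0), int(t1)
        if prev_q is not None:
            if q0 > prev_q:
                yield (prev_q, q0), (prev_t, prev_t)
            if t0 > prev_t:
                yield (q0, q0), (prev_t, t0)
        else:
            if q0 > 0:
                yield (0, q0), (0, 0)
            if t0 > 0:
                yield (q0, q0), (0, t0)
        yield (q0, q1), (t0, t1)
        prev_q, prev_t = q1, t1
    # terminal gaps
    if prev_q is not None:
        qn = len(aln.sequences[0])
        tn = len(aln.sequences[1])
        if prev_q < qn:
            yield (prev_q, qn), (prev_t, prev_t)
        if prev_t < tn:
            yield (qn, qn), (prev_t, tn)
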