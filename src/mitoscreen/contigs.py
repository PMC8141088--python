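"""Contig overlap-graph assembly of organelle (sub)genomes.

Plant mitochondrial genomes assembled with de Bruijn assemblers come out as
contigs whose adjacent ends share an exact k-1 bp sequence (98 bp for a
k=99 assembly).  This module rebuilds the molecule(s) from those end
overlaps:

* :func:`find_end_overlaps` — every exact fixed-length end-to-end linkage,
  reverse complements included;
* :func:`detect_contained` — contigs fully included in another contig;
* :func:`classify_plasmid_like` — contigs that are near-identical to small
  autonomous plasmid-like circles and therefore not part of the main genome;
* :func:`assemble_master` — the smallest walk(s) through the linkage graph
  that use every genomic contig at least once, emitting subgenomes;
* :func:`anchor_end_to_molecule` — place a contig end inside an assembled
  molecule (the in-silico analogue of walking out from a contig end by
  fusion-primer nested PCR).

Overlaps are exact matches only; approximate overlaps are rejected by
design, because k-1 overlaps from a de Bruijn assembler are exact.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import networkx as nx

from .align import alignment_identity, nt_aligner
from .seqs import find_all, revcomp

logger = logging.getLogger(__name__)

DEFAULT_OVERLAP = 98

Orient = str  # '+' or '-'
Node = tuple[str, Orient]


def _flip(orient: Orient) -> Orient:
    return "-" if orient == "+" else "+"


@dataclass(frozen=True)
class Contig:
    """An assembled DNA segment."""

    id: str
    seq: str

    def __post_init__(self):
        object.__setattr__(self, "seq", self.seq.upper())

    @property
    def length(self) -> int:
        return len(self.seq)

    def oriented(self, orient: Orient) -> str:
        return self.seq if orient == "+" else revcomp(self.seq)


def as_contigs(records: dict[str, str] | list[Contig]) -> list[Contig]:
    if isinstance(records, dict):
        return [Contig(name, seq) for name, seq in records.items()]
    return list(records)


@dataclass(frozen=True)
class Linkage:
    """An exact end overlap joining oriented contig a to oriented contig b.

    Reading a in orientation ``a_orient``, its final ``overlap_len`` bases
    equal the initial ``overlap_len`` bases of b read in ``b_orient``.
    ``a_end``/``b_end`` name the physical contig ends involved on the
    original (+) strands.
    """

    a_id: str
    a_end: str
    a_orient: Orient
    b_id: str
    b_end: str
    b_orient: Orient
    overlap_len: int
    is_self: bool = False

    @property
    def a_node(self) -> Node:
        return (self.a_id, self.a_orient)

    @property
    def b_node(self) -> Node:
        return (self.b_id, self.b_orient)

    def twin(self) -> "Linkage":
        """The same physical junction read on the opposite strand."""
        return _join_to_linkage((self.b_id, _flip(self.b_orient)),
                                (self.a_id, _flip(self.a_orient)),
                                self.overlap_len)


def _join_to_linkage(a: Node, b: Node, overlap_len: int) -> Linkage:
    return Linkage(
        a_id=a[0],
        a_end="tail" if a[1] == "+" else "head",
        a_orient=a[1],
        b_id=b[0],
        b_end="head" if b[1] == "+" else "tail",
        b_orient=b[1],
        overlap_len=overlap_len,
        is_self=(a == b),
    )


def find_end_overlaps(contigs, overlap_len: int = DEFAULT_OVERLAP) -> list[Linkage]:
    """All exact end overlaps of length ``overlap_len`` among the contigs.

    Both orientations are considered; each physical junction is reported once
    in its canonical orientation (the strand on which the shared overlap-mer
    is lexicographically smaller).  Contigs shorter than the overlap are
    rejected with a warning rather than an error.
    """
    if overlap_len < 1:
        raise ValueError("overlap_len must be >= 1")
    contigs = as_contigs(contigs)
    usable = []
    for contig in contigs:
        if contig.length < overlap_len:
            logger.warning("contig %s (%d bp) shorter than overlap %d bp; skipped",
                           contig.id, contig.length, overlap_len)
            continue
        usable.append(contig)

    by_head: dict[str, list[Node]] = {}
    tails: list[tuple[Node, str]] = []
    for contig in usable:
        for orient in ("+", "-"):
            oseq = contig.oriented(orient)
            node = (contig.id, orient)
            by_head.setdefault(oseq[:overlap_len], []).append(node)
            tails.append((node, oseq[-overlap_len:]))

    seen: set[tuple[Node, Node]] = set()
    linkages: list[Linkage] = []
    for a_node, kmer in tails:
        for b_node in by_head.get(kmer, ()):
            join = (a_node, b_node)
            rc_kmer = revcomp(kmer)
            twin = ((b_node[0], _flip(b_node[1])), (a_node[0], _flip(a_node[1])))
            if rc_kmer < kmer:
                canonical = twin
            elif rc_kmer > kmer:
                canonical = join
            else:
                canonical = min(join, twin)
            if canonical in seen:
                continue
            seen.add(canonical)
            linkages.append(_join_to_linkage(canonical[0], canonical[1], overlap_len))
    linkages.sort(key=lambda lk: (lk.a_id, lk.a_orient, lk.b_id, lk.b_orient))
    return linkages


def oriented_joins(linkages: list[Linkage]) -> set[tuple[Node, Node]]:
    """Expand canonical linkages into the full set of oriented joins."""
    joins: set[tuple[Node, Node]] = set()
    for lk in linkages:
        joins.add((lk.a_node, lk.b_node))
        tw = lk.twin()
        joins.add((tw.a_node, tw.b_node))
    return joins


# ---------------------------------------------------------------------------
# end anchoring


@dataclass(frozen=True)
class Placement:
    """A maximal exact placement of a contig end inside a target molecule."""

    target_start: int  # 1-based inclusive
    target_end: int    # 1-based inclusive
    orientation: Orient
    match_len: int


def anchor_end_to_molecule(contig: Contig, end: str, target: str,
                           overlap_len: int = DEFAULT_OVERLAP) -> list[Placement]:
    """Place the terminal ``overlap_len``-mer of a contig end on a molecule.

    Every exact occurrence of the end k-mer (either strand) is extended
    inward along the contig for as long as identity continues, mirroring how
    adjacent sequence determined by nested-PCR walking is mapped back onto an
    assembled subgenome.  An empty list signals an unlinked end.
    """
    if end not in ("head", "tail"):
        raise ValueError("end must be 'head' or 'tail'")
    if len(target) < overlap_len or contig.length < overlap_len:
        return []
    placements: list[Placement] = []
    for orientation in ("+", "-"):
        oseq = contig.seq if orientation == "+" else revcomp(contig.seq)
        # on the oriented sequence the anchored end keeps its identity:
        # a head stays the leftmost k-mer under '+', and under '-' the head
        # becomes the rightmost k-mer of the reverse complement.
        at_left = (end == "head") == (orientation == "+")
        if at_left:
            kmer = oseq[:overlap_len]
            for pos in find_all(target, kmer):
                ext = overlap_len
                while (ext < len(oseq) and pos + ext < len(target)
                       and oseq[ext] == target[pos + ext]):
                    ext += 1
                placements.append(Placement(pos + 1, pos + ext, orientation, ext))
        else:
            kmer = oseq[-overlap_len:]
            for pos in find_all(target, kmer):
                ext = overlap_len
                while (ext < len(oseq) and pos - (ext - overlap_len) > 0
                       and oseq[-ext - 1] == target[pos - (ext - overlap_len) - 1]):
                    ext += 1
                start = pos + overlap_len - ext
                placements.append(Placement(start + 1, pos + overlap_len, orientation, ext))
    placements.sort(key=lambda p: (p.target_start, p.orientation))
    return placements


# ---------------------------------------------------------------------------
# plasmid-like classification


@dataclass(frozen=True)
class PlasmidCall:
    contig_id: str
    ref_id: str | None
    identity_pct: float
    verdict: str  # 'plasmid_like' | 'genomic'


def _rotate_to_anchor(contig_seq: str, ref_seq: str, anchor_len: int = 16) -> str:
    """Rotate a circular reference so it starts where the contig starts."""
    doubled = ref_seq + ref_seq
    for offset in range(0, min(len(contig_seq) - anchor_len + 1, 256), anchor_len):
        anchor = contig_seq[offset:offset + anchor_len]
        pos = doubled.find(anchor)
        if pos != -1:
            start = (pos - offset) % len(ref_seq)
            return doubled[start:start + len(ref_seq)]
    return ref_seq


def classify_plasmid_like(contigs, plasmid_refs: dict[str, str],
                          min_identity_pct: float = 99.0,
                          circular_refs: bool = True) -> list[PlasmidCall]:
    """Flag contigs nearly identical to known plasmid-like molecules.

    Circular references are rotated to the best shared anchor before a global
    affine-gap alignment; identity counts gap columns.  With an empty
    reference set every verdict is 'genomic'.
    """
    contigs = as_contigs(contigs)
    aligner = nt_aligner("global")
    calls = []
    for contig in contigs:
        best_ref, best_ident = None, 0.0
        for ref_id, ref_seq in plasmid_refs.items():
            for strand_seq in (contig.seq, revcomp(contig.seq)):
                ref = _rotate_to_anchor(strand_seq, ref_seq) if circular_refs else ref_seq
                if max(len(ref), len(strand_seq)) > 4 * min(len(ref), len(strand_seq)):
                    continue  # grossly different sizes cannot reach the threshold
                ident = alignment_identity(aligner.align(strand_seq, ref)[0])
                if ident > best_ident:
                    best_ref, best_ident = ref_id, ident
        verdict = "plasmid_like" if best_ref is not None and best_ident >= min_identity_pct else "genomic"
        calls.append(PlasmidCall(contig.id, best_ref, round(best_ident, 2), verdict))
    return calls


# ---------------------------------------------------------------------------
# containment


@dataclass(frozen=True)
class Containment:
    inner_id: str
    outer_id: str
    outer_start: int  # 1-based inclusive
    outer_end: int
    strand: Orient
    duplicate: bool = False


def detect_contained(contigs) -> list[Containment]:
    """Contigs whose full sequence (either strand) lies inside another contig.

    Identical (or reverse-complement identical) contigs are reported as
    mutual containments flagged ``duplicate``.
    """
    contigs = as_contigs(contigs)
    out: list[Containment] = []
    for inner in contigs:
        for outer in contigs:
            if inner.id == outer.id or inner.length > outer.length:
                continue
            dup = inner.length == outer.length
            for strand in ("+", "-"):
                probe = inner.seq if strand == "+" else revcomp(inner.seq)
                pos = outer.seq.find(probe)
                if pos != -1:
                    out.append(Containment(inner.id, outer.id, pos + 1,
                                           pos + inner.length, strand, dup))
                    break
    return out


# ---------------------------------------------------------------------------
# smallest-genome assembly


@dataclass
class Subgenome:
    """An ordered, oriented contig path realising one assembled molecule."""

    id: str
    path: list[Node]
    topology: str  # 'linear' | 'circular'
    seq: str
    coord_map: list[tuple[str, Orient, int, int]]  # (contig, orient, start, end) 1-based
    circularizable: bool = False

    @property
    def length(self) -> int:
        return len(self.seq)


@dataclass
class AssemblyResult:
    subgenomes: list[Subgenome]
    unplaced: list[str]
    alternatives: dict[str, list[list[Node]]]
    excluded: list[str]
    diagnostics: list[str] = field(default_factory=list)


def _walk_sequence(path: list[Node], contig_map: dict[str, Contig], k: int):
    seq_parts = [contig_map[path[0][0]].oriented(path[0][1])]
    coord_map = [(path[0][0], path[0][1], 1, contig_map[path[0][0]].length)]
    pos = contig_map[path[0][0]].length
    for cid, orient in path[1:]:
        oseq = contig_map[cid].oriented(orient)
        seq_parts.append(oseq[k:])
        start = pos - k + 1
        pos = start + len(oseq) - 1
        coord_map.append((cid, orient, start, pos))
    return "".join(seq_parts), coord_map


def _mirror(path: list[Node]) -> list[Node]:
    return [(cid, _flip(o)) for cid, o in reversed(path)]


class _WalkSearch:
    """Bounded exhaustive search for the smallest covering walk.

    Depth-first enumeration over oriented nodes with a per-contig copy cap,
    pruned by a simple remaining-length lower bound and a visited-state memo.
    Ties are broken later by lexicographic path order.
    """

    MAX_EXPANSIONS = 500_000

    def __init__(self, comp_ids, joins, lengths, k, max_copies):
        self.ids = sorted(comp_ids)
        self.index = {cid: i for i, cid in enumerate(self.ids)}
        self.lengths = lengths
        self.k = k
        self.max_copies = max_copies
        self.adj: dict[Node, list[Node]] = {}
        for a, b in joins:
            if a[0] in self.index and b[0] in self.index:
                self.adj.setdefault(a, []).append(b)
        for nbrs in self.adj.values():
            nbrs.sort()
        self.best_len: int | None = None
        self.best_walks: list[list[Node]] = []
        self.best_partial: tuple[int, int, list[Node]] | None = None  # (-covered, len, path)
        self.expansions = 0
        self.truncated = False
        self.memo: dict[tuple, int] = {}

    def run(self):
        starts = sorted((cid, o) for cid in self.ids for o in ("+", "-"))
        for start in starts:
            counts = [0] * len(self.ids)
            counts[self.index[start[0]]] = 1
            self._dfs(start, tuple(counts), self.lengths[start[0]], [start])
        return self

    def _record(self, length: int, path: list[Node], covered: int):
        if covered == len(self.ids):
            if self.best_len is None or length < self.best_len:
                self.best_len = length
                self.best_walks = [list(path)]
            elif length == self.best_len and len(self.best_walks) < 64:
                self.best_walks.append(list(path))
        key = (-covered, length)
        if self.best_partial is None or key < self.best_partial[:2]:
            self.best_partial = (-covered, length, list(path))

    def _dfs(self, node: Node, counts: tuple, length: int, path: list[Node]):
        self.expansions += 1
        if self.expansions > self.MAX_EXPANSIONS:
            self.truncated = True
            return
        covered = sum(1 for c in counts if c > 0)
        self._record(length, path, covered)
        bound = length + sum(self.lengths[cid] - self.k
                             for cid, c in zip(self.ids, counts) if c == 0)
        if self.best_len is not None and bound > self.best_len:
            return
        state = (node, counts)
        prev = self.memo.get(state)
        if prev is not None and prev < length:
            return
        self.memo[state] = length if prev is None else min(prev, length)
        for nxt in self.adj.get(node, ()):
            i = self.index[nxt[0]]
            if counts[i] >= self.max_copies:
                continue
            nc = list(counts)
            nc[i] += 1
            path.append(nxt)
            self._dfs(nxt, tuple(nc), length + self.lengths[nxt[0]] - self.k, path)
            path.pop()
            if self.truncated:
                return


def assemble_master(contigs, linkages: list[Linkage],
                    max_copies_per_contig: int = 2,
                    exclude: set[str] | None = None) -> AssemblyResult:
    """Assemble subgenomes as the smallest configuration using every contig.

    Contained contigs are excluded automatically (one representative of each
    identical-duplicate group is kept); further exclusions (e.g. plasmid-like
    contigs) are supplied by the caller.  For every connected component of
    the linkage graph the search enumerates walks that visit each of the
    component's contigs at least once and at most ``max_copies_per_contig``
    times, minimising total molecule length; all co-minimal configurations
    are reported, the lexicographically smallest as the primary path.
    Components with no covering walk are emitted as their best partial
    molecule with a diagnostic.  Contigs with no linkage at all become
    single-contig subgenomes and are listed as unplaced.
    """
    contigs = as_contigs(contigs)
    contig_map = {c.id: c for c in contigs}
    exclude = set(exclude or ())
    diagnostics: list[str] = []

    contained = detect_contained(contigs)
    dup_seen: set[str] = set()
    for cont in contained:
        if cont.duplicate:
            keep = min(cont.inner_id, cont.outer_id)
            drop = max(cont.inner_id, cont.outer_id)
            if keep not in dup_seen:
                dup_seen.add(keep)
            exclude.add(drop)
        else:
            exclude.add(cont.inner_id)
    excluded = sorted(exclude & set(contig_map))

    required = [cid for cid in contig_map if cid not in exclude]
    k = linkages[0].overlap_len if linkages else DEFAULT_OVERLAP
    joins = {(a, b) for a, b in oriented_joins(linkages)
             if a[0] in contig_map and b[0] in contig_map
             and a[0] not in exclude and b[0] not in exclude}

    graph = nx.Graph()
    graph.add_nodes_from(required)
    for (a_id, _), (b_id, _) in joins:
        graph.add_edge(a_id, b_id)

    lengths = {cid: contig_map[cid].length for cid in required}
    walks: list[tuple[list[Node], bool]] = []  # (path, full-coverage?)
    walk_alternatives: list[list[list[Node]]] = []
    unplaced: list[str] = []

    for comp in nx.connected_components(graph):
        comp_ids = sorted(comp)
        comp_joins = {(a, b) for a, b in joins if a[0] in comp}
        if len(comp_ids) == 1 and not comp_joins:
            unplaced.append(comp_ids[0])
            walks.append(([(comp_ids[0], "+")], True))
            walk_alternatives.append([])
            continue
        search = _WalkSearch(comp_ids, comp_joins, lengths, k, max_copies_per_contig).run()
        if search.truncated:
            diagnostics.append(
                f"walk enumeration truncated for component {comp_ids}; result may be partial")
        if search.best_len is not None:
            canon = {}
            for path in search.best_walks:
                canon[tuple(min(path, _mirror(path)))] = None
            ordered = sorted(canon)
            primary = [list(p) for p in ordered][0]
            walks.append((primary, True))
            walk_alternatives.append([list(p) for p in ordered[1:]])
        else:
            _, _, path = search.best_partial
            covered = {cid for cid, _ in path}
            diagnostics.append(
                f"no walk covers all of component {comp_ids} within copy cap "
                f"{max_copies_per_contig}; best partial walk covers {sorted(covered)}")
            walks.append((min(path, _mirror(path)), False))
            walk_alternatives.append([])

    built = []
    for (path, _full), alts in zip(walks, walk_alternatives):
        seq, coord_map = _walk_sequence(path, contig_map, k)
        circ = (path[-1], path[0]) in joins and len(path) > 1
        built.append((seq, path, coord_map, circ, alts))
    built.sort(key=lambda item: (-len(item[0]), item[1]))

    subgenomes = []
    alternatives: dict[str, list[list[Node]]] = {}
    for i, (seq, path, coord_map, circ, alts) in enumerate(built, start=1):
        sub = Subgenome(id=f"subgenome-{i}", path=path, topology="linear",
                        seq=seq, coord_map=coord_map, circularizable=circ)
        subgenomes.append(sub)
        if alts:
            alternatives[sub.id] = alts
    return AssemblyResult(subgenomes=subgenomes, unplaced=sorted(unplaced),
                          alternatives=alternatives, excluded=excluded,
                          diagnostics=diagnostics)
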