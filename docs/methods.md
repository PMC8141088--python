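# Methods

## The problem

Cytoplasmic male sterility (CMS) in plants is caused by mitochondrial open
reading frames that are unique to the sterile cytoplasm.  These loci share
a stereotyped anatomy: they are chimeras of known mitochondrial gene
fragments and novel sequence, they sit downstream of a promoter captured
from an expressed gene (which explains their transcription in anthers),
they encode a protein with at least one transmembrane helix, and they
often sit on a recombinant molecule — a backbone interval substituted by an
insert flanked by short shared sequences — that coexists with the
progenitor-type molecule in the same organelle.  `mitoscreen` implements
the screen that identifies such candidates from an assembled mitogenome
and the sequence-level analogues of the experiments that validate them.

## Assembly from end-overlap contigs

De Bruijn assemblers emit contigs whose adjacent ends share an exact
*k−1*-mer; the package treats overlaps as exact matches only (default
98 bp, the *k* = 99 case).  `find_end_overlaps` indexes both terminal
*k−1*-mers of every contig in both orientations and reports each physical
junction once, canonicalised on the strand whose overlap-mer is
lexicographically smaller; the reverse-orientation twin is derivable from
any linkage.  Contigs shorter than the overlap are skipped with a warning.

Contained contigs (full-length substring of another contig on either
strand) are excluded from assembly paths but retained in reports; exact
duplicates are flagged as mutual containments and one representative is
kept.  Plasmid-like classification rotates each circular reference to the
best shared anchor (first exact 16-mer of the contig found in the doubled
reference), then computes a global affine-gap identity with gap columns in
the denominator; the verdict threshold is ≥ 99%.

`assemble_master` searches for the smallest molecule(s) that use every
remaining contig at least once: a depth-first enumeration over oriented
nodes with a per-contig copy cap (default 2, because plant mitogenomes
carry large repeats that appear twice in one master molecule), pruned by a
remaining-length lower bound and a visited-state memo, with a hard
expansion budget (500,000 states) that degrades to a diagnosed partial
answer rather than hanging.  All co-minimal walks are reported; the
primary path is the lexicographically smallest after mirror
canonicalisation (a walk and its reverse complement are the same
molecule).  Topology is always reported linear; when the two walk ends are
themselves linked the subgenome is flagged `circularizable`, never
silently circularised.  A molecule's length satisfies
`sum(contig lengths) − junctions × overlap` by construction, and the test
suite checks this on every assembly.

Coordinates are 1-based inclusive in every output; internal indices are
0-based half-open.

## The specificity screen

ORFs are ATG-initiated under the universal genetic code (plant mitochondria
use it), minimum 70 aa; per stop-bounded frame segment only the longest
(first-ATG) reading is reported, and ORFs that reach a sequence end without
a stop codon are not called.  Codons containing N are never translated and
break segments.  A `stop_to_stop` convention is available behind a switch
for comparison with annotation tools that use it.  Candidates are named
`orf<aa>`; collisions get letter suffixes.

The discard rule — an ORF is "common" when > 99% identical to a reference
mitogenome region — is implemented with edlib semi-global (infix)
alignment of the whole ORF against each reference on both strands:
identity is matches over alignment columns from the alignment path, and
query coverage is 1.0 by construction, which satisfies the 0.95 coverage
floor.  This choice trades the generality of local alignment for speed on
100–400-kb references; for the screen's purpose it is conservative in the
right direction, since a partially-matching ORF scores lower identity and
is retained as specific.  Presence/absence across the panel calls
`identical` on an exact full-length substring match (either strand),
`partial` when the whole ORF or either half places at ≥ 80% identity, else
`absent`; a candidate is unique when no panel genome has an identical
copy.

## Chimera annotation

Pairwise alignment uses Biopython's `PairwiseAligner`: nucleotides at
match +2 / mismatch −3 / gap open −5 / extend −2, peptides with BLOSUM62
and −11/−1 affine gaps.  Percent identity is always matches / alignment
columns with gap columns counted — this is what makes "overall identity"
between unequal-length sequences well defined.  `annotate_segments`
collects local alignments per donor (both strands, iterative masking of
claimed query intervals, at most 6 rounds per donor) passing the length
(≥ 50 bp) and identity (≥ 70%) floors, then tiles them along the query
greedily by score with ≤ 10 bp overlap slack; an exact
weighted-interval-scheduling tiler is available behind `method="exact"`
for audit.  `longest_exact_match` binary-searches the shared-substring
length with k-mer sets (both strands of the second sequence), breaking
ties by the smallest first-sequence start; it is checked against an
O(n·m) dynamic program in the tests.  `compare_flanking` reports each
difference of a global alignment at its position relative to the start
codon: +1 is the A of ATG, −1 the base immediately upstream, no
position 0.

## Transmembrane prediction

An HMM-based predictor is deliberately not re-implemented; the package
uses the classic Kyte–Doolittle sliding window (19 residues, truncated at
the ends, unknown residues scored 0 with a warning).  Maximal runs with
window mean ≥ 1.6 are merged across gaps of ≤ 3 residues and reported when
≥ 18 residues long.  This recovers helix count and interval, which is the
level at which CMS candidate proteins are compared; posterior
probabilities are out of scope.  Note that raising the threshold can split
one run into two and thereby *increase* the helix count even though the
total residues covered never increases; the tests assert the coverage
monotonicity (at merge gap 0), not a count monotonicity.

## In-silico validation

`apply_substitution` replaces a 1-based inclusive backbone interval with an
insert and verifies the declared shared junction flanks, raising an error
that names the offending junction.  `locate_substitution` recovers an
event from backbone + recombinant via longest common prefix/suffix, exact
whenever the insert diverges from the backbone immediately after its
flanks.  The embedded enzyme table is BamHI G^GATCC, SacI GAGCT^C, NdeI
CA^TATG, NspV TT^CGAA; cut positions come from site occurrences (both
strands for non-palindromic sites), fragments are returned in molecule
order, linear fragment lengths always sum to the molecule length (asserted
on every call), an uncut circle is one flagged fragment, and
`gel_size_kbp` rounds to 2 significant figures for comparison with blot
ladders.  Probe hits are interval intersections, with wrap-around handled
on circles.  `insilico_pcr` finds all convergent primer-landing pairs
(both primer-role arrangements) within a product cap; mismatch-tolerant
landing uses a vectorised Hamming scan, and primers must be ≥ 15 nt.

The pipeline's structure-validation stage needs no truth input: it anchors
the candidate molecule's terminal 98-mers inside the main subgenome
(handling a reverse-complemented molecule), infers the implied
substitution event when both anchors are unique, rebuilds the recombinant,
and reports per-enzyme probed fragment sizes for both structures plus
junction-PCR products that amplify from exactly one structure.

## The synthetic generator

The generator emulates the data situation of a CMS candidate screen, not
real mitochondrial biology in full.  Defaults (all overridable in
`SimConfig`): 120,000-bp genome at GC 0.44 (rice-mitogenome-like; 120 kb
keeps a full multi-seed test run inside a single-CPU budget while staying
in the realistic 100–400-kb organelle range), 20 ATG-initiated genes of
150–450 aa built from sense codons with 200-bp annotated promoters, a
substitution event of 17,911 bp replaced by a 6,141-bp insert (the event
scale the workflow is designed around) with 98-bp shared flanks, a 312-aa
chimeric ORF (novel codons 2–28, hydrophobic Leu/Ile/Val block at residues
29–55, a 48-nt block at codons 34–49 shared verbatim with the cox2 gene,
donor segment covering nt 100–936 of an orf288-like gene at a planted 94%
identity realised as seeded substitutions), a captured rpl5 promoter at
~99% identity directly upstream, a second planted 115-aa novel ORF,
fragmentation into 12 tiles with one duplicated interior tile plus one
212-bp contained contig and three plasmid-like contigs (2,135/1,548/969 bp
at ~99% identity to their circular references), and a 5-genome panel at
0.2% divergence of which 3 carry the second ORF verbatim.  A single seed
drives named independent substreams (reference, CMS derivation,
fragmentation, panel, extras), so outputs are byte-identical per config
and adding one stage never perturbs another.

Three constructions keep the truth manifest exact rather than merely
likely.  First, the duplicated tile is spliced into the molecule and that
rebuilt molecule *is* the progenitor reference — contigs reassemble to
exactly the reference, and the CMS genome differs from it by exactly the
event, which is the relationship the screen presumes.  Second, planted
identities and exact-block lengths are protected: substitutions avoid the
start/stop codons and the hydrophobic/shared-block region, the chimera's
novel hydrophobic codons are drawn ≥ 2 bases away from the donor's
corresponding codons so local alignment cannot blur the planted
breakpoint, and the bases flanking the 48-nt shared block are chosen so
the exact match cannot extend by chance.  Third, the planted ORFs must be
the *only* novel ORFs: the donor gene is drawn free of nested ≥ 70-aa ORFs,
in-frame upstream ATGs in the captured promoter are disrupted (counted as
part of its planted divergence), and any incidental ≥ 70-aa ORF arising in
the insert is broken by planting a stop codon in the offender's own frame
— in spacer sequence where possible, otherwise by a sense-preserving edit
inside a planted ORF's unprotected codons (the realised donor identity is
then recomputed into the manifest).  These repairs are generator
postconditions defining the simulated study condition ("exactly two
specific ORFs exist"), not statistical claims about random sequence.

What the generator does not emulate — and what passing tests therefore do
not show about real data: RNA editing and trans-splicing, repeat-mediated
recombination dynamics and substoichiometric molecules, sequencing error
(the pipeline starts from finished contigs), biased codon usage, and
genes on the reverse strand (all simulated genes are forward-strand for
coordinate simplicity; the screen itself is strand-symmetric and is
tested as such on constructed inputs).

## Determinism and numerical choices

Every random draw in the package flows from explicit
`numpy.random.Generator` streams; pipeline reports contain no timestamps
and serialise with sorted keys, so re-running a config is byte-identical.
Alignment ties are broken deterministically (first-reported optimum;
smallest query interval for exact matches; lexicographic path order for
assemblies).  Identity values are reported to 0.01% internally and rounded
to integers only where a headline percent is conventional.

## Test-suite problem sizes

Oracle-backed checks run at sizes chosen to keep the default suite a
few minutes on one CPU: round-trip assembly on twenty-five 50-kb genomes
(8 tiles, repeat + contained), six-frame ORF oracle on five 10-kb
sequences, the O(n·m) longest-common-substring oracle on few-kb pairs,
the naive digest oracle on 50-kb molecules, and ten full end-to-end
screens at the default 120-kb study conditions.  The accession-based
regression (`mitoscreen.regression`) runs the same measurement chain on
the deposited public records; it requires those FASTAs locally (they are
large third-party sequences and are not bundled), so its acceptance test
is red in a freshly cloned offline tree and documents exactly which files
to fetch.

## Known limitations

The smallest-genome search is exact only within its expansion budget;
pathological linkage graphs (many high-multiplicity repeats) fall back to
a diagnosed best partial answer.  The semi-global screen identity slightly
understates the best local identity for ORFs half-present in a reference,
which can only make the screen more inclusive.  Promoter-capture detection
compares fixed-length upstream windows and assumes annotated reference
promoters.  The hydropathy predictor reports no topology and cannot
distinguish signal anchors from membrane spans.
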