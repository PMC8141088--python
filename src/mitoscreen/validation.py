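"""In-silico validation of recombinant genome structures.

Whether a candidate molecule really sits inside the main genome as a
substitution event — one backbone interval swapped for an insert flanked by
shared sequence — is classically validated by Southern blotting (fragment
sizes predicted by restriction digest, probed near the junctions) and by
linkage PCR across the junctions.  This module performs the sequence-level
part of those experiments:

* :func:`apply_substitution` builds the recombinant molecule and checks the
  shared junction flanks;
* :func:`locate_substitution` recovers an event's coordinates by comparing
  backbone and recombinant;
* :func:`digest` / :func:`probe_fragments` predict restriction fragments and
  which of them a probe detects;
* :func:`insilico_pcr` predicts PCR products for a primer pair.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .seqs import find_all, revcomp

#: recognition site and cut offset (bases 5' of the cut on the top strand)
ENZYMES: dict[str, tuple[str, int]] = {
    "BamHI": ("GGATCC", 1),
    "SacI": ("GAGCTC", 5),
    "NdeI": ("CATATG", 2),
    "NspV": ("TTCGAA", 2),
}


@dataclass(frozen=True)
class SubstitutionEvent:
    """A backbone interval replaced by an insert molecule."""

    backbone_id: str
    start: int  # 1-based inclusive, replaced interval on the backbone
    end: int
    insert_id: str
    left_flank: int = 0   # bp of the insert's 5' end shared with the backbone
    right_flank: int = 0

    @property
    def replaced_len(self) -> int:
        return self.end - self.start + 1

    def recombinant_length(self, backbone_len: int, insert_len: int) -> int:
        return backbone_len - self.replaced_len + insert_len


class JunctionMismatchError(ValueError):
    pass


def apply_substitution(backbone: str, event: SubstitutionEvent, insert: str) -> str:
    """Replace backbone[start..end] (1-based inclusive) with the insert.

    When the event declares shared flanks, the insert's terminal flanks must
    equal the backbone at the corresponding junctions; a mismatch raises
    :class:`JunctionMismatchError` naming the junction.
    """
    if not (1 <= event.start <= event.end <= len(backbone)):
        raise ValueError(f"replaced interval [{event.start},{event.end}] outside backbone")
    s0, e0 = event.start - 1, event.end  # 0-based half-open
    if event.left_flank:
        want = backbone[s0:s0 + event.left_flank]
        if insert[:event.left_flank] != want:
            raise JunctionMismatchError(
                f"left junction: insert 5' {event.left_flank}-bp flank does not match "
                f"backbone {event.start}..{event.start + event.left_flank - 1}")
    if event.right_flank:
        want = backbone[e0 - event.right_flank:e0]
        if insert[-event.right_flank:] != want:
            raise JunctionMismatchError(
                f"right junction: insert 3' {event.right_flank}-bp flank does not match "
                f"backbone {event.end - event.right_flank + 1}..{event.end}")
    return backbone[:s0] + insert + backbone[e0:]


def locate_substitution(backbone: str, recombinant: str,
                        flank_len: int) -> SubstitutionEvent | None:
    """Recover the replaced interval by the junction shared flanks.

    The longest common prefix/suffix of the two molecules end ``flank_len``
    bases into the insert on each side (the shared flanks), which pins the
    replaced backbone interval exactly when the insert's interior diverges
    from the backbone immediately after the flanks.
    """
    limit = min(len(backbone), len(recombinant))
    p = 0
    while p < limit and backbone[p] == recombinant[p]:
        p += 1
    q = 0
    while q < limit - p and backbone[-q - 1] == recombinant[-q - 1]:
        q += 1
    start = p - flank_len + 1
    end = len(backbone) - q + flank_len
    if start < 1 or end > len(backbone) or start > end:
        return None
    return SubstitutionEvent("backbone", start, end, "insert",
                             left_flank=flank_len, right_flank=flank_len)


# ---------------------------------------------------------------------------
# restriction digest


@dataclass(frozen=True)
class RestrictionFragment:
    enzyme: str
    site: str
    start: int   # 1-based inclusive; for a circular wrap fragment start > end
    end: int
    length: int
    probe_hit: bool = False
    uncut: bool = False


def _cut_positions(molecule: str, site: str, offset: int) -> list[int]:
    """0-based positions after which the molecule is cut."""
    cuts = {pos + offset for pos in find_all(molecule, site)}
    rc_site = revcomp(site)
    if rc_site != site:  # non-palindromic: the bottom-strand site also cuts
        cuts |= {pos + (len(site) - offset) for pos in find_all(molecule, rc_site)}
    return sorted(c for c in cuts if 0 < c < len(molecule)) if site else []


def digest(molecule: str, enzymes, topology: str = "linear") -> list[RestrictionFragment]:
    """Predict restriction fragments for one enzyme or a combined digest.

    ``enzymes`` is an enzyme name from :data:`ENZYMES`, a (name, site,
    offset) tuple, or a list of either (a double digest pools the cuts).
    Fragments are returned in molecule order; on a linear molecule their
    lengths sum to the molecule length, on a circular one there are as many
    fragments as cut sites (an uncut circle is one full-length fragment
    flagged ``uncut``).
    """
    if topology not in ("linear", "circular"):
        raise ValueError("topology must be 'linear' or 'circular'")
    if isinstance(enzymes, (str, tuple)):
        enzymes = [enzymes]
    specs = []
    for enz in enzymes:
        if isinstance(enz, str):
            if enz not in ENZYMES:
                raise KeyError(f"unknown enzyme {enz!r}; known: {sorted(ENZYMES)}")
            site, offset = ENZYMES[enz]
            specs.append((enz, site, offset))
        else:
            specs.append(tuple(enz))
    label = "+".join(spec[0] for spec in specs)
    site_label = ",".join(spec[1] for spec in specs)
    molecule = molecule.upper()
    cuts = sorted({c for _, site, offset in specs
                   for c in _cut_positions(molecule, site.upper(), offset)})
    n = len(molecule)
    fragments: list[RestrictionFragment] = []
    if topology == "linear":
        bounds = [0] + cuts + [n]
        for lo, hi in zip(bounds, bounds[1:]):
            fragments.append(RestrictionFragment(label, site_label, lo + 1, hi, hi - lo))
    else:
        if not cuts:
            return [RestrictionFragment(label, site_label, 1, n, n, uncut=True)]
        for i, lo in enumerate(cuts):
            hi = cuts[(i + 1) % len(cuts)]
            length = (hi - lo) % n or n
            end = hi if hi > lo else hi  # wrap fragment keeps start > end
            fragments.append(RestrictionFragment(label, site_label, lo + 1, end, length))
        fragments.sort(key=lambda f: f.start)
    assert topology == "circular" or sum(f.length for f in fragments) == n
    return fragments


def gel_size_kbp(length_bp: int) -> float:
    """Gel-style fragment size: kbp rounded to 2 significant figures."""
    kbp = length_bp / 1000.0
    if kbp == 0:
        return 0.0
    from math import floor, log10
    digits = 1 - floor(log10(abs(kbp)))
    return round(kbp, digits)


def probe_fragments(fragments: list[RestrictionFragment],
                    probe_start: int, probe_end: int,
                    molecule_length: int | None = None) -> list[RestrictionFragment]:
    """Set ``probe_hit`` on fragments intersecting the probe interval
    (1-based inclusive).  Handles circular wrap fragments when
    ``molecule_length`` is given."""
    if probe_start > probe_end:
        raise ValueError("probe interval reversed")
    out = []
    for frag in fragments:
        if frag.start <= frag.end:
            hit = frag.start <= probe_end and probe_start <= frag.end
        else:  # wraps the origin
            if molecule_length is None:
                raise ValueError("molecule_length needed for circular wrap fragments")
            hit = probe_end >= frag.start or probe_start <= frag.end
        out.append(replace(frag, probe_hit=hit))
    return out


def southern_prediction(backbone: str, recombinant: str, enzyme,
                        probe_on_backbone: tuple[int, int],
                        probe_on_recombinant: tuple[int, int],
                        topology: str = "linear"):
    """Fragment sizes a junction probe detects on each molecule.

    Two coexisting genome structures produce two band sets; their multiset
    difference is the diagnostic signal.
    """
    sizes = {}
    for name, mol, probe in (("backbone", backbone, probe_on_backbone),
                             ("recombinant", recombinant, probe_on_recombinant)):
        frags = probe_fragments(digest(mol, enzyme, topology), probe[0], probe[1],
                                molecule_length=len(mol))
        sizes[name] = sorted(f.length for f in frags if f.probe_hit)
    return sizes


# ---------------------------------------------------------------------------
# in-silico PCR


@dataclass(frozen=True)
class PcrProduct:
    start: int   # 1-based inclusive, 5' end of the left primer on the template
    end: int     # 1-based inclusive, 5'-end complement of the right primer
    length: int
    left_primer: str   # 'fwd' | 'rev' — which primer acts as the left primer
    mismatches: int


def _primer_sites(template: str, primer: str, max_mismatch: int) -> list[tuple[int, int]]:
    """(0-based position, mismatch count) of primer landings on the + strand."""
    n, m = len(template), len(primer)
    if m > n:
        return []
    if max_mismatch == 0:
        return [(p, 0) for p in find_all(template, primer)]
    t = np.frombuffer(template.encode(), dtype=np.uint8)
    p = np.frombuffer(primer.encode(), dtype=np.uint8)
    mism = np.zeros(n - m + 1, dtype=np.int32)
    for j in range(m):
        mism += t[j:j + n - m + 1] != p[j]
    return [(int(i), int(mism[i])) for i in np.nonzero(mism <= max_mismatch)[0]]


def insilico_pcr(template: str, fwd_primer: str, rev_primer: str,
                 max_product: int = 8000, max_mismatch: int = 0) -> list[PcrProduct]:
    """All products a convergent primer pair yields on a linear template.

    A product spans from the 5' end of the left-annealing primer to the
    5'-end complement of the right-annealing primer; both arrangements
    (forward primer left, reverse primer left) are considered.
    """
    fwd, rev = fwd_primer.upper(), rev_primer.upper()
    if len(fwd) < 15 or len(rev) < 15:
        raise ValueError("primers must be at least 15 nt")
    template = template.upper()
    products = []
    for left, right, tag in ((fwd, rev, "fwd"), (rev, fwd, "rev")):
        left_sites = _primer_sites(template, left, max_mismatch)
        right_sites = _primer_sites(template, revcomp(right), max_mismatch)
        for i, mm_l in left_sites:
            for j, mm_r in right_sites:
                end = j + len(right)
                length = end - i
                if length < max(len(left), len(right)) or length > max_product:
                    continue
                products.append(PcrProduct(i + 1, end, length, tag, mm_l + mm_r))
    products.sort(key=lambda p: (p.start, p.end, p.left_primer))
    return products
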