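"""Small DNA sequence utilities shared across the package.

Coordinates follow the package-wide convention: all user-facing intervals
are 1-based inclusive; internal indices are 0-based half-open.
"""

from __future__ import annotations

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (N-safe)."""
    return seq.translate(_COMPLEMENT)[::-1]


def gc_fraction(seq: str) -> float:
    if not seq:
        return 0.0
    return (seq.count("G") + seq.count("C")) / len(seq)


def find_all(haystack: str, needle: str, overlapping: bool = True) -> list[int]:
    """All 0-based occurrence positions of ``needle`` in ``haystack``."""
    out = []
    i = haystack.find(needle)
    step = 1 if overlapping else max(len(needle), 1)
    while i != -1:
        out.append(i)
        i = haystack.find(needle, i + step)
    return out
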