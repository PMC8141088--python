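"""Sliding-window hydropathy prediction of transmembrane helices.

A Kyte-Doolittle window predictor: per-residue hydropathy values are
averaged over a centred window (default 19 residues, the classic
membrane-span window), maximal runs of residues above a threshold are
merged across short dips and reported as candidate transmembrane helices.

This is an explicit, documented substitute for HMM-based predictors such as
TMHMM: it recovers helix count and approximate interval, not posterior
probabilities, which is the level at which candidate CMS proteins are
compared.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

logger = logging.getLogger(__name__)

#: Kyte & Doolittle (1982) hydropathy scale.
KYTE_DOOLITTLE = {
    "A": 1.8, "R": -4.5, "N": -3.5, "D": -3.5, "C": 2.5,
    "Q": -3.5, "E": -3.5, "G": -0.4, "H": -3.2, "I": 4.5,
    "L": 3.8, "K": -3.9, "M": 1.9, "F": 2.8, "P": -1.6,
    "S": -0.8, "T": -0.7, "W": -0.9, "Y": -1.3, "V": 4.2,
}

DEFAULT_WINDOW = 19


@dataclass(frozen=True)
class TmHelix:
    start_aa: int  # 1-based inclusive
    end_aa: int
    mean_hydropathy: float

    @property
    def length(self) -> int:
        return self.end_aa - self.start_aa + 1


def hydropathy_profile(peptide: str, window: int = DEFAULT_WINDOW) -> np.ndarray:
    """Centred moving average of residue hydropathy; truncated windows at
    the ends.  Unknown residues score 0 with a warning."""
    if len(peptide) < window:
        raise ValueError(f"peptide ({len(peptide)} aa) shorter than window {window}")
    values = np.empty(len(peptide))
    for i, res in enumerate(peptide.upper()):
        if res not in KYTE_DOOLITTLE:
            logger.warning("unknown residue %r at position %d scored 0", res, i + 1)
            values[i] = 0.0
        else:
            values[i] = KYTE_DOOLITTLE[res]
    half = window // 2
    csum = np.concatenate(([0.0], np.cumsum(values)))
    n = len(values)
    idx = np.arange(n)
    lo = np.maximum(idx - half, 0)
    hi = np.minimum(idx + half + 1, n)
    return (csum[hi] - csum[lo]) / (hi - lo)


def predict_tm(peptide: str, threshold: float = 1.6, min_len: int = 18,
               merge_gap: int = 3, window: int = DEFAULT_WINDOW) -> list[TmHelix]:
    """Maximal above-threshold runs of the hydropathy profile.

    Runs separated by at most ``merge_gap`` residues are merged; merged runs
    shorter than ``min_len`` are dropped.  Helices are disjoint and sorted.
    """
    profile = hydropathy_profile(peptide, window=window)
    above = profile >= threshold
    runs: list[list[int]] = []
    i = 0
    n = len(above)
    while i < n:
        if above[i]:
            j = i
            while j + 1 < n and above[j + 1]:
                j += 1
            if runs and i - runs[-1][1] - 1 <= merge_gap:
                runs[-1][1] = j
            else:
                runs.append([i, j])
            i = j + 1
        else:
            i += 1
    helices = []
    for start, end in runs:
        if end - start + 1 >= min_len:
            helices.append(TmHelix(start + 1, end + 1,
                                   float(np.round(profile[start:end + 1].mean(), 3))))
    return helices
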