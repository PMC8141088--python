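"""Independent brute-force oracles the implementation is checked against.

These deliberately use the most naive possible formulation of each
operation; they share no code path with the package internals they verify.
"""

import numpy as np

COMP = str.maketrans("ACGTN", "TGCAN")
STOPS = {"TAA", "TAG", "TGA"}


def rc(seq: str) -> str:
    return seq.translate(COMP)[::-1]


def orf_scan(seq: str, min_aa: int):
    """Six-frame ORF scan: walk every ATG forward to a stop, then keep only
    the earliest ATG per (strand, stop) segment.  Returns a set of
    (start, end, strand) 1-based forward-strand intervals."""
    found = {}
    L = len(seq)
    for strand in ("+", "-"):
        s = seq if strand == "+" else rc(seq)
        for i in range(L - 2):
            if s[i:i + 3] != "ATG":
                continue
            j = i
            stop = None
            while j + 3 <= L:
                codon = s[j:j + 3]
                if "N" in codon:
                    break
                if codon in STOPS:
                    stop = j
                    break
                j += 3
            if stop is None:
                continue
            aa = (stop - i) // 3
            if aa < min_aa:
                continue
            key = (strand, stop)
            if key not in found or i < found[key]:
                found[key] = i
    out = set()
    for (strand, stop), i in found.items():
        lo, hi = i, stop + 3  # 0-based half-open on the oriented strand
        if strand == "+":
            out.add((lo + 1, hi, "+"))
        else:
            out.add((L - hi + 1, L - lo, "-"))
    return out


def longest_common_substring(a: str, b: str) -> int:
    """Classic O(n*m) dynamic program (numpy row recurrence), considering b
    on both strands; returns the length only."""
    best = 0
    aa = np.frombuffer(a.encode(), dtype=np.uint8)
    for bseq in (b, rc(b)):
        bb = np.frombuffer(bseq.encode(), dtype=np.uint8)
        prev = np.zeros(len(bb), dtype=np.int32)
        for ch in aa:
            cur = np.zeros(len(bb), dtype=np.int32)
            eq = bb == ch
            cur[eq] = 1
            cur[1:][eq[1:]] += prev[:-1][eq[1:]]
            best = max(best, int(cur.max(initial=0)))
            prev = cur
    return best


def digest_sites(seq: str, site: str, offset: int):
    """Cut positions by sliding a window over every position."""
    cuts = set()
    for i in range(len(seq) - len(site) + 1):
        if seq[i:i + len(site)] == site:
            cuts.add(i + offset)
        if seq[i:i + len(site)] == rc(site) and rc(site) != site:
            cuts.add(i + len(site) - offset)
    return sorted(c for c in cuts if 0 < c < len(seq))


def all_walks_min_length(contigs: dict[str, str], joins, k: int, max_copies: int):
    """Exhaustive enumeration of covering walks (no pruning, no memo);
    returns the minimal total molecule length, or None if infeasible."""
    ids = sorted(contigs)
    adj = {}
    for a, b in joins:
        adj.setdefault(a, []).append(b)
    best = [None]

    def rec(node, counts, length):
        if all(counts[c] > 0 for c in ids):
            if best[0] is None or length < best[0]:
                best[0] = length
        for nxt in adj.get(node, []):
            if counts[nxt[0]] >= max_copies:
                continue
            counts[nxt[0]] += 1
            rec(nxt, counts, length + len(contigs[nxt[0]]) - k)
            counts[nxt[0]] -= 1

    for cid in ids:
        for orient in ("+", "-"):
            counts = {c: 0 for c in ids}
            counts[cid] = 1
            rec((cid, orient), counts, len(contigs[cid]))
    return best[0]


def primer_landings(template: str, primer: str):
    return [i for i in range(len(template) - len(primer) + 1)
            if template[i:i + len(primer)] == primer]
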