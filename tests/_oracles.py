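"""Independent brute-force oracles used by the test suite.

These deliberately avoid the library's code paths: alignment scores come
from exhaustive enumeration of alignment paths, codon consequences from a
hard-coded genetic-code table, Fisher p-values from explicit hypergeometric
tail sums, and chain scores from subset enumeration.
"""

from __future__ import annotations

import itertools
from math import comb

# --- standard genetic code, written out independently -----------------------

_CODE_BLOCK = """
TTT F TTC F TTA L TTG L CTT L CTC L CTA L CTG L
ATT I ATC I ATA I ATG M GTT V GTC V GTA V GTG V
TCT S TCC S TCA S TCG S CCT P CCC P CCA P CCG P
ACT T ACC T ACA T ACG T GCT A GCC A GCA A GCG A
TAT Y TAC Y TAA * TAG * CAT H CAC H CAA Q CAG Q
AAT N AAC N AAA K AAG K GAT D GAC D GAA E GAG E
TGT C TGC C TGA * TGG W CGT R CGC R CGA R CGG R
AGT S AGC S AGA R AGG R GGT G GGC G GGA G GGG G
"""

GENETIC_CODE = dict(zip(_CODE_BLOCK.split()[0::2], _CODE_BLOCK.split()[1::2]))


def codon_consequence_oracle(codon: str, pos: int, alt: str) -> str:
    """Translate-and-compare verdict for a single-base codon change."""
    mutated = codon[: pos - 1] + alt + codon[pos:]
    return (
        "synonymous"
        if GENETIC_CODE[codon] == GENETIC_CODE[mutated]
        else "nonsynonymous"
    )


def translate_oracle(nt: str) -> str:
    """Codon-walk translation; N-containing codons -> X, stops -> *."""
    out = []
    for i in range(0, len(nt) - len(nt) % 3, 3):
        codon = nt[i : i + 3].upper()
        out.append(GENETIC_CODE.get(codon, "X"))
    return "".join(out)


# --- exhaustive local alignment ---------------------------------------------


def _global_score_enum(a: str, b: str, matrix, gap_open: int, gap_extend: int):
    """Max global alignment score of a vs b by enumerating every path.

    Affine convention: a gap run of length k costs gap_open + k*gap_extend.
    Returns None when either string is empty and the other is not (pure-gap
    alignments are covered by substring enumeration in the caller).
    """
    best = [None]

    def rec(i: int, j: int, score: float, prev: str) -> None:
        if i == len(a) and j == len(b):
            if best[0] is None or score > best[0]:
                best[0] = score
            return
        if i < len(a) and j < len(b):
            rec(i + 1, j + 1, score + matrix[a[i], b[j]], "m")
        if i < len(a):
            cost = gap_extend + (gap_open if prev != "a" else 0)
            rec(i + 1, j, score - cost, "a")
        if j < len(b):
            cost = gap_extend + (gap_open if prev != "b" else 0)
            rec(i, j + 1, score - cost, "b")

    rec(0, 0, 0.0, "m")
    return best[0]


def smith_waterman_oracle(
    q: str, s: str, matrix, gap_open: int = 11, gap_extend: int = 1
) -> float:
    """Best local alignment score: max over all substring pairs of the
    enumerated global score, floored at 0."""
    best = 0.0
    for i1, j1 in itertools.combinations(range(len(q) + 1), 2):
        for i2, j2 in itertools.combinations(range(len(s) + 1), 2):
            g = _global_score_enum(q[i1:j1], s[i2:j2], matrix, gap_open, gap_extend)
            if g is not None and g > best:
                best = g
    return best


# --- Fisher exact (one-sided, over-representation) ---------------------------


def fisher_greater_oracle(a: int, b: int, c: int, d: int) -> float:
    """P(X >= a) for X hypergeometric with a+b draws, a+c successes, n total."""
    n = a + b + c + d
    draws, successes = a + b, a + c
    denom = comb(n, draws)
    p = 0.0
    for k in range(a, min(draws, successes) + 1):
        if draws - k > n - successes:
            continue
        p += comb(successes, k) * comb(n - successes, draws - k) / denom
    return min(1.0, p)


# --- collinear chain enumeration ---------------------------------------------


def best_chain_size_oracle(points: list[tuple[float, float]], max_gap: float) -> int:
    """Max cardinality of a valid collinear chain, by subset enumeration.

    A subset is a valid chain iff, sorted by x, both coordinates strictly
    increase and consecutive gaps on both axes are <= max_gap.
    """
    best = 0
    n = len(points)
    for mask in range(1, 1 << n):
        subset = sorted(
            (points[i] for i in range(n) if mask & (1 << i)),
        )
        ok = True
        for (x0, y0), (x1, y1) in zip(subset, subset[1:]):
            if not (x0 < x1 and y0 < y1 and x1 - x0 <= max_gap and y1 - y0 <= max_gap):
                ok = False
                break
        if ok:
            best = max(best, len(subset))
    return best
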