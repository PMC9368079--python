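"""Independent brute-force oracles used by the test suite.

These deliberately avoid the code paths they check: exact rational
arithmetic for the combinatorial tests, direct window enumeration for
seed sites, and naive scans for string matching.
"""

from __future__ import annotations

from fractions import Fraction
from math import comb

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "U": "A"}


def fisher_two_sided_oracle(a: int, b: int, c: int, d: int) -> Fraction:
    """Two-sided Fisher p by enumerating every 2x2 table with the observed
    margins, in exact rational arithmetic."""
    r1, r2, c1 = a + b, c + d, a + c
    n = r1 + r2
    if r1 == 0 or r2 == 0 or c1 == 0 or c1 == n:
        return Fraction(1)
    denom = comb(n, c1)
    tables = []
    for k in range(0, c1 + 1):
        if k <= r1 and c1 - k <= r2:
            tables.append(Fraction(comb(r1, k) * comb(r2, c1 - k), denom))
    obs = Fraction(comb(r1, a) * comb(r2, c), denom)
    p = sum(t for t in tables if t <= obs)
    return min(p, Fraction(1))


def hypergeom_upper_tail_oracle(N: int, K: int, n: int, k: int) -> Fraction:
    """P(X >= k) for X ~ Hypergeometric(N, K, n), exact rational."""
    denom = comb(N, n)
    total = Fraction(0)
    for i in range(k, min(K, n) + 1):
        if n - i <= N - K:
            total += Fraction(comb(K, i) * comb(N - K, n - i), denom)
    return total


def revcomp_oracle(seq: str) -> str:
    return "".join(_COMP[b] for b in reversed(seq.upper()))


def seed_sites_oracle(mirna: str, utr: str, allow_6mer: bool = False):
    """Enumerate canonical seed sites by direct window comparison.

    Returns a list of (start, end, site_type) tuples in UTR order,
    reporting the strongest applicable type at each offset.
    """
    m = mirna.upper().replace("U", "T")
    u = utr.upper().replace("U", "T")
    sites = []
    for i in range(len(u)):
        # does u[i:i+7] pair positions 2..8?  site runs 3'->5' on the miRNA
        def pairs(span, mir_positions):
            if i + span > len(u):
                return False
            for off in range(span):
                mp = mir_positions - off  # 1-based miRNA position
                if _COMP[m[mp - 1]] != u[i + off]:
                    return False
            return True

        if pairs(7, 8):
            if i + 7 < len(u) and u[i + 7] == "A":
                sites.append((i, i + 8, "8mer"))
            else:
                sites.append((i, i + 7, "7mer-m8"))
            continue
        if pairs(6, 7):
            if i + 6 < len(u) and u[i + 6] == "A":
                sites.append((i, i + 7, "7mer-A1"))
            elif allow_6mer:
                sites.append((i, i + 6, "6mer"))
    return sites


def best_adapter_position_oracle(read: str, adapter: str, min_overlap: int,
                                 max_rate: float) -> int:
    """Leftmost adapter start position meeting the mismatch-rate gate,
    scanning every start position naively; -1 when none."""
    for p in range(len(read) - min_overlap + 1):
        overlap = min(len(adapter), len(read) - p)
        if overlap < min_overlap:
            break
        mm = sum(1 for x, y in zip(read[p:p + overlap], adapter[:overlap])
                 if x != y)
        if mm <= int(max_rate * overlap):
            return p
    return -1
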