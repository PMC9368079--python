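"""Minimum-free-energy folding of single RNA hairpins.

Novel-miRNA calling only ever needs the best *single stem-loop* a candidate
locus can form: a chain of nested base pairs (the stem, possibly interrupted
by bulges and internal loops) closed by one terminal loop.  The default
backend here computes that structure exactly by dynamic programming under a
nearest-neighbour model: Watson-Crick and G:U pairs, Turner-style stacking
free energies for adjacent pairs, and size-dependent initiation penalties
for hairpin loops, bulges and internal loops.  Multibranch structures are
deliberately outside the model.

The energy unit throughout is kcal/mol at 37 degC.  A structure is reported
only when its free energy is negative; otherwise the open chain (zero pairs,
zero energy) is returned.

Any folder producing a dot-bracket string plus an energy can stand in as a
backend; ``fold_hairpin(seq, backend="vienna")`` delegates to the ViennaRNA
bindings when they are installed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from numba import njit

_RT37 = 0.0019872 * 310.15  # kcal/mol

# nucleotide codes: A=0 C=1 G=2 T/U=3
_CODE = {"A": 0, "C": 1, "G": 2, "T": 3, "U": 3}

# pair type indices for the 6 admissible pairs
_PAIR_NAMES = ["AU", "UA", "CG", "GC", "GU", "UG"]
PAIR_INDEX = np.full((4, 4), -1, dtype=np.int8)
PAIR_INDEX[0, 3] = 0  # A:U
PAIR_INDEX[3, 0] = 1  # U:A
PAIR_INDEX[1, 2] = 2  # C:G
PAIR_INDEX[2, 1] = 3  # G:C
PAIR_INDEX[2, 3] = 4  # G:U
PAIR_INDEX[3, 2] = 5  # U:G

# Stacking free energies dG37 for helix 5'-XY-3' / 3'-X'Y'-5', indexed by
# (outer pair X:X', inner pair Y:Y').  Watson-Crick entries follow the
# standard Turner nearest-neighbour set; wobble-containing stacks use
# representative averaged values (one G:U pair ~ -1.2, two ~ -0.5), which is
# adequate for classification work where only the stability *class* of a
# stem matters.
_WC = {
    ("AU", "AU"): -0.93,
    ("AU", "UA"): -1.10,
    ("AU", "CG"): -2.24,
    ("AU", "GC"): -2.08,
    ("UA", "AU"): -1.33,
    ("UA", "UA"): -0.93,
    ("UA", "CG"): -2.35,
    ("UA", "GC"): -2.11,
    ("CG", "AU"): -2.11,
    ("CG", "UA"): -2.08,
    ("CG", "CG"): -3.26,
    ("CG", "GC"): -2.36,
    ("GC", "AU"): -2.35,
    ("GC", "UA"): -2.24,
    ("GC", "CG"): -3.42,
    ("GC", "GC"): -3.26,
}

STACK = np.zeros((6, 6), dtype=np.float64)
for _i, _pi in enumerate(_PAIR_NAMES):
    for _j, _pj in enumerate(_PAIR_NAMES):
        if (_pi, _pj) in _WC:
            STACK[_i, _j] = _WC[(_pi, _pj)]
        else:
            n_wobble = (_pi in ("GU", "UG")) + (_pj in ("GU", "UG"))
            STACK[_i, _j] = -1.2 if n_wobble == 1 else -0.5

_MAXLEN = 1024  # longest loop for which penalties are tabulated

def _extrapolate(table: dict[int, float], nmax: int) -> np.ndarray:
    out = np.zeros(nmax, dtype=np.float64)
    last = max(table)
    for n in range(1, nmax):
        if n in table:
            out[n] = table[n]
        elif n < min(table):
            out[n] = table[min(table)]
        else:
            out[n] = table[last] + 1.75 * _RT37 * math.log(n / last)
    return out

# loop initiation penalties (kcal/mol), Jacobson-Stockmayer extrapolation
HAIRPIN_INIT = _extrapolate({3: 5.4, 4: 5.6, 5: 5.7, 6: 5.4, 7: 6.0, 8: 5.5, 9: 6.4}, _MAXLEN)
BULGE_INIT = _extrapolate({1: 3.8, 2: 2.8, 3: 3.2, 4: 3.6, 5: 4.0, 6: 4.4}, _MAXLEN)
INTERNAL_INIT = _extrapolate({2: 1.0, 3: 1.9, 4: 1.1, 5: 2.0, 6: 1.9, 7: 2.1, 8: 2.3, 9: 2.4, 10: 2.5}, _MAXLEN)

INTERNAL_ASYMMETRY = 0.6   # per unpaired-count difference, capped
INTERNAL_ASYMMETRY_MAX = 3.0
MIN_HAIRPIN_LOOP = 3
MAX_LOOP_SIDE = 30         # bulge / internal-loop side length bound in the DP


class FoldingError(ValueError):
    pass


def encode(seq: str) -> np.ndarray:
    """Encode a DNA/RNA string as int8 codes (A=0 C=1 G=2 T/U=3)."""
    try:
        return np.array([_CODE[b] for b in seq.upper()], dtype=np.int8)
    except KeyError as exc:
        raise FoldingError(f"non-ACGTU base in sequence: {exc.args[0]!r}") from None


@njit(cache=True)
def _fold_kernel(codes, pair_index, stack, hp_init, bulge_init, internal_init):
    n = codes.size
    INF = 1e9
    E = np.full((n, n), INF, dtype=np.float64)
    bk = np.full((n, n), -1, dtype=np.int32)
    bl = np.full((n, n), -1, dtype=np.int32)
    for span in range(MIN_HAIRPIN_LOOP + 1, n):
        for i in range(0, n - span):
            j = i + span
            p = pair_index[codes[i], codes[j]]
            if p < 0:
                continue
            # close a hairpin loop
            best = hp_init[j - i - 1]
            bbk = -1
            bbl = -1
            kmax = i + 1 + MAX_LOOP_SIDE
            for k in range(i + 1, j - MIN_HAIRPIN_LOOP - 1):
                if k > kmax:
                    break
                n1 = k - i - 1
                lmin = j - 1 - MAX_LOOP_SIDE
                for l in range(j - 1, k + MIN_HAIRPIN_LOOP, -1):
                    if l < lmin:
                        break
                    if E[k, l] >= INF:
                        continue
                    q = pair_index[codes[k], codes[l]]
                    if q < 0:
                        continue
                    n2 = j - l - 1
                    if n1 == 0 and n2 == 0:
                        e = stack[p, q]
                    elif n1 == 0 or n2 == 0:
                        nb = n1 + n2
                        e = bulge_init[nb]
                        if nb == 1:
                            e += stack[p, q]  # single-nt bulges keep coaxial stacking
                    else:
                        asym = INTERNAL_ASYMMETRY * abs(n1 - n2)
                        if asym > INTERNAL_ASYMMETRY_MAX:
                            asym = INTERNAL_ASYMMETRY_MAX
                        e = internal_init[n1 + n2] + asym
                    tot = E[k, l] + e
                    if tot < best - 1e-9:
                        best = tot
                        bbk = k
                        bbl = l
            E[i, j] = best
            bk[i, j] = bbk
            bl[i, j] = bbl
    return E, bk, bl


@dataclass
class HairpinStructure:
    """A folded single hairpin: sequence, pair list and free energy."""

    sequence: str
    dotbracket: str
    mfe: float
    pairs: list[tuple[int, int]] = field(default_factory=list)
    backend: str = "nn"

    @property
    def n_pairs(self) -> int:
        return len(self.pairs)

    def vienna_lines(self) -> str:
        """Vienna-format record: sequence line, then structure with energy."""
        return f"{self.sequence}\n{self.dotbracket} ({self.mfe:6.2f})"


def _empty(seq: str, backend: str = "nn") -> HairpinStructure:
    return HairpinStructure(seq, "." * len(seq), 0.0, [], backend)


def fold_hairpin(seq: str, backend: str = "nn") -> HairpinStructure:
    """Fold ``seq`` into its minimum-free-energy single hairpin.

    Returns the open chain (no pairs, mfe 0) when no structure with
    negative free energy exists.
    """
    if backend == "nn":
        return _fold_nn(seq)
    if backend == "vienna":
        return _fold_vienna(seq)
    raise FoldingError(f"unknown folding backend {backend!r}")


def _fold_nn(seq: str) -> HairpinStructure:
    codes = encode(seq)
    n = codes.size
    if n < MIN_HAIRPIN_LOOP + 2:
        return _empty(seq)
    E, bk, bl = _fold_kernel(codes, PAIR_INDEX, STACK, HAIRPIN_INIT, BULGE_INIT, INTERNAL_INIT)
    # outermost closing pair of the best hairpin
    best = 0.0
    bi = bj = -1
    for i in range(n):
        for j in range(i + MIN_HAIRPIN_LOOP + 1, n):
            if E[i, j] < best - 1e-9:
                best = E[i, j]
                bi, bj = i, j
    if bi < 0:
        return _empty(seq)
    pairs: list[tuple[int, int]] = []
    i, j = bi, bj
    while i >= 0:
        pairs.append((i, j))
        i, j = int(bk[i, j]), int(bl[i, j])
    db = ["."] * n
    for a, b in pairs:
        db[a] = "("
        db[b] = ")"
    return HairpinStructure(seq, "".join(db), round(float(best), 2), pairs, "nn")


def _fold_vienna(seq: str) -> HairpinStructure:
    try:
        import RNA
    except ImportError as exc:  # pragma: no cover
        raise FoldingError("ViennaRNA python bindings are not installed") from exc
    rna = seq.upper().replace("T", "U")
    db, mfe = RNA.fold(rna)
    pairs = pairs_from_dotbracket(db)
    return HairpinStructure(seq, db, float(mfe), pairs, "vienna")


def pairs_from_dotbracket(db: str) -> list[tuple[int, int]]:
    stack: list[int] = []
    pairs: list[tuple[int, int]] = []
    for i, c in enumerate(db):
        if c == "(":
            stack.append(i)
        elif c == ")":
            if not stack:
                raise FoldingError("unbalanced dot-bracket string")
            pairs.append((stack.pop(), i))
    if stack:
        raise FoldingError("unbalanced dot-bracket string")
    return sorted(pairs)
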