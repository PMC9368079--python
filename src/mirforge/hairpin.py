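"""Stem-loop feature extraction and the 11-criterion novel-miRNA call.

A candidate miRNA locus (a genome-mapped read tag plus 80 nt of flank on
each side) is folded and the resulting hairpin measured against eleven
secondary-structure criteria.  A locus is called a novel miRNA hairpin only
when *all* criteria hold.

Operational definitions adopted here (the terms are standard in miRNA
discovery pipelines but rarely written down precisely):

* a *bulge* is any run of unpaired nucleotides between two consecutive
  stem pairs (a one-sided bulge proper or a two-sided internal loop); its
  size is the total number of unpaired nucleotides on both strands;
* a bulge is *biased* when its unpaired nucleotides lie on one strand only;
* an *error* in the mature region is an unpaired mature-arm position;
* a bulge is "in the mature region" when at least one of its unpaired
  positions falls inside the mature interval;
* *maturity in the stem* is the fraction of mature positions lying within
  the stem (the folded span minus the terminal loop);
* base pairs "in the mature region" are pairs with at least one partner
  inside the mature interval.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .fold import HairpinStructure, fold_hairpin

CRITERION_NAMES = [f"c{i}" for i in range(1, 12)]

CRITERION_DESCRIPTIONS = {
    "c1": "<=12 nt in any one bulge in the stem",
    "c2": "free energy <= -15 kcal/mol",
    "c3": "terminal loop <= 20 nt",
    "c4": "<=4 biased errors in any one bulge in the mature region",
    "c5": "<=7 errors (unpaired nt) in the mature region",
    "c6": ">=80% of the mature region within the stem",
    "c7": ">16 base pairs in the stem",
    "c8": "hairpin length (up stem + down stem + terminal loop) >= 50 nt",
    "c9": "<=8 nt in any one bulge in the mature region",
    "c10": "<=2 biased bulges in the mature region",
    "c11": ">=12 base pairs in the mature region",
}


@dataclass
class Bulge:
    """Unpaired interruption between two consecutive stem pairs."""

    five_prime: tuple[int, int]   # half-open interval of unpaired nt, 5' strand
    three_prime: tuple[int, int]  # half-open interval of unpaired nt, 3' strand
    n5: int
    n3: int
    in_mature: bool = False
    mature_unpaired: int = 0      # unpaired positions of this bulge inside the mature

    @property
    def size(self) -> int:
        return self.n5 + self.n3

    @property
    def biased(self) -> bool:
        return (self.n5 == 0) != (self.n3 == 0)


@dataclass
class HairpinFeatures:
    mfe: float
    n_stem_pairs: int
    terminal_loop_len: int
    hairpin_len: int
    max_stem_bulge: int
    mature_errors: int
    maturity_in_stem: float       # fraction in [0, 1]
    max_mature_bulge: int
    max_biased_mature_bulge: int
    n_biased_mature_bulges: int
    pairs_in_mature: int
    mature_in_span: bool
    bulges: list[Bulge] = field(default_factory=list)


@dataclass
class HairpinVerdict:
    criteria: dict[str, bool]

    @property
    def overall(self) -> bool:
        return all(self.criteria.values())

    @property
    def failing(self) -> list[str]:
        return [c for c in CRITERION_NAMES if not self.criteria[c]]

    def __getattr__(self, name):
        crit = self.__dict__.get("criteria", {})
        if name in crit:
            return crit[name]
        raise AttributeError(name)


@dataclass(frozen=True)
class CriteriaThresholds:
    """Cutoffs for the 11 structure criteria (comparators are fixed)."""

    max_stem_bulge: int = 12          # c1, <=
    max_mfe: float = -15.0            # c2, <=
    max_terminal_loop: int = 20       # c3, <=
    max_biased_bulge_errors: int = 4  # c4, <=
    max_mature_errors: int = 7        # c5, <=
    min_maturity_in_stem: float = 0.80  # c6, >=
    min_stem_pairs: int = 16          # c7, strict >
    min_hairpin_len: int = 50         # c8, >=
    max_mature_bulge: int = 8         # c9, <=
    max_biased_mature_bulges: int = 2  # c10, <=
    min_mature_pairs: int = 12        # c11, >=


DEFAULT_THRESHOLDS = CriteriaThresholds()


def _nested_chain(pairs: list[tuple[int, int]], mature: tuple[int, int]) -> list[tuple[int, int]]:
    """Select the maximal nesting chain of pairs around the mature interval.

    The internal folder only ever emits a single chain; for general
    dot-bracket input (e.g. a ViennaRNA structure with a multiloop) the
    stem whose span overlaps the mature interval best is kept.
    """
    if not pairs:
        return []
    pairs = sorted(pairs)
    # parent of each pair = closest enclosing pair
    chains: list[list[tuple[int, int]]] = []
    stack: list[tuple[int, int]] = []
    current: list[tuple[int, int]] = []
    for p in pairs:
        while stack and not (stack[-1][0] < p[0] and p[1] < stack[-1][1]):
            stack.pop()
        if stack and current and current[-1] == stack[-1]:
            current.append(p)
        else:
            if current:
                chains.append(current)
            # start a new chain seeded with the enclosing path
            current = [p]
        stack.append(p)
    if current:
        chains.append(current)
    ms, me = mature

    def overlap(chain):
        a, b = chain[0]
        return max(0, min(b + 1, me) - max(a, ms))

    best = max(chains, key=lambda ch: (overlap(ch), len(ch), -ch[0][0]))
    return best


def extract_stem_loop_features(
    structure: HairpinStructure, mature: tuple[int, int]
) -> HairpinFeatures:
    """Measure the criteria inputs for ``structure`` with the mature placed
    at the half-open interval ``mature`` on the hairpin sequence."""
    ms, me = mature
    if not (0 <= ms < me <= len(structure.sequence)):
        raise ValueError(f"mature interval {mature} outside sequence")
    chain = _nested_chain(structure.pairs, mature)
    mature_len = me - ms
    if not chain:
        return HairpinFeatures(
            mfe=structure.mfe, n_stem_pairs=0, terminal_loop_len=0, hairpin_len=0,
            max_stem_bulge=0, mature_errors=mature_len, maturity_in_stem=0.0,
            max_mature_bulge=0, max_biased_mature_bulge=0, n_biased_mature_bulges=0,
            pairs_in_mature=0, mature_in_span=False,
        )
    outer_i, outer_j = chain[0]
    inner_i, inner_j = chain[-1]
    terminal_loop = inner_j - inner_i - 1
    hairpin_len = outer_j - outer_i + 1

    paired = set()
    for a, b in chain:
        paired.add(a)
        paired.add(b)

    bulges: list[Bulge] = []
    for (a, b), (c, d) in zip(chain, chain[1:]):
        n5, n3 = c - a - 1, b - d - 1
        if n5 + n3 == 0:
            continue
        bulge = Bulge((a + 1, c), (d + 1, b), n5, n3)
        m_un = sum(1 for x in range(a + 1, c) if ms <= x < me)
        m_un += sum(1 for x in range(d + 1, b) if ms <= x < me)
        bulge.mature_unpaired = m_un
        bulge.in_mature = m_un > 0
        bulges.append(bulge)

    mature_pos = range(ms, me)
    errors = sum(1 for x in mature_pos if x not in paired)
    # stem = folded span minus the terminal loop
    in_stem = sum(
        1 for x in mature_pos
        if (outer_i <= x <= inner_i) or (inner_j <= x <= outer_j)
    )
    maturity = in_stem / mature_len if mature_len else 0.0
    mature_bulges = [b for b in bulges if b.in_mature]
    biased_mature = [b for b in mature_bulges if b.biased]
    pairs_in_mature = sum(1 for a, b in chain if (ms <= a < me) or (ms <= b < me))
    mature_in_span = ms >= outer_i and me <= outer_j + 1

    return HairpinFeatures(
        mfe=structure.mfe,
        n_stem_pairs=len(chain),
        terminal_loop_len=terminal_loop,
        hairpin_len=hairpin_len,
        max_stem_bulge=max((b.size for b in bulges), default=0),
        mature_errors=errors,
        maturity_in_stem=maturity,
        max_mature_bulge=max((b.size for b in mature_bulges), default=0),
        max_biased_mature_bulge=max((b.size for b in biased_mature), default=0),
        n_biased_mature_bulges=len(biased_mature),
        pairs_in_mature=pairs_in_mature,
        mature_in_span=mature_in_span,
        bulges=bulges,
    )


def classify_novel_mirna(
    features: HairpinFeatures, thresholds: CriteriaThresholds = DEFAULT_THRESHOLDS
) -> HairpinVerdict:
    """Apply the 11 structure criteria; the call passes only if all hold.

    Comparator strictness follows the printed rules exactly: all bulge,
    loop and error limits are inclusive; the stem-pair count alone is a
    strict inequality (more than 16 pairs).
    """
    t = thresholds
    f = features
    criteria = {
        "c1": f.max_stem_bulge <= t.max_stem_bulge,
        "c2": f.mfe <= t.max_mfe,
        "c3": f.terminal_loop_len <= t.max_terminal_loop,
        "c4": f.max_biased_mature_bulge <= t.max_biased_bulge_errors,
        "c5": f.mature_errors <= t.max_mature_errors,
        "c6": f.mature_in_span and f.maturity_in_stem >= t.min_maturity_in_stem,
        "c7": f.n_stem_pairs > t.min_stem_pairs,
        "c8": f.hairpin_len >= t.min_hairpin_len,
        "c9": f.max_mature_bulge <= t.max_mature_bulge,
        "c10": f.n_biased_mature_bulges <= t.max_biased_mature_bulges,
        "c11": f.pairs_in_mature >= t.min_mature_pairs,
    }
    return HairpinVerdict(criteria)


def evaluate_locus(
    sequence: str,
    mature: tuple[int, int],
    backend: str = "nn",
    thresholds: CriteriaThresholds = DEFAULT_THRESHOLDS,
) -> tuple[HairpinStructure, HairpinFeatures, HairpinVerdict]:
    """Fold a flanked locus sequence and run the full classification."""
    structure = fold_hairpin(sequence, backend=backend)
    features = extract_stem_loop_features(structure, mature)
    return structure, features, classify_novel_mirna(features, thresholds)
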