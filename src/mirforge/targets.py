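"""miRNA target prediction on 3'UTRs by two independent predictors.

The *seed scanner* reports canonical seed sites: positions on the UTR
complementary (Watson-Crick only) to miRNA positions 2-8.  Site types
follow the canonical hierarchy:

* 8mer     -- match to positions 2-8 plus an A opposite position 1;
* 7mer-m8  -- match to positions 2-8;
* 7mer-A1  -- match to positions 2-7 plus an A opposite position 1;
* 6mer     -- match to positions 2-7 alone (excluded by default).

The *aligner* performs a Smith-Waterman-style complementarity alignment
of the whole miRNA against the UTR with G:U wobble at reduced score,
affine gap penalties, and doubled weight for seed positions 2-8, and
scores the resulting duplex with the same nearest-neighbour stacking
energies used by the folding module.  A site must clear both the score
and the duplex-energy threshold.

A (miRNA, transcript) pair is retained only when both predictors report
sites whose UTR intervals overlap by at least one nucleotide.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numba import njit

from .annotate import revcomp
from .fold import PAIR_INDEX, STACK, encode

SEED_START, SEED_END = 1, 8     # 0-based slice of miRNA positions 2..8

# pair table padded with a non-pairing sentinel code (4), used to mask
# already-reported UTR spans between alignment rounds
_PAIR5 = np.full((5, 5), -1, dtype=np.int8)
_PAIR5[:4, :4] = PAIR_INDEX

MATCH_SCORE = 5.0
WOBBLE_SCORE = 1.0
MISMATCH_SCORE = -3.0
GAP_OPEN = -9.0
GAP_EXTEND = -4.0
SEED_WEIGHT = 2.0
DUPLEX_INIT = 4.09              # kcal/mol, duplex initiation
NICK_PENALTY = 0.5              # per interruption of the paired stack


@dataclass(frozen=True)
class PredictorConfig:
    min_site_type: str = "7mer"          # "6mer" admits marginal sites
    score_threshold: float = 140.0
    energy_threshold: float = -20.0      # kcal/mol
    allow_gu: bool = True


@dataclass
class TargetSite:
    mirna: str
    transcript: str
    start: int
    end: int
    site_type: str                       # 8mer | 7mer-m8 | 7mer-A1 | 6mer | aligner
    score: float = 0.0
    energy: float = 0.0
    predictors: set = field(default_factory=set)


class TargetPredictionError(ValueError):
    pass


def _norm(seq: str) -> str:
    return seq.upper().replace("U", "T")


def scan_seed_sites(
    mirna_name: str,
    mirna_seq: str,
    transcript: str,
    utr: str,
    config: PredictorConfig = PredictorConfig(),
) -> list[TargetSite]:
    """All canonical seed sites of one miRNA on one UTR.

    At each UTR offset only the strongest applicable type is reported
    (8mer > 7mer-m8 > 7mer-A1 > 6mer).
    """
    m = _norm(mirna_seq)
    if len(m) < 8:
        raise TargetPredictionError(f"{mirna_name}: miRNA shorter than 8 nt")
    u = _norm(utr)
    rc28 = revcomp(m[SEED_START:SEED_END])    # 7 nt, pairs positions 2-8
    rc27 = revcomp(m[SEED_START:SEED_END - 1])  # 6 nt, pairs positions 2-7
    allow_6mer = config.min_site_type == "6mer"
    sites = []
    for i in range(len(u) - 5):
        window7 = u[i:i + 7]
        if window7 == rc28:
            if u[i + 7:i + 8] == "A":
                sites.append(TargetSite(mirna_name, transcript, i, i + 8,
                                        "8mer", predictors={"seed"}))
            else:
                sites.append(TargetSite(mirna_name, transcript, i, i + 7,
                                        "7mer-m8", predictors={"seed"}))
            continue
        if u[i:i + 6] == rc27:
            if u[i + 6:i + 7] == "A":
                sites.append(TargetSite(mirna_name, transcript, i, i + 7,
                                        "7mer-A1", predictors={"seed"}))
            elif allow_6mer:
                sites.append(TargetSite(mirna_name, transcript, i, i + 6,
                                        "6mer", predictors={"seed"}))
    return sites


@njit(cache=True)
def _sw_kernel(mir_codes, utr_codes, pair_index, match, wobble, mismatch,
               gap_open, gap_extend, seed_weight, seed_lo, seed_hi):
    """Affine-gap local alignment of the reversed miRNA vs the UTR.

    mir_codes is the miRNA 3'->5' so both sequences run in UTR
    orientation; row index k corresponds to miRNA position (len-k),
    1-based from the 5' end.
    """
    nm, nu = mir_codes.size, utr_codes.size
    NEG = -1e9
    H = np.zeros((nm + 1, nu + 1))
    E = np.full((nm + 1, nu + 1), NEG)  # gap in miRNA (along UTR)
    F = np.full((nm + 1, nu + 1), NEG)  # gap in UTR (along miRNA)
    best = 0.0
    bi = bj = 0
    for k in range(1, nm + 1):
        pos = nm - k + 1  # 1-based miRNA position
        w = seed_weight if seed_lo <= pos <= seed_hi else 1.0
        for j in range(1, nu + 1):
            p = pair_index[mir_codes[k - 1], utr_codes[j - 1]]
            if p == 2 or p == 3 or p == 0 or p == 1:
                s = match * w
            elif p == 4 or p == 5:
                s = wobble * w
            else:
                s = mismatch * w
            e = max(H[k, j - 1] + gap_open, E[k, j - 1] + gap_extend)
            f = max(H[k - 1, j] + gap_open, F[k - 1, j] + gap_extend)
            h = H[k - 1, j - 1] + s
            if e > h:
                h = e
            if f > h:
                h = f
            if h < 0.0:
                h = 0.0
            H[k, j] = h
            E[k, j] = e
            F[k, j] = f
            if h > best:
                best = h
                bi, bj = k, j
    return best, bi, bj, H, E, F


def align_miranda_like(
    mirna_name: str,
    mirna_seq: str,
    transcript: str,
    utr: str,
    config: PredictorConfig = PredictorConfig(),
) -> list[TargetSite]:
    """miRanda-style complementarity sites of one miRNA on one UTR.

    Non-overlapping local alignments are extracted greedily from best to
    worst; a site is reported when score >= score_threshold and duplex
    energy <= energy_threshold.
    """
    m = _norm(mirna_seq)
    u = _norm(utr)
    if len(u) < len(m):
        return []
    mir_codes = encode(m)[::-1].copy()
    utr_codes = encode(u)
    wobble = WOBBLE_SCORE if config.allow_gu else MISMATCH_SCORE
    sites: list[TargetSite] = []
    masked = np.zeros(len(u), dtype=bool)
    while True:
        score, bi, bj, H, E, F = _sw_kernel(
            mir_codes, utr_codes, _PAIR5, MATCH_SCORE, wobble,
            MISMATCH_SCORE, GAP_OPEN, GAP_EXTEND, SEED_WEIGHT,
            SEED_START + 1, SEED_END)
        if score < config.score_threshold:
            break
        pairs, start, end = _traceback(H, E, F, mir_codes, utr_codes, bi, bj,
                                       wobble)
        energy = duplex_energy(pairs, mir_codes, utr_codes)
        if energy <= config.energy_threshold:
            sites.append(TargetSite(mirna_name, transcript, start, end,
                                    "aligner", score=float(score),
                                    energy=round(energy, 2),
                                    predictors={"aligner"}))
        masked[start:end] = True
        utr_codes = utr_codes.copy()
        utr_codes[masked] = 4  # non-pairing sentinel
        if masked.all():
            break
    return sorted(sites, key=lambda s: s.start)


def _traceback(H, E, F, mir_codes, utr_codes, bi, bj, wobble):
    """Recover aligned pairs (k, j) from the DP matrices."""
    pairs = []
    k, j = bi, bj
    end = bj
    state = "H"
    nm = mir_codes.size
    while k > 0 and j > 0 and H[k, j] > 0:
        if state == "H":
            if H[k, j] == E[k, j]:
                state = "E"
                continue
            if H[k, j] == F[k, j]:
                state = "F"
                continue
            pairs.append((k - 1, j - 1))
            k, j = k - 1, j - 1
        elif state == "E":
            if E[k, j] == E[k, j - 1] + GAP_EXTEND:
                j -= 1
            else:
                j -= 1
                state = "H"
        else:
            if F[k, j] == F[k - 1, j] + GAP_EXTEND:
                k -= 1
            else:
                k -= 1
                state = "H"
    start = j
    return pairs[::-1], start, end


def duplex_energy(pairs, mir_codes, utr_codes) -> float:
    """Nearest-neighbour hybridisation energy of an aligned duplex.

    Sums stacking energies over runs of contiguous complementary pairs
    (contiguous on both strands), plus a duplex-initiation term and a
    small penalty per interruption.
    """
    paired = [(k, j) for k, j in pairs
              if 0 <= utr_codes[j] <= 3
              and PAIR_INDEX[mir_codes[k], utr_codes[j]] >= 0]
    if not paired:
        return 0.0
    e = DUPLEX_INIT
    nicks = 0
    for (k1, j1), (k2, j2) in zip(paired, paired[1:]):
        if k2 == k1 + 1 and j2 == j1 + 1:
            p1 = PAIR_INDEX[mir_codes[k1], utr_codes[j1]]
            p2 = PAIR_INDEX[mir_codes[k2], utr_codes[j2]]
            # stack orientation: along the UTR 5'->3'
            e += STACK[p2, p1]
        else:
            nicks += 1
    e += NICK_PENALTY * nicks
    return float(e)


def intersect_predictions(
    seed_sites: list[TargetSite],
    aligner_sites: list[TargetSite],
) -> list[TargetSite]:
    """Keep (miRNA, transcript) pairs supported by both predictors with
    overlapping site intervals; merged sites carry both flags."""
    by_pair: dict[tuple[str, str], list[TargetSite]] = {}
    for s in aligner_sites:
        by_pair.setdefault((s.mirna, s.transcript), []).append(s)
    out = []
    for s in seed_sites:
        for a in by_pair.get((s.mirna, s.transcript), []):
            if min(s.end, a.end) - max(s.start, a.start) >= 1:
                merged = TargetSite(
                    s.mirna, s.transcript,
                    min(s.start, a.start), max(s.end, a.end),
                    s.site_type, score=a.score, energy=a.energy,
                    predictors={"seed", "aligner"})
                out.append(merged)
                break
    return out


def predict_targets(
    mirnas: dict[str, str],
    utrs: dict[str, str],
    config: PredictorConfig = PredictorConfig(),
) -> tuple[list[TargetSite], list[TargetSite], list[TargetSite]]:
    """Run both predictors over all miRNA x UTR combinations.

    Returns (seed sites, aligner sites, intersected sites).
    """
    seed_all, align_all = [], []
    for mname, mseq in sorted(mirnas.items()):
        for tname, useq in sorted(utrs.items()):
            seed_all.extend(scan_seed_sites(mname, mseq, tname, useq, config))
            align_all.extend(align_miranda_like(mname, mseq, tname, useq, config))
    return seed_all, align_all, intersect_predictions(seed_all, align_all)
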