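"""Mapping cascade for cleaned sequence tags and miRNA name grammar.

Tags are assigned in a fixed cascade, mirroring how small-RNA discovery
pipelines consume a miRBase-style catalog:

1. species precursors: a tag aligning ungapped within an annotated mature
   arm (allowing end shifts up to a window and at most one substitution)
   is a *known* species miRNA, named after the mature with isomiR
   suffixes;
2. other-species precursors: remaining tags matching a foreign precursor
   arm whose precursor also locates on the study genome become *known by
   homology*;
3. genome: remaining tags placed exactly on the genome become *novel
   candidates* (``PC-`` names) and are handed to the hairpin classifier
   with +/-80 nt of flank;
4. anything else is left unassigned.

Name grammar (isomiR end-variation naming)::

    <base>[_L<+/-x>][R<+/-y>][_1ss<pos><ref><alt>]     known miRNAs
    PC-<arm>-<serial>_<total count>                    novel candidates

``L+x`` denotes x extra nucleotides at the 5' end relative to the
annotated mature (``L-x`` a trim), ``R+/-y`` the same at the 3' end, and
``1ss<pos><ref><alt>`` a single substitution at 1-based position ``pos``
of the tag.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import pandas as pd

COMPLEMENT = str.maketrans("ACGTU", "TGCAA")


def revcomp(seq: str) -> str:
    return seq.upper().translate(COMPLEMENT)[::-1]


@dataclass
class PrecursorRecord:
    """Hairpin precursor with annotated mature arm interval(s)."""

    id: str
    species: str
    sequence: str
    mature: dict[str, tuple[int, int]] = field(default_factory=dict)  # arm -> 0-based half-open
    mature_names: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for arm, (s, e) in self.mature.items():
            if not (0 <= s < e <= len(self.sequence)):
                raise ValueError(f"{self.id}: mature {arm} interval outside precursor")
        ivals = sorted(self.mature.values())
        for (s1, e1), (s2, e2) in zip(ivals, ivals[1:]):
            if s2 < e1:
                raise ValueError(f"{self.id}: mature arms overlap")


@dataclass
class MappingResult:
    tag: str
    category: str                    # known_species | known_homolog | novel_candidate | unassigned
    reference: str | None = None     # precursor id, or chrom for candidates
    arm: str | None = None
    left_offset: int = 0
    right_offset: int = 0
    mismatch: tuple[int, str, str] | None = None  # (1-based tag pos, ref, alt)
    interval: tuple[int, int] | None = None
    strand: str | None = None
    name: str | None = None


def _count_mismatches(a: str, b: str, limit: int) -> int:
    m = 0
    for x, y in zip(a, b):
        if x != y:
            m += 1
            if m > limit:
                return m
    return m


def _best_arm_hit(tag: str, prec: PrecursorRecord, window: int, max_mismatch: int):
    """Best ungapped placement of ``tag`` within a mature arm of ``prec``.

    Returns (mismatches, |lo|+|ro|, arm, lo, ro, mm_detail) or None.
    """
    best = None
    L = len(tag)
    seq = prec.sequence
    for arm in sorted(prec.mature):
        ms, me = prec.mature[arm]
        for lo in range(-window, window + 1):
            start = ms - lo
            end = start + L
            if start < 0 or end > len(seq):
                continue
            ro = end - me
            if abs(ro) > window:
                continue
            ref = seq[start:end]
            nmm = _count_mismatches(tag, ref, max_mismatch)
            if nmm > max_mismatch:
                continue
            detail = None
            if nmm:
                pos = next(i for i in range(L) if tag[i] != ref[i])
                detail = (pos + 1, ref[pos], tag[pos])
            key = (nmm, abs(lo) + abs(ro), arm, lo, ro)
            if best is None or key < best[0]:
                best = (key, arm, lo, ro, detail)
    return best


def map_to_precursors(
    tags: list[str],
    precursors: list[PrecursorRecord],
    window: int = 2,
    max_mismatch: int = 1,
) -> list[MappingResult]:
    """Stage 1 of the cascade: assign tags to species precursor arms."""
    if window < 0:
        raise ValueError("window must be >= 0")
    precs = sorted(precursors, key=lambda p: p.id)
    out = []
    for tag in tags:
        best = None
        for prec in precs:
            hit = _best_arm_hit(tag, prec, window, max_mismatch)
            if hit is None:
                continue
            key = (hit[0][0], hit[0][1], prec.id)
            if best is None or key < best[0]:
                best = (key, prec, hit)
        if best is None:
            out.append(MappingResult(tag, "unassigned"))
            continue
        _, prec, (_, arm, lo, ro, detail) = best
        base = prec.mature_names.get(arm, f"{prec.id}-{arm}")
        res = MappingResult(
            tag, "known_species", reference=prec.id, arm=arm,
            left_offset=lo, right_offset=ro, mismatch=detail,
        )
        res.name = format_mirna_name(base, lo, ro, detail)
        out.append(res)
    return out


def map_homologs(
    results: list[MappingResult],
    other_precursors: list[PrecursorRecord],
    genome: str,
    window: int = 2,
    max_mismatch: int = 1,
) -> list[MappingResult]:
    """Stage 2: route still-unassigned tags through foreign precursors.

    A hit only counts when the foreign precursor itself occurs in the
    study genome (exact substring search standing in for a BLAST
    localization); otherwise the tag stays unassigned.
    """
    if not other_precursors:
        return results
    precs = sorted(other_precursors, key=lambda p: p.id)
    located = {p.id: genome.find(p.sequence) for p in precs}
    out = []
    for res in results:
        if res.category != "unassigned":
            out.append(res)
            continue
        best = None
        for prec in precs:
            hit = _best_arm_hit(res.tag, prec, window, max_mismatch)
            if hit is None:
                continue
            key = (hit[0][0], hit[0][1], prec.id)
            if best is None or key < best[0]:
                best = (key, prec, hit)
        if best is None:
            out.append(res)
            continue
        _, prec, (_, arm, lo, ro, detail) = best
        pos = located[prec.id]
        if pos < 0:
            out.append(res)  # precursor absent from genome: stays unassigned
            continue
        base = prec.mature_names.get(arm, f"{prec.id}-{arm}")
        new = MappingResult(
            res.tag, "known_homolog", reference=prec.id, arm=arm,
            left_offset=lo, right_offset=ro, mismatch=detail,
            interval=(pos, pos + len(prec.sequence)), strand="+",
        )
        new.name = format_mirna_name(base, lo, ro, detail)
        out.append(new)
    return out


@dataclass
class CandidateLocus:
    tag: str
    chrom: str
    start: int
    end: int
    strand: str
    context: str            # tag +/- flank, oriented 5'->3' on the tag strand
    mature_in_context: tuple[int, int]


def _find_all(haystack: str, needle: str, limit: int) -> list[int]:
    hits, start = [], 0
    while len(hits) <= limit:
        i = haystack.find(needle, start)
        if i < 0:
            break
        hits.append(i)
        start = i + 1
    return hits


def locate_genomic_candidates(
    results: list[MappingResult],
    genome: str,
    chrom: str = "chrS",
    flank: int = 80,
    max_loci: int = 10,
) -> tuple[list[MappingResult], list[CandidateLocus]]:
    """Stage 3: place remaining tags on the genome (both strands, exact).

    Tags with more than ``max_loci`` placements are treated as repetitive
    and discarded.  Each placement carries its +/-``flank`` nt context
    (reverse-complemented for minus-strand hits) for the hairpin stage.
    """
    out, loci = [], []
    rc_genome_cache: dict[str, list[int]] = {}
    for res in results:
        if res.category != "unassigned":
            out.append(res)
            continue
        tag = res.tag
        fwd = _find_all(genome, tag, max_loci)
        rev = _find_all(genome, revcomp(tag), max_loci)
        placements = [(p, "+") for p in fwd] + [(p, "-") for p in rev]
        if not placements:
            out.append(res)
            continue
        if len(placements) > max_loci:
            out.append(res)  # repetitive; stays unassigned
            continue
        first = None
        for pos, strand in placements:
            start, end = pos, pos + len(tag)
            cs, ce = max(0, start - flank), min(len(genome), end + flank)
            ctx = genome[cs:ce]
            m = (start - cs, end - cs)
            if strand == "-":
                ctx = revcomp(ctx)
                m = (len(ctx) - (end - cs), len(ctx) - (start - cs))
            loci.append(CandidateLocus(tag, chrom, start, end, strand, ctx, m))
            if first is None:
                first = (start, end, strand)
        new = MappingResult(
            tag, "novel_candidate", reference=chrom,
            interval=first[:2], strand=first[2],
        )
        out.append(new)
    return out, loci


def assign_candidate_names(
    results: list[MappingResult],
    arms: dict[str, str],
    totals: dict[str, int],
) -> list[MappingResult]:
    """Give novel candidates their ``PC-<arm>-<serial>_<total>`` names.

    Serials follow discovery order; the trailing number is the tag's total
    read count across libraries.
    """
    serial = 0
    for res in results:
        if res.category != "novel_candidate":
            continue
        serial += 1
        arm = arms.get(res.tag, "5p")
        res.arm = arm
        res.name = f"PC-{arm}-{serial}_{totals.get(res.tag, 0)}"
    return results


_KNOWN_RE = re.compile(
    r"^(?P<base>.+?)"
    r"(?:_(?=[LR])(?:L(?P<lo>[+-]\d+))?(?:R(?P<ro>[+-]\d+))?)?"
    r"(?:_1ss(?P<pos>\d+)(?P<ref>[ACGTU])(?P<alt>[ACGTU]))?$"
)
_PC_RE = re.compile(r"^PC-(?P<arm>[53]p)-(?P<serial>\d+)_(?P<total>\d+)$")


def format_mirna_name(
    base: str,
    left_offset: int = 0,
    right_offset: int = 0,
    mismatch: tuple[int, str, str] | None = None,
) -> str:
    name = base
    if left_offset or right_offset:
        name += "_"
        if left_offset:
            name += f"L{left_offset:+d}"
        if right_offset:
            name += f"R{right_offset:+d}"
    if mismatch is not None:
        pos, ref, alt = mismatch
        name += f"_1ss{pos}{ref}{alt}"
    return name


class NameParseError(ValueError):
    pass


def parse_mirna_name(name: str) -> dict:
    """Invert :func:`format_mirna_name`; also understands PC names."""
    pc = _PC_RE.match(name)
    if pc:
        return {
            "kind": "candidate",
            "arm": pc["arm"],
            "serial": int(pc["serial"]),
            "total": int(pc["total"]),
        }
    m = _KNOWN_RE.match(name)
    if not m or not m["base"]:
        raise NameParseError(f"unparseable miRNA name: {name!r}")
    mismatch = None
    if m["pos"] is not None:
        mismatch = (int(m["pos"]), m["ref"], m["alt"])
    return {
        "kind": "known",
        "base": m["base"],
        "left_offset": int(m["lo"]) if m["lo"] else 0,
        "right_offset": int(m["ro"]) if m["ro"] else 0,
        "mismatch": mismatch,
    }


def run_cascade(
    tag_table: pd.DataFrame,
    precursors: list[PrecursorRecord],
    other_precursors: list[PrecursorRecord],
    genome: str,
    chrom: str = "chrS",
    window: int = 2,
    max_mismatch: int = 1,
    flank: int = 80,
    max_loci: int = 10,
) -> tuple[pd.DataFrame, list[CandidateLocus]]:
    """Run the full cascade over a collapsed tag table.

    Returns a mapping table (one row per tag) and the candidate loci for
    the hairpin stage.  Candidate arm labels are resolved later, once the
    loci are folded; PC serials here use placeholder arm '5p' when no arm
    is supplied.
    """
    tags = list(tag_table["sequence"])
    res = map_to_precursors(tags, precursors, window, max_mismatch)
    res = map_homologs(res, other_precursors, genome, window, max_mismatch)
    res, loci = locate_genomic_candidates(res, genome, chrom, flank, max_loci)
    totals = dict(zip(tag_table["sequence"], tag_table["total"]))
    res = assign_candidate_names(res, {}, totals)
    rows = []
    for r in res:
        rows.append({
            "sequence": r.tag,
            "name": r.name if r.name else "",
            "category": r.category,
            "reference": r.reference or "",
            "arm": r.arm or "",
            "left_offset": r.left_offset,
            "right_offset": r.right_offset,
            "mismatch": (
                f"{r.mismatch[0]}{r.mismatch[1]}{r.mismatch[2]}" if r.mismatch else ""
            ),
            "start": r.interval[0] if r.interval else -1,
            "end": r.interval[1] if r.interval else -1,
            "strand": r.strand or "",
        })
    table = pd.DataFrame(rows)
    return table, loci
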