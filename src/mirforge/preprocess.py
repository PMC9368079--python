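"""Raw-read cleanup: adapter trimming, junk removal, tag collapsing and
ncRNA-family filtering.

The stage order is fixed: trim adapters -> drop junk/length failures ->
collapse to unique 18-26 nt tags with per-library counts -> remove tags
matching catalogued contaminant families (rRNA > tRNA > snRNA > snoRNA
priority).  Base qualities are parsed but otherwise ignored.  Every input
read is accounted for: reads in = surviving reads + sum of per-category
removals.
"""

from __future__ import annotations

import math
import warnings
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import pysam

MIN_TAG_LEN = 18
MAX_TAG_LEN = 26
ENTROPY_THRESHOLD = 1.0     # bits
MAX_BASE_FRACTION = 0.8
CONTAMINANT_PRIORITY = ["rRNA", "tRNA", "snRNA", "snoRNA"]

FILTER_CATEGORIES = [
    "adapter_dimer", "no_adapter", "junk_lowcomplexity", "repeat", "length",
    "rRNA", "tRNA", "snRNA", "snoRNA",
]


@dataclass
class FilterReport:
    """Per-library accounting of removed reads by category."""

    library: str
    input_reads: int = 0
    surviving: int = 0
    removed: Counter = field(default_factory=Counter)

    def to_row(self) -> dict:
        row = {"library": self.library, "input_reads": self.input_reads,
               "surviving": self.surviving}
        row.update({c: self.removed.get(c, 0) for c in FILTER_CATEGORIES})
        return row

    def conserved(self) -> bool:
        return self.input_reads == self.surviving + sum(self.removed.values())


def trim_adapter(read: str, adapter: str, min_overlap: int = 6,
                 max_mismatch_rate: float = 0.1) -> tuple[str | None, str]:
    """Return (insert, category) for one read.

    The insert is the read prefix before the leftmost acceptable adapter
    match (full matches preferred via the mismatch-rate gate; 3' partial
    overlaps of at least ``min_overlap`` nt are accepted).  Categories:
    ``ok``, ``adapter_dimer`` (empty insert), ``no_adapter``,
    ``junk_lowcomplexity`` (empty read).
    """
    if not adapter:
        raise ValueError("adapter sequence must be non-empty")
    if not read:
        return None, "junk_lowcomplexity"
    # exact occurrence bounds the scan; an earlier mismatch-tolerant match
    # (within the rate gate) still takes precedence
    exact = read.find(adapter)
    limit = exact if exact >= 0 else len(read)
    pos = _scan_adapter(read[:limit + len(adapter) - 1], adapter,
                        min_overlap, max_mismatch_rate)
    if pos < 0 or (exact >= 0 and pos > exact):
        pos = exact
    if pos < 0:
        return None, "no_adapter"
    if pos == 0:
        return None, "adapter_dimer"
    return read[:pos], "ok"


def _scan_adapter(read: str, adapter: str, min_overlap: int,
                  max_mismatch_rate: float) -> int:
    n, m = len(read), len(adapter)
    for p in range(0, n - min_overlap + 1):
        overlap = min(m, n - p)
        limit = int(max_mismatch_rate * overlap)
        mm = 0
        for a, b in zip(read[p:p + overlap], adapter[:overlap]):
            if a != b:
                mm += 1
                if mm > limit:
                    break
        else:
            return p
    return -1


def shannon_entropy(seq: str) -> float:
    """Base-composition entropy in bits."""
    if not seq:
        return 0.0
    n = len(seq)
    return -sum(c / n * math.log2(c / n) for c in Counter(seq).values())


def is_tandem_repeat(seq: str, max_period: int = 3) -> bool:
    for period in range(1, max_period + 1):
        if len(seq) >= 2 * period:
            unit = seq[:period]
            if all(seq[i] == unit[i % period] for i in range(len(seq))):
                return True
    return False


def classify_insert(insert: str) -> str:
    """Junk/length gate for a trimmed insert: returns ``ok`` or a removal
    category (checked in order: length, low complexity, tandem repeat)."""
    if not (MIN_TAG_LEN <= len(insert) <= MAX_TAG_LEN):
        return "length"
    counts = Counter(insert)
    if (max(counts.values()) / len(insert) >= MAX_BASE_FRACTION
            or shannon_entropy(insert) < ENTROPY_THRESHOLD):
        return "junk_lowcomplexity"
    if is_tandem_repeat(insert):
        return "repeat"
    return "ok"


def clean_library(fastq: str | Path, adapter: str, min_overlap: int = 6,
                  max_mismatch_rate: float = 0.1,
                  library: str | None = None) -> tuple[Counter, FilterReport]:
    """Trim and junk-filter one FASTQ library; returns surviving insert
    counts and the library's filter report."""
    library = library or Path(fastq).stem
    report = FilterReport(library)
    inserts: Counter = Counter()
    with pysam.FastxFile(str(fastq)) as fh:
        for entry in fh:
            report.input_reads += 1
            insert, cat = trim_adapter(entry.sequence.upper(), adapter,
                                       min_overlap, max_mismatch_rate)
            if cat != "ok":
                report.removed[cat] += 1
                continue
            cat = classify_insert(insert)
            if cat != "ok":
                report.removed[cat] += 1
                continue
            report.surviving += 1
            inserts[insert] += 1
    return inserts, report


def collapse_tags(per_library: dict[str, Counter]) -> pd.DataFrame:
    """Collapse cleaned inserts into a unique-tag table.

    One row per distinct sequence, one count column per library plus a
    total, sorted lexicographically by sequence.
    """
    libs = list(per_library)
    all_tags = sorted(set().union(*[set(c) for c in per_library.values()])) \
        if per_library else []
    data = {"sequence": all_tags}
    for lib in libs:
        data[lib] = [per_library[lib].get(t, 0) for t in all_tags]
    df = pd.DataFrame(data)
    df["total"] = df[libs].sum(axis=1) if libs else pd.Series([], dtype=int)
    return df


def filter_contaminants(
    tags: pd.DataFrame,
    catalog: list[tuple[str, str, str]],
    reports: dict[str, FilterReport] | None = None,
    max_mismatch: int = 0,
) -> pd.DataFrame:
    """Remove tags matching catalogued ncRNA families.

    ``catalog`` holds (family, id, sequence) entries.  A tag matching any
    entry as an exact substring (or with <=1 mismatch when configured) is
    removed and attributed to one family, ties broken by the fixed
    priority rRNA > tRNA > snRNA > snoRNA.  Removal counts (in read
    units) are added to the per-library reports when given.
    """
    if not catalog:
        warnings.warn("empty contaminant catalog; no tags removed")
        return tags
    by_family: dict[str, list[str]] = {}
    for family, _cid, seq in catalog:
        by_family.setdefault(family, []).append(seq.upper())
    families = [f for f in CONTAMINANT_PRIORITY if f in by_family]
    families += sorted(set(by_family) - set(CONTAMINANT_PRIORITY))
    keep, hit_family = [], []
    for tag in tags["sequence"]:
        fam_hit = None
        for fam in families:
            if any(_matches(tag, seq, max_mismatch) for seq in by_family[fam]):
                fam_hit = fam
                break
        keep.append(fam_hit is None)
        hit_family.append(fam_hit)
    removed = tags.loc[[not k for k in keep]]
    if reports is not None:
        lib_cols = [c for c in tags.columns if c not in ("sequence", "total")]
        for (_, row), fam in zip(removed.iterrows(),
                                 [f for f in hit_family if f]):
            for lib in lib_cols:
                if row[lib]:
                    reports[lib].removed[fam] += int(row[lib])
                    reports[lib].surviving -= int(row[lib])
    return tags.loc[keep].reset_index(drop=True)


def _matches(tag: str, contaminant: str, max_mismatch: int) -> bool:
    if max_mismatch == 0:
        return tag in contaminant
    L = len(tag)
    if L > len(contaminant):
        return False
    for p in range(len(contaminant) - L + 1):
        mm = 0
        for a, b in zip(tag, contaminant[p:p + L]):
            if a != b:
                mm += 1
                if mm > max_mismatch:
                    break
        else:
            return True
    return False


def run_preprocess(
    fastqs: dict[str, str | Path],
    adapter: str,
    contaminants: list[tuple[str, str, str]] | None = None,
    min_overlap: int = 6,
    max_mismatch_rate: float = 0.1,
    contaminant_mismatch: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Full cleanup over a set of libraries.

    Returns the unique-tag table and the per-library filter report table.
    """
    per_lib, reports = {}, {}
    for lib, path in fastqs.items():
        inserts, report = clean_library(path, adapter, min_overlap,
                                        max_mismatch_rate, library=lib)
        per_lib[lib] = inserts
        reports[lib] = report
    tags = collapse_tags(per_lib)
    if contaminants:
        tags = filter_contaminants(tags, contaminants, reports,
                                   contaminant_mismatch)
    report_df = pd.DataFrame([reports[lib].to_row() for lib in per_lib])
    return tags, report_df
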