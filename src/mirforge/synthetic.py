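"""Ground-truthed synthetic inputs for the whole pipeline.

The generator emulates the study design the package targets: three
treatment groups (control and two oxidative-stress doses, CON / LOS /
MOS) with three replicate small-RNA libraries each, single-end 36 or
50 bp reads.  It plants:

* known miRNAs -- designed precursor hairpins with annotated mature arms
  (a miRBase-like species catalog);
* homolog miRNAs -- foreign-species precursors embedded verbatim in the
  genome;
* novel loci -- genome-embedded hairpins that satisfy all 11 structure
  criteria of the hairpin module;
* decoy loci -- hairpins violating exactly one designated criterion each;
* contamination -- ncRNA-family fragments, adapter dimers and
  low-complexity reads;
* negative-binomial counts with planted log2 fold changes between the
  control and each stress group, realised as isomiR-bearing reads.

Every planted novel/decoy construction is verified against the hairpin
classifier (in its final +/-80 nt genomic context) at generation time and
regenerated on failure, so the truth tables are guaranteed consistent
with the package's own structure model.  All randomness flows from the
single config seed; identical configs produce byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .annotate import PrecursorRecord, revcomp
from .hairpin import CRITERION_NAMES, evaluate_locus

# Illumina TruSeq small-RNA 3' adapter
DEFAULT_ADAPTER = "TGGAATTCTCGGGTGCCAAGG"

# contamination composition (fractions of the contaminated read share)
NCRNA_SHARE = 0.50
ADAPTER_DIMER_SHARE = 0.25
LOW_COMPLEXITY_SHARE = 0.25

FLANK = 80


class ConfigError(ValueError):
    pass


@dataclass
class SimulationConfig:
    seed: int = 1
    n_known_mirnas: int = 30
    n_homolog_mirnas: int = 4
    n_novel_loci: int = 8
    n_decoy_loci: int = 11
    groups: tuple[str, ...] = ("CON", "LOS", "MOS")
    replicates_per_group: int = 3
    reads_per_library: int = 100_000
    read_length: int = 50
    adapter_sequence: str = DEFAULT_ADAPTER
    contamination_fraction: float = 0.05
    de_fraction: float = 0.10
    planted_log2fc: float = 2.0
    nb_dispersion: float = 0.05
    isomir_shift_window: int = 2
    substitution_rate: float = 0.02
    genome_length: int = 100_000
    n_genes: int = 120
    utr_length: int = 600
    targets_per_mirna: tuple[int, int] = (4, 10)

    def __post_init__(self) -> None:
        if self.reads_per_library <= 0:
            raise ConfigError("reads_per_library must be > 0")
        if self.read_length not in (36, 50):
            raise ConfigError("read_length must be 36 or 50")
        for name in ("contamination_fraction", "de_fraction", "substitution_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name} must lie in [0, 1]")
        if self.nb_dispersion < 0:
            raise ConfigError("nb_dispersion must be >= 0")
        if not self.adapter_sequence:
            raise ConfigError("adapter_sequence must be non-empty")
        if self.isomir_shift_window < 0:
            raise ConfigError("isomir_shift_window must be >= 0")

    @property
    def libraries(self) -> list[str]:
        return [f"{g}_{r}" for g in self.groups
                for r in range(1, self.replicates_per_group + 1)]

    def library_groups(self) -> dict[str, str]:
        return {lib: lib.rsplit("_", 1)[0] for lib in self.libraries}

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimulationConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "groups" in raw:
            raw["groups"] = tuple(raw["groups"])
        if "targets_per_mirna" in raw:
            raw["targets_per_mirna"] = tuple(raw["targets_per_mirna"])
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        d = dataclasses.asdict(self)
        d["groups"] = list(d["groups"])
        d["targets_per_mirna"] = list(d["targets_per_mirna"])
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=True)


# ---------------------------------------------------------------------------
# hairpin design

_PAIR_BASES = {"GC": ("G", "C"), "CG": ("C", "G"), "AU": ("A", "T"),
               "UA": ("T", "A"), "GU": ("G", "T"), "UG": ("T", "G")}
# G:U wobbles keep designed stems from being perfectly self-complementary
# (a perfect stem's mature would also exact-match the minus strand at the
# opposite arm, which natural precursors avoid)
_STRONG_WEIGHTS = {"GC": 0.34, "CG": 0.30, "AU": 0.12, "UA": 0.09,
                   "GU": 0.08, "UG": 0.07}
_WEAK_WEIGHTS = {"AU": 0.35, "UA": 0.25, "GU": 0.25, "UG": 0.15}


@dataclass
class HairpinDesign:
    sequence: str                  # DNA, 5'->3'
    mature: tuple[int, int]        # half-open on sequence
    arm: str
    mature_3p: tuple[int, int] | None = None


def make_hairpin(
    rng: np.random.Generator,
    n_pairs: int,
    loop_len: int,
    inserts: dict[int, tuple[int, int]] | None = None,
    mature_pairs: tuple[int, int] = (0, 21),
    mature_loop_ext: int = 0,
    arm: str = "5p",
    pair_weights: dict[str, float] | None = None,
    loop_base: str = "A",
    fill5: str = "A",
    fill3: str = "C",
    with_3p_mature: bool = False,
) -> HairpinDesign:
    """Construct a stem-loop sequence with a prescribed pairing layout.

    ``inserts[q] = (n5, n3)`` places n5/n3 unpaired nucleotides between
    stem pairs q and q+1 on the 5'/3' strand.  The mature spans stem
    pairs ``mature_pairs`` (inclusive) on the chosen arm, optionally
    extended ``mature_loop_ext`` nt into the terminal loop.
    """
    inserts = inserts or {}
    weights = pair_weights or _STRONG_WEIGHTS
    kinds = sorted(weights)
    probs = np.array([weights[k] for k in kinds], dtype=float)
    probs /= probs.sum()
    choice = rng.choice(len(kinds), size=n_pairs, p=probs)
    b5, b3 = [], []
    for c in choice:
        x, y = _PAIR_BASES[kinds[c]]
        b5.append(x)
        b3.append(y)
    five: list[str] = []
    pos5 = [0] * n_pairs
    for p in range(n_pairs):
        pos5[p] = len(five)
        five.append(b5[p])
        if p in inserts and inserts[p][0]:
            five.extend(fill5 * inserts[p][0])
    loop = [loop_base] * loop_len
    offset = len(five) + loop_len
    three: list[str] = []
    pos3 = [0] * n_pairs
    for p in range(n_pairs - 1, -1, -1):
        pos3[p] = offset + len(three)
        three.append(b3[p])
        if p > 0 and (p - 1) in inserts and inserts[p - 1][1]:
            three.extend(fill3 * inserts[p - 1][1])
    seq = "".join(five + loop + three)
    m_lo, m_hi = mature_pairs
    if arm == "5p":
        ms = pos5[m_lo]
        me = pos5[m_hi] + 1 + mature_loop_ext
    else:
        ms = pos3[m_hi] - mature_loop_ext
        me = pos3[m_lo] + 1
    mature_3p = None
    if with_3p_mature:
        lo3, hi3 = mature_pairs
        mature_3p = (pos3[hi3], pos3[lo3] + 1)
    return HairpinDesign(seq, (ms, me), arm, mature_3p)


# per-criterion decoy layouts: each violates exactly one criterion
_DECOY_LAYOUTS: dict[str, dict] = {
    "c1": dict(n_pairs=30, loop_len=8, inserts={24: (14, 0)}, mature_pairs=(0, 21)),
    # The free-energy decoy must stay above -15 kcal/mol while keeping >16
    # stem pairs, which forces an all-A:U stem; its loop and (at embedding
    # time) its flanks are C-only so that no competing structure can form
    # in the folding window.
    "c2": dict(n_pairs=17, loop_len=16, mature_pairs=(0, 16),
               mature_loop_ext=1,
               pair_weights={"AU": 0.38, "UA": 0.32, "GU": 0.15, "UG": 0.15},
               loop_base="C"),
    "c3": dict(n_pairs=26, loop_len=25, mature_pairs=(0, 21)),
    "c4": dict(n_pairs=30, loop_len=8, inserts={10: (6, 0)}, mature_pairs=(0, 15)),
    "c5": dict(n_pairs=30, loop_len=8,
               inserts={3: (2, 2), 6: (2, 2), 9: (2, 2), 12: (2, 2)},
               mature_pairs=(0, 13)),
    "c6": dict(n_pairs=26, loop_len=15, mature_pairs=(11, 25), mature_loop_ext=7),
    "c7": dict(n_pairs=16, loop_len=18, mature_pairs=(0, 15), mature_loop_ext=2),
    "c8": dict(n_pairs=18, loop_len=4, mature_pairs=(0, 17)),
    "c9": dict(n_pairs=30, loop_len=8, inserts={8: (5, 5)}, mature_pairs=(0, 16)),
    "c10": dict(n_pairs=30, loop_len=8,
                inserts={4: (1, 0), 9: (1, 0), 14: (1, 0)}, mature_pairs=(0, 18)),
    "c11": dict(n_pairs=30, loop_len=8,
                inserts={2: (2, 2), 5: (2, 2), 8: (3, 3)}, mature_pairs=(0, 10)),
}

_PASSING_LAYOUT = dict(n_pairs=26, loop_len=8, mature_pairs=(2, 23))


class GenerationError(RuntimeError):
    pass


def design_passing_hairpin(rng: np.random.Generator, arm: str = "5p",
                           with_3p_mature: bool = False,
                           max_tries: int = 200) -> HairpinDesign:
    """A hairpin whose mature passes all 11 criteria (verified by folding)."""
    for _ in range(max_tries):
        d = make_hairpin(rng, arm=arm, with_3p_mature=with_3p_mature,
                         **_PASSING_LAYOUT)
        if not _mature_unique(d):
            continue
        _, _, verdict = evaluate_locus(d.sequence, d.mature)
        if verdict.overall:
            return d
    raise GenerationError("could not design a criteria-passing hairpin")


def _mature_unique(d: HairpinDesign) -> bool:
    """The mature must occur exactly once and its reverse complement not
    at all, so genome placement is unambiguous."""
    matures = [d.sequence[s:e] for s, e in [d.mature] +
               ([d.mature_3p] if d.mature_3p else [])]
    for m in matures:
        if d.sequence.count(m) != 1 or revcomp(m) in d.sequence:
            return False
    return True


def design_decoy(criterion: str, rng: np.random.Generator,
                 max_tries: int = 400) -> HairpinDesign:
    """A hairpin failing exactly ``criterion`` (verified by folding)."""
    if criterion not in _DECOY_LAYOUTS:
        raise ValueError(f"unknown criterion {criterion!r}")
    for _ in range(max_tries):
        d = make_hairpin(rng, **_DECOY_LAYOUTS[criterion])
        if not _mature_unique(d):
            continue
        _, _, verdict = evaluate_locus(d.sequence, d.mature)
        if verdict.failing == [criterion]:
            return d
    raise GenerationError(f"could not design a decoy for {criterion}")


# ---------------------------------------------------------------------------
# reference catalog

_BASES = np.array(list("ACGT"))


def _random_seq(rng: np.random.Generator, n: int, alphabet: str = "ACGT") -> str:
    return "".join(rng.choice(list(alphabet), size=n))


@dataclass
class PlantedLocus:
    entity_id: str
    kind: str                    # novel | decoy | homolog
    start: int                   # genome coordinates of the hairpin
    end: int
    mature_start: int
    mature_end: int
    strand: str = "+"
    arm: str = "5p"
    criterion: str = ""          # designated failing criterion for decoys


@dataclass
class ReferenceBundle:
    chrom: str
    genome: str
    known: list[PrecursorRecord]
    other_species: list[PrecursorRecord]
    contaminants: list[tuple[str, str, str]]
    utrs: dict[str, str]
    annotations: pd.DataFrame
    entities: pd.DataFrame       # per-miRNA truth: id, kind, mature, context
    loci: list[PlantedLocus]
    target_truth: pd.DataFrame   # planted miRNA -> gene sites


def _embed_block(rng: np.random.Generator, design: HairpinDesign,
                 check: str | None, criterion: str = "",
                 gap: int = 100, max_tries: int = 60,
                 flank_base: str | None = None,
                 flank_alphabet: str = "ACGT") -> tuple[str, int, int]:
    """Wrap a designed hairpin in flanking background and verify that the
    +/-80 nt mature context still yields the intended verdict.

    ``check`` is ``"pass"`` or ``"fail_exact"`` (None skips verification).
    ``flank_base`` forces homopolymer flanks -- used for the free-energy
    decoy, whose marginal stem would otherwise be overwhelmed by chance
    background structure in the folding window.
    """
    ms, me = design.mature
    for attempt in range(max_tries):
        if flank_base:
            left = right = flank_base * gap
        else:
            left = _random_seq(rng, gap, flank_alphabet)
            right = _random_seq(rng, gap, flank_alphabet)
        block = left + design.sequence + right
        gms, gme = gap + ms, gap + me
        cs, ce = gms - FLANK, gme + FLANK
        ctx = block[cs:ce]
        _, _, verdict = evaluate_locus(ctx, (FLANK, FLANK + (me - ms)))
        if check == "pass" and not verdict.overall:
            continue
        if check == "fail_exact" and verdict.failing != [criterion]:
            continue
        return block, gap, gap + len(design.sequence)
    raise GenerationError(f"could not embed hairpin (check={check} {criterion})")


def _design_and_embed(rng: np.random.Generator, kind: str, criterion: str = "",
                      max_redesigns: int = 25):
    """Design a hairpin and embed it in verified flanking background,
    redesigning the hairpin itself when no acceptable flanks are found."""
    last: GenerationError | None = None
    for _ in range(max_redesigns):
        if kind == "decoy":
            d = design_decoy(criterion, rng)
            check = "fail_exact"
            flank_base = "C" if criterion == "c2" else None
            # A/C flanks cannot pair with each other, so chance background
            # helices cannot extend the designed stem from outside and
            # change which criterion the decoy fails.
            flank_alphabet = "AC"
        else:
            d = design_passing_hairpin(rng)
            check = "pass" if kind == "novel" else None
            flank_base = None
            flank_alphabet = "ACGT"
        try:
            block, hs, he = _embed_block(rng, d, check=check,
                                         criterion=criterion,
                                         max_tries=1 if flank_base else 25,
                                         flank_base=flank_base,
                                         flank_alphabet=flank_alphabet)
        except GenerationError as exc:
            last = exc
            continue
        return d, block, hs, he
    raise GenerationError(f"embedding failed for {kind} {criterion}: {last}")


def build_reference_catalog(config: SimulationConfig) -> ReferenceBundle:
    """Generate the full reference bundle with its truth tables."""
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 11]))
    chrom = "chrS"

    known: list[PrecursorRecord] = []
    entity_rows: list[dict] = []
    for i in range(config.n_known_mirnas):
        with_3p = i % 2 == 0
        d = design_passing_hairpin(rng, with_3p_mature=with_3p)
        pid = f"ssc-mir-{100 + i}"
        mature = {"5p": d.mature}
        names = {"5p": f"ssc-miR-{100 + i}-5p"}
        if with_3p and d.mature_3p is not None:
            mature["3p"] = d.mature_3p
            names["3p"] = f"ssc-miR-{100 + i}-3p"
        prec = PrecursorRecord(pid, "ssc", d.sequence, mature, names)
        known.append(prec)
        for arm, (ms, me) in mature.items():
            entity_rows.append(_entity_row(
                entity_id=names[arm], kind="known", mature=d.sequence[ms:me],
                ctx_left=d.sequence[max(0, ms - 4):ms],
                ctx_right=d.sequence[me:me + 4],
                reference=pid, arm=arm,
            ))

    # genomic blocks: homologs, novels, decoys
    other: list[PrecursorRecord] = []
    loci: list[PlantedLocus] = []
    blocks: list[tuple[str, str]] = []  # (entity/locus id, block sequence)
    block_meta: list[dict] = []

    for i in range(config.n_homolog_mirnas):
        d, block, hs, he = _design_and_embed(rng, "homolog")
        pid = f"hsa-mir-{900 + i}"
        name = f"hsa-miR-{900 + i}-5p"
        other.append(PrecursorRecord(pid, "hsa", d.sequence,
                                     {"5p": d.mature}, {"5p": name}))
        ms, me = d.mature
        blocks.append((name, block))
        block_meta.append(dict(entity_id=name, kind="homolog", hs=hs, he=he,
                               ms=hs + ms, me=hs + me, arm="5p", criterion="",
                               reference=pid,
                               mature=d.sequence[ms:me],
                               ctx_left=block[hs + ms - 4:hs + ms],
                               ctx_right=block[hs + me:hs + me + 4]))
    # foreign precursors NOT present in the genome (must stay unassigned)
    for i in range(2):
        d = design_passing_hairpin(rng)
        pid = f"hsa-mir-{990 + i}"
        other.append(PrecursorRecord(pid, "hsa", d.sequence, {"5p": d.mature},
                                     {"5p": f"hsa-miR-{990 + i}-5p"}))

    for i in range(config.n_novel_loci):
        d, block, hs, he = _design_and_embed(rng, "novel")
        eid = f"novel-{i + 1}"
        ms, me = d.mature
        blocks.append((eid, block))
        block_meta.append(dict(entity_id=eid, kind="novel", hs=hs, he=he,
                               ms=hs + ms, me=hs + me, arm=d.arm, criterion="",
                               reference=chrom, mature=d.sequence[ms:me],
                               ctx_left=block[hs + ms - 4:hs + ms],
                               ctx_right=block[hs + me:hs + me + 4]))

    for i in range(config.n_decoy_loci):
        crit = CRITERION_NAMES[i % len(CRITERION_NAMES)]
        d, block, hs, he = _design_and_embed(rng, "decoy", crit)
        eid = f"decoy-{crit}-{i + 1}"
        ms, me = d.mature
        blocks.append((eid, block))
        block_meta.append(dict(entity_id=eid, kind="decoy", hs=hs, he=he,
                               ms=hs + ms, me=hs + me, arm=d.arm, criterion=crit,
                               reference=chrom, mature=d.sequence[ms:me],
                               ctx_left=block[hs + ms - 4:hs + ms],
                               ctx_right=block[hs + me:hs + me + 4]))

    # assemble the genome: background / block / background / block ...
    pieces: list[str] = []
    cursor = 0
    used = sum(len(b) for _, b in blocks)
    spare = max(config.genome_length - used, 200 * (len(blocks) + 1))
    gap_sizes = _split_gaps(rng, spare, len(blocks) + 1)
    genome_parts = []
    for (eid, block), gap in zip(blocks, gap_sizes[:-1]):
        genome_parts.append(_random_seq(rng, gap))
        cursor += gap
        meta = next(m for m in block_meta if m["entity_id"] == eid)
        meta["genome_start"] = cursor
        genome_parts.append(block)
        cursor += len(block)
    genome_parts.append(_random_seq(rng, gap_sizes[-1]))
    genome = "".join(genome_parts)

    for meta in block_meta:
        off = meta["genome_start"]
        loci.append(PlantedLocus(
            entity_id=meta["entity_id"], kind=meta["kind"],
            start=off + meta["hs"], end=off + meta["he"],
            mature_start=off + meta["ms"], mature_end=off + meta["me"],
            arm=meta["arm"], criterion=meta["criterion"],
        ))
        entity_rows.append(_entity_row(
            entity_id=meta["entity_id"], kind=meta["kind"],
            mature=meta["mature"], ctx_left=meta["ctx_left"],
            ctx_right=meta["ctx_right"], reference=meta["reference"],
            arm=meta["arm"], criterion=meta["criterion"],
        ))

    contaminants = []
    for i, family in enumerate(["rRNA", "tRNA", "snRNA", "snoRNA"] * 4):
        length = int(rng.integers(80, 150))
        contaminants.append((family, f"{family}-{i + 1}", _random_seq(rng, length)))

    entities = pd.DataFrame(entity_rows)
    utrs, target_truth = _build_utrs(rng, config, entities)
    annotations = _build_annotations(rng, config)

    return ReferenceBundle(chrom, genome, known, other, contaminants, utrs,
                           annotations, entities, loci, target_truth)


def _entity_row(entity_id, kind, mature, ctx_left, ctx_right, reference, arm,
                criterion="") -> dict:
    return dict(entity_id=entity_id, kind=kind, mature=mature,
                ctx_left=ctx_left, ctx_right=ctx_right, reference=reference,
                arm=arm, criterion=criterion)


def _split_gaps(rng: np.random.Generator, total: int, n: int) -> list[int]:
    w = rng.dirichlet(np.full(n, 5.0))
    sizes = np.maximum((w * total).astype(int), 200)
    return list(sizes)


def _build_utrs(rng, config, entities):
    """Random 3'UTRs with perfect-complement target sites planted for the
    known/homolog/novel matures."""
    genes = [f"G{i + 1:04d}" for i in range(config.n_genes)]
    utrs = {g: _random_seq(rng, config.utr_length) for g in genes}
    rows = []
    lo, hi = config.targets_per_mirna
    mirnas = entities[entities.kind.isin(["known", "homolog", "novel"])]
    for _, ent in mirnas.iterrows():
        n_t = int(rng.integers(lo, hi + 1))
        chosen = rng.choice(len(genes), size=n_t, replace=False)
        site = revcomp(ent.mature)
        for gi in chosen:
            g = genes[gi]
            pos = int(rng.integers(20, config.utr_length - len(site) - 20))
            utrs[g] = utrs[g][:pos] + site + utrs[g][pos + len(site):]
            rows.append(dict(mirna=ent.entity_id, gene=g, start=pos,
                             end=pos + len(site)))
    return utrs, pd.DataFrame(rows)


def _build_annotations(rng, config):
    genes = [f"G{i + 1:04d}" for i in range(config.n_genes)]
    go_terms = [(f"GO:{7000 + i:07d}", f"biological process {i + 1}", "GO_BP")
                for i in range(20)]
    kegg = [(f"ko{4000 + i:05d}", f"signaling pathway {i + 1}", "KEGG")
            for i in range(12)]
    rows = []
    for g in genes:
        for tid, tname, ont in go_terms + kegg:
            if rng.random() < 0.08:
                rows.append(dict(gene=g, term_id=tid, term_name=tname,
                                 ontology=ont))
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# counts and reads

def simulate_counts(
    config: SimulationConfig,
    entities: pd.DataFrame,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Negative-binomial counts per entity x library with planted DE.

    Returns (counts, truth) where truth carries each entity's baseline
    mean, per-stress-group log2 fold change and DE flag.  Fold changes
    are planted between the control (first group) and *each* stress
    group, mirroring a shared stress response.
    """
    if config.nb_dispersion < 0:
        raise ConfigError("nb_dispersion must be >= 0")
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 23]))
    ids = list(entities.entity_id)
    n = len(ids)
    weights = rng.gamma(2.0, 1.0, size=n)
    clean_target = config.reads_per_library * (1.0 - config.contamination_fraction)
    base_mean = weights / weights.sum() * clean_target

    lfc = np.zeros(n)
    n_de = int(round(config.de_fraction * n))
    de_idx = rng.choice(n, size=n_de, replace=False) if n_de else np.array([], int)
    signs = np.where(np.arange(n_de) % 2 == 0, 1.0, -1.0)
    lfc[de_idx] = signs * config.planted_log2fc

    control = config.groups[0]
    counts = {}
    for lib in config.libraries:
        group = lib.rsplit("_", 1)[0]
        mu = base_mean * np.where(group == control, 1.0, 2.0 ** lfc)
        counts[lib] = _nb_draw(rng, mu, config.nb_dispersion)
    counts_df = pd.DataFrame(counts, index=ids)
    counts_df.index.name = "entity_id"

    truth = entities.copy()
    truth["baseline_mean"] = base_mean
    truth["log2fc"] = lfc
    truth["de"] = lfc != 0.0
    return counts_df, truth


def _nb_draw(rng, mu, dispersion):
    if dispersion == 0:
        return rng.poisson(mu)
    r = 1.0 / dispersion
    p = r / (r + mu)
    return rng.negative_binomial(r, p)


_SHIFT_PROBS = {0: [1.0], 1: [0.15, 0.70, 0.15],
                2: [0.03, 0.12, 0.70, 0.12, 0.03]}


def synthesize_reads(
    config: SimulationConfig,
    bundle: ReferenceBundle,
    counts: pd.DataFrame,
    outdir: str | Path,
) -> dict[str, Path]:
    """Write one FASTQ per library realising the simulated counts.

    Each clean read is a sampled mature or isomiR (end shifts drawn
    within the configured window using flanking precursor/genome
    context, at most one substitution) followed by the 3' adapter,
    padded/truncated to the read length.  The configured fraction of
    reads is contamination: ncRNA fragments, adapter dimers and
    low-complexity sequence in a fixed 50/25/25 split.
    """
    if len(config.adapter_sequence) > config.read_length:
        raise ConfigError("adapter longer than read_length")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 37]))
    ent = bundle.entities.set_index("entity_id")
    w = config.isomir_shift_window
    shifts = list(range(-w, w + 1))
    probs = _SHIFT_PROBS[w] if w in _SHIFT_PROBS else None
    paths = {}
    f = config.contamination_fraction
    for lib in counts.columns:
        path = outdir / f"{lib}.fastq"
        paths[lib] = path
        serial = 0
        with open(path, "w") as out:
            for eid, c in counts[lib].items():
                row = ent.loc[eid]
                for _ in range(int(c)):
                    serial += 1
                    insert = _isomir(rng, row.mature, row.ctx_left,
                                     row.ctx_right, shifts, probs,
                                     config.substitution_rate)
                    _write_read(out, lib, serial, insert, config, f"clean:{eid}")
            n_clean = int(counts[lib].sum())
            n_contam = int(round(n_clean * f / (1.0 - f))) if f < 1 else 0
            for k in range(n_contam):
                serial += 1
                u = rng.random()
                if u < NCRNA_SHARE:
                    fam, cid, seq = bundle.contaminants[
                        int(rng.integers(len(bundle.contaminants)))]
                    L = int(rng.integers(18, 27))
                    p = int(rng.integers(0, len(seq) - L + 1))
                    _write_read(out, lib, serial, seq[p:p + L], config,
                                f"contaminant:{fam}")
                elif u < NCRNA_SHARE + ADAPTER_DIMER_SHARE:
                    _write_read(out, lib, serial, "", config, "adapter_dimer")
                else:
                    base = "ACGT"[int(rng.integers(4))]
                    L = int(rng.integers(20, 25))
                    _write_read(out, lib, serial, base * L, config,
                                "low_complexity")
    return paths


def _isomir(rng, mature, ctx_left, ctx_right, shifts, probs, sub_rate):
    d5 = int(rng.choice(shifts, p=probs)) if len(shifts) > 1 else 0
    d3 = int(rng.choice(shifts, p=probs)) if len(shifts) > 1 else 0
    seq = mature
    if d5 > 0 and len(ctx_left) >= d5:
        seq = ctx_left[len(ctx_left) - d5:] + seq
    elif d5 < 0:
        seq = seq[-d5:]
    if d3 > 0 and len(ctx_right) >= d3:
        seq = seq + ctx_right[:d3]
    elif d3 < 0:
        seq = seq[:d3]
    if not (18 <= len(seq) <= 26):
        seq = mature
    if sub_rate and rng.random() < sub_rate:
        pos = int(rng.integers(len(seq)))
        alt = "ACGT"[int(rng.integers(4))]
        while alt == seq[pos]:
            alt = "ACGT"[int(rng.integers(4))]
        seq = seq[:pos] + alt + seq[pos + 1:]
    return seq


def _write_read(out, lib, serial, insert, config, label):
    read = (insert + config.adapter_sequence).ljust(config.read_length, "A")
    read = read[:config.read_length]
    out.write(f"@{lib}.{serial} {label}\n{read}\n+\n"
              f"{'I' * config.read_length}\n")


# ---------------------------------------------------------------------------
# on-disk bundle

def write_reference_bundle(bundle: ReferenceBundle, outdir: str | Path) -> dict[str, Path]:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}

    def fasta(name, records):
        p = outdir / name
        SeqIO.write(records, str(p), "fasta")
        paths[name] = p

    fasta("genome.fa", [SeqRecord(Seq(bundle.genome), id=bundle.chrom, description="")])
    fasta("known_precursors.fa",
          [SeqRecord(Seq(p.sequence), id=p.id, description=p.species)
           for p in bundle.known])
    fasta("other_precursors.fa",
          [SeqRecord(Seq(p.sequence), id=p.id, description=p.species)
           for p in bundle.other_species])
    fasta("contaminants.fa",
          [SeqRecord(Seq(seq), id=cid, description=family)
           for family, cid, seq in bundle.contaminants])
    fasta("utr.fa", [SeqRecord(Seq(s), id=g, description="")
                     for g, s in sorted(bundle.utrs.items())])

    for fname, precs in [("known_mature.bed", bundle.known),
                         ("other_mature.bed", bundle.other_species)]:
        bed_rows = []
        for prec in precs:
            for arm, (s, e) in sorted(prec.mature.items()):
                bed_rows.append([prec.id, s, e, prec.mature_names[arm], 0, "+"])
        bed = pd.DataFrame(bed_rows, columns=["chrom", "start", "end", "name",
                                              "score", "strand"])
        paths[fname] = outdir / fname
        bed.to_csv(paths[fname], sep="\t", header=False, index=False)

    for name, df in [("annotations.tsv", bundle.annotations),
                     ("truth_entities.tsv", bundle.entities),
                     ("truth_targets.tsv", bundle.target_truth)]:
        paths[name] = outdir / name
        df.to_csv(paths[name], sep="\t", index=False)

    loci_df = pd.DataFrame([dataclasses.asdict(l) for l in bundle.loci])
    paths["truth_loci.tsv"] = outdir / "truth_loci.tsv"
    loci_df.to_csv(paths["truth_loci.tsv"], sep="\t", index=False)
    return paths


def simulate_ct_table(
    config: SimulationConfig,
    truth: pd.DataFrame,
    n_assays: int = 8,
    reference_gene: str = "U6",
) -> pd.DataFrame:
    """Synthetic qPCR Ct table for the 2^-ddCt validation stage.

    Picks the strongest planted DE miRNAs (plus non-DE fillers) and emits
    per-sample Ct values whose group differences encode the planted fold
    changes, normalised against a stable reference gene.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 53]))
    de = truth[truth.de].sort_values("baseline_mean", ascending=False)
    non_de = truth[~truth.de].sort_values("baseline_mean", ascending=False)
    assays = list(de.entity_id[:n_assays])
    assays += list(non_de.entity_id[: max(0, n_assays - len(assays))])
    lfc = dict(zip(truth.entity_id, truth.log2fc))
    control = config.groups[0]
    rows = []
    for lib in config.libraries:
        group = lib.rsplit("_", 1)[0]
        ref_ct = 18.0 + rng.normal(0, 0.15)
        rows.append(dict(sample=lib, group=group, gene=reference_gene,
                         reference=reference_gene, ct=round(ref_ct, 3)))
        for gene in assays:
            delta = lfc[gene] if group != control else 0.0
            ct = 24.0 - delta + rng.normal(0, 0.2)
            rows.append(dict(sample=lib, group=group, gene=gene,
                             reference=reference_gene, ct=round(ct, 3)))
    return pd.DataFrame(rows)


def generate_dataset(config: SimulationConfig, outdir: str | Path):
    """Build catalog + counts + reads and write everything under ``outdir``.

    Returns (bundle, counts, truth, paths).
    """
    outdir = Path(outdir)
    bundle = build_reference_catalog(config)
    counts, truth = simulate_counts(config, bundle.entities)
    paths = write_reference_bundle(bundle, outdir)
    fastqs = synthesize_reads(config, bundle, counts, outdir / "reads")
    paths.update({f"reads/{k}": v for k, v in fastqs.items()})
    counts_path = outdir / "truth_counts.tsv"
    counts.to_csv(counts_path, sep="\t")
    paths["truth_counts.tsv"] = counts_path
    truth_path = outdir / "truth_expression.tsv"
    truth.to_csv(truth_path, sep="\t", index=False)
    paths["truth_expression.tsv"] = truth_path
    config.to_yaml(outdir / "config.yaml")
    return bundle, counts, truth, paths
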