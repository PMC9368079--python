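"""End-to-end orchestration: simulate -> preprocess -> annotate ->
hairpin -> differential expression -> targets -> enrichment/networks.

Each stage writes TSV outputs under the run directory and registers them
(with SHA-256 checksums and its parameters) in ``manifest.json``.  Runs
are single-process and deterministic: the same config and seed reproduce
byte-identical tables.  A truth-aware recovery report (DE sensitivity
and false-discovery proportion, novel-hairpin precision/recall, known
mature recovery) is emitted for synthetic runs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import annotate as ann
from . import diffexpr as de
from . import enrichnet as en
from . import targets as tg
from .hairpin import CRITERION_NAMES, evaluate_locus
from .preprocess import run_preprocess
from .synthetic import SimulationConfig, generate_dataset

log = logging.getLogger("mirforge")


@dataclass
class PipelineConfig:
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    outdir: str | Path = "run"
    alpha: float = 0.05
    fc_threshold: float = 1.0
    mapping_window: int = 2
    max_mismatch: int = 1
    flank: int = 80
    predictor: tg.PredictorConfig = field(default_factory=tg.PredictorConfig)
    min_mirnas_per_pathway: int = 3

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        import yaml
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        sim = SimulationConfig(**raw.pop("simulation", {}))
        pred = tg.PredictorConfig(**raw.pop("predictor", {}))
        return cls(simulation=sim, predictor=pred, **raw)


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


class PipelineRun:
    """Mutable state threaded through the stages of one run."""

    def __init__(self, config: PipelineConfig):
        self.config = config
        self.outdir = Path(config.outdir)
        self.outdir.mkdir(parents=True, exist_ok=True)
        self.manifest: dict = {"stages": [], "config": _config_dict(config)}
        self.bundle = None
        self.counts = None
        self.truth = None
        self.tags = None
        self.report = None
        self.mapping = None
        self.loci = None
        self.verdicts = None
        self.de_tables: dict[str, pd.DataFrame] = {}
        self.de_mirnas: dict[str, str] = {}
        self.sites = None
        self.enrichment = None
        self.networks = {}

    def record(self, stage: str, outputs: dict[str, Path], **params) -> None:
        self.manifest["stages"].append({
            "stage": stage,
            "outputs": {str(k): _sha256(Path(v)) for k, v in outputs.items()},
            "params": params,
        })

    def write_manifest(self) -> Path:
        path = self.outdir / "manifest.json"
        with open(path, "w") as fh:
            json.dump(self.manifest, fh, indent=2, sort_keys=True, default=str)
        return path


def _config_dict(config: PipelineConfig) -> dict:
    d = dataclasses.asdict(config)
    d["outdir"] = str(d["outdir"])
    return d


def run_pipeline(config: PipelineConfig) -> PipelineRun:
    """Execute all stages in order; aborts with the failing stage's name,
    retaining any partial outputs already written."""
    run = PipelineRun(config)
    stages = [
        ("simulate", _stage_simulate),
        ("preprocess", _stage_preprocess),
        ("annotate", _stage_annotate),
        ("hairpin", _stage_hairpin),
        ("diffexpr", _stage_diffexpr),
        ("targets", _stage_targets),
        ("enrichnet", _stage_enrichnet),
    ]
    for name, fn in stages:
        log.info("stage %s", name)
        try:
            fn(run)
        except Exception as exc:
            run.write_manifest()
            raise StageError(name, exc) from exc
    _recovery_report(run)
    run.write_manifest()
    return run


def _stage_simulate(run: PipelineRun) -> None:
    cfg = run.config.simulation
    simdir = run.outdir / "sim"
    run.bundle, run.counts, run.truth, paths = generate_dataset(cfg, simdir)
    run.record("simulate", paths, seed=cfg.seed)


def _stage_preprocess(run: PipelineRun) -> None:
    cfg = run.config.simulation
    fastqs = {lib: run.outdir / "sim" / "reads" / f"{lib}.fastq"
              for lib in cfg.libraries}
    run.tags, run.report = run_preprocess(
        fastqs, cfg.adapter_sequence, run.bundle.contaminants)
    tag_path = run.outdir / "tags.tsv"
    rep_path = run.outdir / "filter_report.tsv"
    run.tags.to_csv(tag_path, sep="\t", index=False)
    run.report.to_csv(rep_path, sep="\t", index=False)
    run.record("preprocess", {"tags.tsv": tag_path,
                              "filter_report.tsv": rep_path},
               adapter=cfg.adapter_sequence)


def _stage_annotate(run: PipelineRun) -> None:
    c = run.config
    run.mapping, run.loci = ann.run_cascade(
        run.tags, run.bundle.known, run.bundle.other_species,
        run.bundle.genome, run.bundle.chrom,
        window=c.mapping_window, max_mismatch=c.max_mismatch, flank=c.flank)
    path = run.outdir / "mapping.tsv"
    run.mapping.to_csv(path, sep="\t", index=False)
    bed = pd.DataFrame(
        [[l.chrom, l.start, l.end, l.tag, 0, l.strand] for l in run.loci])
    bed_path = run.outdir / "candidate_loci.bed"
    bed.to_csv(bed_path, sep="\t", header=False, index=False)
    run.record("annotate", {"mapping.tsv": path, "candidate_loci.bed": bed_path},
               window=c.mapping_window, max_mismatch=c.max_mismatch)


def cluster_candidate_loci(loci: list[ann.CandidateLocus],
                           totals: dict[str, int]) -> list[dict]:
    """Group overlapping candidate placements (isomiR stacks) into loci,
    keeping the highest-count tag as each cluster's representative."""
    clusters: list[dict] = []
    for locus in sorted(loci, key=lambda l: (l.chrom, l.strand, l.start)):
        last = clusters[-1] if clusters else None
        if (last and last["chrom"] == locus.chrom
                and last["strand"] == locus.strand
                and locus.start <= last["end"]):
            last["members"].append(locus)
            last["end"] = max(last["end"], locus.end)
        else:
            clusters.append(dict(chrom=locus.chrom, strand=locus.strand,
                                 start=locus.start, end=locus.end,
                                 members=[locus]))
    for cl in clusters:
        cl["rep"] = max(cl["members"],
                        key=lambda l: (totals.get(l.tag, 0), l.tag))
    return clusters


def _stage_hairpin(run: PipelineRun) -> None:
    totals = dict(zip(run.tags["sequence"], run.tags["total"]))
    clusters = cluster_candidate_loci(run.loci, totals)
    rows = []
    structures = []
    for cl in clusters:
        rep = cl["rep"]
        structure, features, verdict = evaluate_locus(
            rep.context, rep.mature_in_context)
        loop_mid = None
        if structure.pairs:
            chain_inner = max(structure.pairs, key=lambda p: p[0])
            loop_mid = (chain_inner[0] + chain_inner[1]) / 2
        arm = "5p"
        if loop_mid is not None and rep.mature_in_context[0] > loop_mid:
            arm = "3p"
        row = dict(chrom=cl["chrom"], start=cl["start"], end=cl["end"],
                   strand=cl["strand"], tag=rep.tag,
                   n_tags=len(cl["members"]), mfe=structure.mfe,
                   arm=arm, overall=verdict.overall)
        row.update({c: verdict.criteria[c] for c in CRITERION_NAMES})
        rows.append(row)
        structures.append(f">{cl['chrom']}:{cl['start']}-{cl['end']}({cl['strand']})\n"
                          + structure.vienna_lines())
    run.verdicts = pd.DataFrame(rows)
    path = run.outdir / "hairpin_verdicts.tsv"
    run.verdicts.to_csv(path, sep="\t", index=False)
    db_path = run.outdir / "hairpin_structures.txt"
    db_path.write_text("\n".join(structures) + ("\n" if structures else ""))
    run.record("hairpin", {"hairpin_verdicts.tsv": path,
                           "hairpin_structures.txt": db_path},
               flank=run.config.flank)


def _named_count_matrix(run: PipelineRun) -> pd.DataFrame:
    """Aggregate tag counts by assigned miRNA name (isomiRs stay separate);
    unassigned tags are dropped."""
    lib_cols = [c for c in run.tags.columns if c not in ("sequence", "total")]
    merged = run.tags.merge(run.mapping[["sequence", "name", "category"]],
                            on="sequence")
    named = merged[merged["category"] != "unassigned"]
    return named.groupby("name")[lib_cols].sum()


def _stage_diffexpr(run: PipelineRun) -> None:
    cfg = run.config.simulation
    counts = _named_count_matrix(run)
    matrix = de.CountMatrix(
        counts, {lib: lib.rsplit("_", 1)[0] for lib in counts.columns})
    control = cfg.groups[0]
    outputs = {}
    for group in cfg.groups[1:]:
        res = de.test_differential(matrix, control, group)
        table, tallies = de.call_demirnas(res, run.config.alpha,
                                          run.config.fc_threshold)
        key = f"{control}_vs_{group}"
        run.de_tables[key] = table
        path = run.outdir / f"de_{key}.tsv"
        table.to_csv(path, sep="\t", index=False)
        outputs[path.name] = path
        log.info("%s: %d DE (%d up, %d down)", key, tallies["total_de"],
                 tallies["up"], tallies["down"])
    z = de.zscore_matrix(de.normalize_cpm(counts))
    zpath = run.outdir / "expression_zscores.tsv"
    z.to_csv(zpath, sep="\t")
    outputs[zpath.name] = zpath
    run.record("diffexpr", outputs, alpha=run.config.alpha,
               fc_threshold=run.config.fc_threshold)
    seqs = dict(zip(run.mapping["name"], run.mapping["sequence"]))
    for table in run.de_tables.values():
        for _, r in table[table.de].iterrows():
            if r.mirna in seqs:
                run.de_mirnas[r.mirna] = seqs[r.mirna]


def _stage_targets(run: PipelineRun) -> None:
    seed_sites, aligner_sites, both = tg.predict_targets(
        run.de_mirnas, run.bundle.utrs, run.config.predictor)
    run.sites = both
    rows = [dataclasses.asdict(s) | {"predictors": ",".join(sorted(s.predictors))}
            for s in both]
    df = pd.DataFrame(rows, columns=["mirna", "transcript", "start", "end",
                                     "site_type", "score", "energy",
                                     "predictors"])
    path = run.outdir / "target_sites.tsv"
    df.to_csv(path, sep="\t", index=False)
    run.record("targets", {"target_sites.tsv": path},
               score_threshold=run.config.predictor.score_threshold,
               energy_threshold=run.config.predictor.energy_threshold,
               n_seed=len(seed_sites), n_aligner=len(aligner_sites),
               n_intersection=len(both))


def _stage_enrichnet(run: PipelineRun) -> None:
    targets_by_mirna: dict[str, set[str]] = {}
    for s in run.sites:
        targets_by_mirna.setdefault(s.mirna, set()).add(s.transcript)
    all_targets = sorted(set().union(*targets_by_mirna.values())) \
        if targets_by_mirna else []
    background = sorted(run.bundle.utrs)
    enr = en.enrich_terms(all_targets, background, run.bundle.annotations)
    run.enrichment = enr
    epath = run.outdir / "enrichment.tsv"
    enr.to_csv(epath, sep="\t", index=False)

    gene_edges = [(m, g) for m, gs in targets_by_mirna.items() for g in gs]
    gene_net = en.build_bipartite_network(gene_edges)
    run.networks["gene"] = gene_net
    gpath = run.outdir / "network_mirna_gene.tsv"
    en.network_to_edgelist(gene_net).to_csv(gpath, sep="\t", index=False)

    sig = enr[enr["q"] < 0.5] if not enr.empty else enr
    ann_map: dict[str, set[str]] = {}
    for _, r in run.bundle.annotations.iterrows():
        ann_map.setdefault(r["gene"], set()).add(r["term_id"])
    term_edges = []
    sig_terms = set(sig["term_id"]) if not sig.empty else set()
    for m, gs in targets_by_mirna.items():
        terms = set().union(*[ann_map.get(g, set()) for g in gs]) if gs else set()
        term_edges.extend((m, t) for t in terms & sig_terms)
    term_net = en.build_bipartite_network(
        term_edges, min_left_per_right=run.config.min_mirnas_per_pathway)
    run.networks["term"] = term_net
    tpath = run.outdir / "network_mirna_term.tsv"
    en.network_to_edgelist(term_net).to_csv(tpath, sep="\t", index=False)

    hubs = en.rank_hubs(gene_net, 10)
    hpath = run.outdir / "hub_ranking.tsv"
    pd.DataFrame(hubs, columns=["mirna", "degree"]).to_csv(
        hpath, sep="\t", index=False)
    run.record("enrichnet", {"enrichment.tsv": epath,
                             "network_mirna_gene.tsv": gpath,
                             "network_mirna_term.tsv": tpath,
                             "hub_ranking.tsv": hpath},
               min_mirnas_per_pathway=run.config.min_mirnas_per_pathway)


def entity_count_matrix(run: PipelineRun) -> pd.DataFrame:
    """Observed counts aggregated to planted-entity level, using the name
    grammar for known/homolog miRNAs and locus overlap for genomic ones."""
    lib_cols = [c for c in run.tags.columns if c not in ("sequence", "total")]
    truth = run.truth
    base_to_entity = {e: e for e in truth.entity_id}
    locus_by_interval = [(l.start, l.end, l.entity_id) for l in run.bundle.loci]
    merged = run.tags.merge(run.mapping, on="sequence")
    rows = {}
    for _, r in merged.iterrows():
        entity = None
        if r["category"] in ("known_species", "known_homolog"):
            parsed = ann.parse_mirna_name(r["name"])
            entity = base_to_entity.get(parsed["base"])
        elif r["category"] == "novel_candidate" and r["start"] >= 0:
            for s, e, eid in locus_by_interval:
                if r["start"] < e and r["end"] > s:
                    entity = eid
                    break
        if entity is None:
            continue
        if entity not in rows:
            rows[entity] = {c: 0 for c in lib_cols}
        for c in lib_cols:
            rows[entity][c] += int(r[c])
    return pd.DataFrame.from_dict(rows, orient="index").sort_index()


def _recovery_report(run: PipelineRun) -> None:
    cfg = run.config.simulation
    truth = run.truth
    report: dict = {}

    # known mature recovery with exact ends
    known = truth[truth.kind == "known"]
    mapped = run.mapping.set_index("sequence")
    hits = 0
    for m in known.mature:
        if m in mapped.index:
            r = mapped.loc[m]
            if (r.category == "known_species" and r.left_offset == 0
                    and r.right_offset == 0):
                hits += 1
    report["known_recovery"] = hits / len(known) if len(known) else float("nan")

    # novel hairpin precision/recall at locus level
    verdicts = run.verdicts
    truth_loci = {l.entity_id: l for l in run.bundle.loci}
    called = verdicts[verdicts.overall] if verdicts is not None else pd.DataFrame()
    novel_ids = [l.entity_id for l in run.bundle.loci if l.kind == "novel"]
    tp = 0
    fp = 0
    for _, v in called.iterrows():
        hit = None
        for eid, l in truth_loci.items():
            if v.start < l.end and v.end > l.start:
                hit = l
                break
        if hit is not None and hit.kind == "novel":
            tp += 1
        else:
            fp += 1
    found_novel = set()
    for _, v in called.iterrows():
        for eid in novel_ids:
            l = truth_loci[eid]
            if v.start < l.end and v.end > l.start:
                found_novel.add(eid)
    report["novel_recall"] = (len(found_novel) / len(novel_ids)
                              if novel_ids else float("nan"))
    report["novel_precision"] = tp / (tp + fp) if (tp + fp) else float("nan")
    decoy_ids = [l.entity_id for l in run.bundle.loci if l.kind == "decoy"]
    rejected = set(decoy_ids)
    for _, v in called.iterrows():
        for eid in decoy_ids:
            l = truth_loci[eid]
            if v.start < l.end and v.end > l.start:
                rejected.discard(eid)
    report["decoy_rejection"] = (len(rejected) / len(decoy_ids)
                                 if decoy_ids else float("nan"))

    # DE sensitivity / false-discovery proportion at entity level
    ent_counts = entity_count_matrix(run)
    if not ent_counts.empty:
        matrix = de.CountMatrix(
            ent_counts, {lib: lib.rsplit("_", 1)[0] for lib in ent_counts.columns})
        control = cfg.groups[0]
        truth_de = dict(zip(truth.entity_id, truth.de))
        sens_all, fdp_all = [], []
        for group in cfg.groups[1:]:
            res = de.test_differential(matrix, control, group)
            table, _ = de.call_demirnas(res, run.config.alpha,
                                        run.config.fc_threshold)
            called_de = set(table.loc[table.de, "mirna"])
            pos = {e for e, flag in truth_de.items() if flag and e in ent_counts.index}
            tp_ = len(called_de & pos)
            sens_all.append(tp_ / len(pos) if pos else float("nan"))
            fdp_all.append((len(called_de) - tp_) / len(called_de)
                           if called_de else 0.0)
        report["de_sensitivity"] = float(np.nanmean(sens_all))
        report["de_fdp"] = float(np.mean(fdp_all))

    path = run.outdir / "recovery_report.json"
    with open(path, "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
    run.manifest["recovery"] = report
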