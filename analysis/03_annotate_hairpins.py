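#!/usr/bin/env python
"""Run the mapping cascade (species precursors -> foreign precursors ->
genome) and fold every candidate locus with 80 nt flanks through the
11-criterion novel-miRNA classifier."""

import sys
from pathlib import Path

import pandas as pd

sys.path.insert(0, str(Path(__file__).parent))
from common import RESULTS, SIM_DIR

from mirforge.annotate import run_cascade
from mirforge.hairpin import CRITERION_NAMES, evaluate_locus
from mirforge.io import load_genome, load_precursors
from mirforge.workflow import cluster_candidate_loci


def main():
    tags = pd.read_csv(RESULTS / "tags.tsv", sep="\t")
    chrom, genome = load_genome(SIM_DIR / "genome.fa")
    known = load_precursors(SIM_DIR / "known_precursors.fa",
                            SIM_DIR / "known_mature.bed")
    other = load_precursors(SIM_DIR / "other_precursors.fa",
                            SIM_DIR / "other_mature.bed")

    mapping, loci = run_cascade(tags, known, other, genome, chrom)
    mapping.to_csv(RESULTS / "mapping.tsv", sep="\t", index=False)
    print("cascade categories:", mapping["category"].value_counts().to_dict())

    totals = dict(zip(tags["sequence"], tags["total"]))
    clusters = cluster_candidate_loci(loci, totals)
    rows = []
    for cl in clusters:
        rep = cl["rep"]
        _, _, verdict = evaluate_locus(rep.context, rep.mature_in_context)
        row = dict(chrom=cl["chrom"], start=cl["start"], end=cl["end"],
                   strand=cl["strand"], tag=rep.tag, overall=verdict.overall)
        row.update({c: verdict.criteria[c] for c in CRITERION_NAMES})
        rows.append(row)
    verdicts = pd.DataFrame(rows)
    verdicts.to_csv(RESULTS / "hairpin_verdicts.tsv", sep="\t", index=False)
    print(f"candidate loci (clustered): {len(verdicts)}; "
          f"novel hairpin calls: {int(verdicts['overall'].sum())}")
    failed = verdicts[~verdicts["overall"]]
    tallies = {c: int((~failed[c]).sum()) for c in CRITERION_NAMES
               if (~failed[c]).sum()}
    print("criteria violated among rejected loci:", tallies)


if __name__ == "__main__":
    main()
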