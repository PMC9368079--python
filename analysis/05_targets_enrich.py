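#!/usr/bin/env python
"""Predict targets of the DE miRNAs on the 3'UTR catalog (seed scanner
intersected with the complementarity/energy aligner), run GO/KEGG
enrichment and build the miRNA-gene / miRNA-term networks."""

import sys
from pathlib import Path

import pandas as pd

sys.path.insert(0, str(Path(__file__).parent))
from common import RESULTS, SIM_DIR, STUDY

from mirforge.enrichnet import (build_bipartite_network, enrich_terms,
                                network_to_edgelist, rank_hubs)
from mirforge.io import load_utrs
from mirforge.targets import predict_targets


def main():
    mapping = pd.read_csv(RESULTS / "mapping.tsv", sep="\t")
    seqs = dict(zip(mapping["name"].fillna(""), mapping["sequence"]))
    de_mirnas = {}
    control = STUDY.groups[0]
    for group in STUDY.groups[1:]:
        de = pd.read_csv(RESULTS / f"de_{control}_vs_{group}.tsv", sep="\t")
        for name in de.loc[de["de"], "mirna"]:
            if name in seqs:
                de_mirnas[name] = seqs[name]
    utrs = load_utrs(SIM_DIR / "utr.fa")
    print(f"predicting targets for {len(de_mirnas)} DE miRNAs "
          f"on {len(utrs)} 3'UTRs")

    seed_sites, aligner_sites, both = predict_targets(de_mirnas, utrs)
    sites = pd.DataFrame(
        [dict(mirna=s.mirna, transcript=s.transcript, start=s.start,
              end=s.end, site_type=s.site_type, score=s.score,
              energy=s.energy) for s in both])
    sites.to_csv(RESULTS / "target_sites.tsv", sep="\t", index=False)
    print(f"seed sites: {len(seed_sites)}; aligner sites: "
          f"{len(aligner_sites)}; intersected: {len(both)}")

    targets = sorted(set(sites["transcript"])) if len(sites) else []
    annotation = pd.read_csv(SIM_DIR / "annotations.tsv", sep="\t")
    enr = enrich_terms(targets, sorted(utrs), annotation)
    enr.to_csv(RESULTS / "enrichment.tsv", sep="\t", index=False)
    print(f"enriched terms tested: {len(enr)}; top term: "
          + (f"{enr.loc[0, 'term_id']} (p={enr.loc[0, 'p']:.3g})"
             if len(enr) else "none"))

    edges = list({(s.mirna, s.transcript) for s in both})
    net = build_bipartite_network(edges)
    network_to_edgelist(net).to_csv(RESULTS / "network_mirna_gene.tsv",
                                    sep="\t", index=False)
    hubs = rank_hubs(net, 3)
    pd.DataFrame(rank_hubs(net, 10), columns=["mirna", "degree"]).to_csv(
        RESULTS / "hub_ranking.tsv", sep="\t", index=False)
    print("top hub miRNAs (by distinct target genes):",
          ", ".join(f"{m} ({d})" for m, d in hubs))


if __name__ == "__main__":
    main()
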