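#!/usr/bin/env python
"""Call differentially expressed miRNAs (|log2FC| >= 1, p < 0.05)
between the control group and each stress dose."""

import sys
from pathlib import Path

import pandas as pd

sys.path.insert(0, str(Path(__file__).parent))
from common import RESULTS, STUDY

from mirforge.diffexpr import (CountMatrix, call_demirnas, normalize_cpm,
                               test_differential, zscore_matrix)


def main():
    tags = pd.read_csv(RESULTS / "tags.tsv", sep="\t")
    mapping = pd.read_csv(RESULTS / "mapping.tsv", sep="\t")
    lib_cols = [c for c in tags.columns if c not in ("sequence", "total")]
    merged = tags.merge(mapping[["sequence", "name", "category"]],
                        on="sequence")
    counts = (merged[merged["category"] != "unassigned"]
              .groupby("name")[lib_cols].sum())
    matrix = CountMatrix(counts,
                         {lib: lib.rsplit("_", 1)[0] for lib in lib_cols})

    control = STUDY.groups[0]
    for group in STUDY.groups[1:]:
        res = test_differential(matrix, control, group)
        table, tallies = call_demirnas(res, alpha=0.05, fc_threshold=1.0)
        table.to_csv(RESULTS / f"de_{control}_vs_{group}.tsv", sep="\t",
                     index=False)
        print(f"{control} vs {group}: {tallies['total_de']} DEmiRNAs "
              f"({tallies['up']} up, {tallies['down']} down) "
              f"of {len(table)} tested")
    z = zscore_matrix(normalize_cpm(counts))
    z.to_csv(RESULTS / "expression_zscores.tsv", sep="\t",
             float_format="%.4f")


if __name__ == "__main__":
    main()
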