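#!/usr/bin/env python
"""Clean the raw libraries: trim the 3' adapter, drop junk/adapter
dimers/ncRNA families, and collapse reads to unique 18-26 nt tags."""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).parent))
from common import RESULTS, SIM_DIR, STUDY

from mirforge.io import load_contaminants
from mirforge.preprocess import FILTER_CATEGORIES, run_preprocess


def main():
    fastqs = {lib: SIM_DIR / "reads" / f"{lib}.fastq"
              for lib in STUDY.libraries}
    contaminants = load_contaminants(SIM_DIR / "contaminants.fa")
    tags, report = run_preprocess(fastqs, STUDY.adapter_sequence, contaminants)
    tags.to_csv(RESULTS / "tags.tsv", sep="\t", index=False)
    report.to_csv(RESULTS / "filter_report.tsv", sep="\t", index=False)

    total_in = int(report["input_reads"].sum())
    total_out = int(report["surviving"].sum())
    print(f"input reads: {total_in:,}; surviving: {total_out:,} "
          f"({total_out / total_in:.1%})")
    removed = report[FILTER_CATEGORIES].sum()
    print("removed by category:",
          {k: int(v) for k, v in removed.items() if v})
    print(f"unique 18-26 nt tags: {len(tags):,}")
    conserved = (report["input_reads"]
                 == report["surviving"] + report[FILTER_CATEGORIES].sum(axis=1))
    print(f"read accounting exact in all libraries: {bool(conserved.all())}")


if __name__ == "__main__":
    main()
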