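"""Readers for the on-disk reference bundle written by the simulator.

These mirror :func:`mirforge.synthetic.write_reference_bundle`: FASTA via
Biopython, mature annotations as 6-column BED (0-based half-open on the
precursor), contaminant families in the FASTA description.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd
from Bio import SeqIO

from .annotate import PrecursorRecord


def load_genome(path: str | Path) -> tuple[str, str]:
    """Returns (chromosome name, sequence) of a single-record FASTA."""
    records = list(SeqIO.parse(str(path), "fasta"))
    if len(records) != 1:
        raise ValueError(f"{path}: expected a single-chromosome genome")
    return records[0].id, str(records[0].seq)


def load_precursors(fasta: str | Path,
                    mature_bed: str | Path | None = None) -> list[PrecursorRecord]:
    """Precursor FASTA plus optional mature-arm BED annotations.

    BED names are the mature names; the arm (5p/3p) is inferred from the
    name suffix, defaulting to interval order when absent.
    """
    by_prec: dict[str, list] = {}
    if mature_bed is not None:
        bed = pd.read_csv(mature_bed, sep="\t", header=None,
                          names=["chrom", "start", "end", "name",
                                 "score", "strand"])
        for _, r in bed.iterrows():
            by_prec.setdefault(r["chrom"], []).append(r)
    precursors = []
    for rec in SeqIO.parse(str(fasta), "fasta"):
        species = rec.description.split()[-1] if rec.description else ""
        mature, names = {}, {}
        for r in sorted(by_prec.get(rec.id, []), key=lambda r: r["start"]):
            arm = ("5p" if r["name"].endswith("5p")
                   else "3p" if r["name"].endswith("3p")
                   else ("5p" if not mature else "3p"))
            mature[arm] = (int(r["start"]), int(r["end"]))
            names[arm] = r["name"]
        precursors.append(PrecursorRecord(rec.id, species, str(rec.seq),
                                          mature, names))
    return precursors


def load_contaminants(path: str | Path) -> list[tuple[str, str, str]]:
    """(family, id, sequence) triples; family read from the description."""
    out = []
    for rec in SeqIO.parse(str(path), "fasta"):
        family = rec.description.split()[-1]
        out.append((family, rec.id, str(rec.seq)))
    return out


def load_utrs(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}
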