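"""Shared locations and the study-scale simulation design for the
numbered analysis drivers."""

from pathlib import Path

from mirforge.synthetic import SimulationConfig

RESULTS = Path(__file__).resolve().parents[1] / "results" / "analysis"
# raw simulated data (FASTQ libraries, genome) is bulky and regenerable:
# it lives under scratch/, while the analysis tables go to results/
SIM_DIR = Path(__file__).resolve().parents[1] / "scratch" / "analysis" / "sim"

# Scaled-down study design: 3 groups (control + two stress doses) x 3
# replicate libraries, 20,000 reads each -- enough for every planted
# effect to be measurable while each driver runs in seconds.
STUDY = SimulationConfig(
    seed=2022,
    n_known_mirnas=20,
    n_homolog_mirnas=4,
    n_novel_loci=8,
    n_decoy_loci=11,
    genome_length=60_000,
    reads_per_library=20_000,
    n_genes=120,
)
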