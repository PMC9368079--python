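import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))

from mirforge.synthetic import SimulationConfig, build_reference_catalog
from mirforge.workflow import PipelineConfig, run_pipeline


@pytest.fixture(scope="session")
def small_config():
    """Scaled-down study design used across the suite: 3 groups x 3
    replicates, 12 known miRNAs, 5 novel and 11 decoy loci."""
    return SimulationConfig(
        seed=11, n_known_mirnas=12, n_novel_loci=5, n_decoy_loci=11,
        genome_length=30_000, reads_per_library=6_000, n_genes=80,
    )


@pytest.fixture(scope="session")
def bundle(small_config):
    return build_reference_catalog(small_config)


@pytest.fixture(scope="session")
def pipeline_run(small_config, tmp_path_factory):
    cfg = PipelineConfig(simulation=small_config,
                         outdir=tmp_path_factory.mktemp("run"))
    return run_pipeline(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
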