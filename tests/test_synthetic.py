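import numpy as np
import pandas as pd
import pytest

from mirforge.hairpin import evaluate_locus
from mirforge.synthetic import (ConfigError, SimulationConfig,
                                build_reference_catalog, generate_dataset,
                                simulate_counts, synthesize_reads)


class TestConfig:
    @pytest.mark.parametrize("kwargs", [
        dict(reads_per_library=0),
        dict(read_length=40),
        dict(contamination_fraction=1.5),
        dict(de_fraction=-0.1),
        dict(nb_dispersion=-1.0),
        dict(adapter_sequence=""),
    ])
    def test_invalid_config_rejected(self, kwargs):
        with pytest.raises(ConfigError):
            SimulationConfig(**kwargs)

    def test_yaml_round_trip(self, tmp_path, small_config):
        p = tmp_path / "cfg.yaml"
        small_config.to_yaml(p)
        assert SimulationConfig.from_yaml(p) == small_config


class TestCatalog:
    def test_planted_novel_loci_pass_in_genome_context(self, bundle):
        for l in bundle.loci:
            if l.kind != "novel":
                continue
            ctx = bundle.genome[l.mature_start - 80:l.mature_end + 80]
            _, _, v = evaluate_locus(ctx, (80, 80 + l.mature_end - l.mature_start))
            assert v.overall, l.entity_id

    def test_planted_decoys_fail_exactly_their_criterion(self, bundle):
        decoys = [l for l in bundle.loci if l.kind == "decoy"]
        assert decoys
        for l in decoys:
            ctx = bundle.genome[l.mature_start - 80:l.mature_end + 80]
            _, _, v = evaluate_locus(ctx, (80, 80 + l.mature_end - l.mature_start))
            assert v.failing == [l.criterion], l.entity_id

    def test_mature_annotations_inside_precursors(self, bundle):
        for prec in bundle.known:
            for arm, (s, e) in prec.mature.items():
                assert 0 <= s < e <= len(prec.sequence)
                assert prec.sequence[s:e] in prec.sequence

    def test_homolog_precursors_present_in_genome(self, bundle):
        embedded = [p for p in bundle.other_species
                    if p.id.startswith("hsa-mir-9") and not p.id.startswith("hsa-mir-99")]
        found = [p for p in bundle.other_species if p.sequence in bundle.genome]
        assert len(found) >= 1
        absent = [p for p in bundle.other_species if p.sequence not in bundle.genome]
        assert len(absent) >= 1  # some foreign precursors must stay unlocatable

    def test_empty_known_catalog_allowed(self):
        cfg = SimulationConfig(seed=2, n_known_mirnas=0, n_novel_loci=1,
                               n_decoy_loci=1, n_homolog_mirnas=1,
                               genome_length=5_000, reads_per_library=100)
        b = build_reference_catalog(cfg)
        assert b.known == []
        assert len(b.entities) >= 2

    def test_same_seed_identical_outputs(self, tmp_path, small_config):
        cfg = SimulationConfig(seed=3, n_known_mirnas=4, n_novel_loci=2,
                               n_decoy_loci=3, genome_length=8_000,
                               reads_per_library=500, n_genes=20)
        _, _, _, paths1 = generate_dataset(cfg, tmp_path / "a")
        _, _, _, paths2 = generate_dataset(cfg, tmp_path / "b")
        for key in paths1:
            b1 = paths1[key].read_bytes()
            b2 = paths2[key].read_bytes()
            assert b1 == b2, f"{key} differs between identically-seeded runs"


class TestCounts:
    def _counts(self, **kw):
        defaults = dict(seed=9, groups=("CON", "LOS"), replicates_per_group=3,
                        reads_per_library=200_000, contamination_fraction=0.0)
        defaults.update(kw)
        cfg = SimulationConfig(**defaults)
        ents = pd.DataFrame({"entity_id": [f"m{i}" for i in range(300)]})
        return cfg, *simulate_counts(cfg, ents)

    def test_zero_dispersion_behaves_poisson(self):
        _, counts, truth = self._counts(nb_dispersion=0.0, de_fraction=0.0)
        # index of dispersion across replicates ~ 1 for Poisson
        mu = counts.mean(axis=1)
        var = counts.var(axis=1, ddof=1)
        keep = mu > 50
        ratio = (var[keep] / mu[keep]).mean()
        assert 0.7 < ratio < 1.3

    def test_planted_log2fc_recovered_at_depth(self):
        # Poisson limit: estimator error is then pure counting noise,
        # which vanishes with depth
        _, counts, truth = self._counts(planted_log2fc=2.0, de_fraction=0.2,
                                        nb_dispersion=0.0)
        con = counts[[c for c in counts if c.startswith("CON")]].mean(axis=1)
        los = counts[[c for c in counts if c.startswith("LOS")]].mean(axis=1)
        de = truth.set_index("entity_id")[truth.set_index("entity_id").de]
        strong = de[de.baseline_mean > 200]
        est = np.log2((los[strong.index] + 0.5) / (con[strong.index] + 0.5))
        err = (est - strong.log2fc).abs()
        assert (err < 0.2).mean() > 0.9

    def test_zero_de_fraction_means_no_fold_changes(self):
        _, _, truth = self._counts(de_fraction=0.0)
        assert (truth.log2fc == 0).all()
        assert not truth.de.any()

    def test_de_flags_consistent_with_planted_lfc(self):
        _, _, truth = self._counts(de_fraction=0.3)
        assert (truth.de == (truth.log2fc != 0)).all()
        assert truth.de.sum() == round(0.3 * len(truth))


class TestReads:
    def test_adapter_longer_than_read_length_rejected(self, tmp_path, bundle,
                                                      small_config):
        import dataclasses
        cfg = dataclasses.replace(small_config, read_length=36,
                                  adapter_sequence="T" * 40)
        counts, _ = simulate_counts(cfg, bundle.entities)
        with pytest.raises(ConfigError):
            synthesize_reads(cfg, bundle, counts, tmp_path)

    def test_zero_contamination_reads_all_trace_to_entities(self, tmp_path):
        cfg = SimulationConfig(seed=5, n_known_mirnas=4, n_novel_loci=1,
                               n_decoy_loci=1, genome_length=8_000,
                               reads_per_library=400, n_genes=10,
                               contamination_fraction=0.0,
                               groups=("CON",), replicates_per_group=1)
        b, counts, truth, paths = generate_dataset(cfg, tmp_path)
        fq = (tmp_path / "reads" / "CON_1.fastq").read_text().splitlines()
        labels = [line.split()[-1] for line in fq[::4]]
        assert all(l.startswith("clean:") for l in labels)

    def test_contamination_shares_respected(self, tmp_path):
        cfg = SimulationConfig(seed=6, n_known_mirnas=4, n_novel_loci=0,
                               n_decoy_loci=0, n_homolog_mirnas=0,
                               genome_length=5_000, reads_per_library=4_000,
                               n_genes=10, contamination_fraction=0.4,
                               groups=("CON",), replicates_per_group=1)
        b, counts, truth, paths = generate_dataset(cfg, tmp_path)
        fq = (tmp_path / "reads" / "CON_1.fastq").read_text().splitlines()
        labels = [line.split()[-1] for line in fq[::4]]
        n = len(labels)
        dimers = sum(l == "adapter_dimer" for l in labels)
        # 25% of the 40% contaminated share = 10% of all reads
        assert abs(dimers / n - 0.10) < 0.02
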