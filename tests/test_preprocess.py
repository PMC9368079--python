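import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from mirforge.preprocess import (FILTER_CATEGORIES, classify_insert,
                                 collapse_tags, filter_contaminants,
                                 run_preprocess, shannon_entropy,
                                 trim_adapter, is_tandem_repeat)
from oracles import best_adapter_position_oracle

ADAPTER = "TGGAATTCTCGGGTGCCAAGG"


class TestTrim:
    def test_exact_adapter_yields_insert(self):
        insert = "ACGTACGTACGTACGTACGT"  # 20 nt
        got, cat = trim_adapter(insert + ADAPTER, ADAPTER)
        assert (got, cat) == (insert, "ok")

    def test_adapter_only_read_is_dimer(self):
        got, cat = trim_adapter(ADAPTER + "AAAA", ADAPTER)
        assert got is None and cat == "adapter_dimer"

    def test_read_without_adapter_discarded(self):
        got, cat = trim_adapter("ACGT" * 10, ADAPTER)
        assert got is None and cat == "no_adapter"

    def test_empty_read_is_junk(self):
        assert trim_adapter("", ADAPTER) == (None, "junk_lowcomplexity")

    def test_one_mismatch_in_adapter_still_trimmed(self):
        mutated = "C" + ADAPTER[1:]  # 1 mismatch in 21 nt < 10% rate
        got, cat = trim_adapter("ACGTACGTACGTACGTACGTAC" + mutated, ADAPTER)
        assert cat == "ok" and got == "ACGTACGTACGTACGTACGTAC"

    def test_empty_adapter_rejected(self):
        with pytest.raises(ValueError):
            trim_adapter("ACGT", "")

    @settings(max_examples=150, deadline=None)
    @given(st.text(alphabet="ACGT", min_size=0, max_size=30),
           st.integers(0, 15))
    def test_matches_bruteforce_scan_oracle(self, insert, pad):
        read = (insert + ADAPTER + "A" * pad)[:50]
        pos = best_adapter_position_oracle(read, ADAPTER, 6, 0.1)
        got, cat = trim_adapter(read, ADAPTER, 6, 0.1)
        if pos < 0:
            assert cat == "no_adapter"
        elif pos == 0:
            assert cat == "adapter_dimer"
        else:
            assert got == read[:pos]


class TestJunk:
    def test_homopolymer_removed(self):
        assert classify_insert("A" * 20) == "junk_lowcomplexity"
        assert shannon_entropy("A" * 20) == 0.0

    def test_too_short_and_too_long_removed(self):
        assert classify_insert("ACGTACGTACGTACGTA") == "length"    # 17 nt
        assert classify_insert("ACGTACGTACGTACGTACGTACGTACG") == "length"  # 27

    def test_random_22mer_retained(self, rng):
        for _ in range(50):
            seq = "".join(rng.choice(list("ACGT"), 22))
            if max(seq.count(b) for b in "ACGT") / 22 < 0.8:
                assert classify_insert(seq) == "ok"

    def test_tandem_repeats_removed(self):
        assert is_tandem_repeat("ACACACACACACACACACAC")
        assert classify_insert("ACGACGACGACGACGACGACG") == "repeat"
        assert not is_tandem_repeat("ACGTACGTACGTACGTACGTAC")


class TestCollapse:
    def test_counts_preserved_across_libraries(self):
        from collections import Counter
        tags = collapse_tags({
            "lib1": Counter({"ACGTACGTACGTACGTAC": 3}),
            "lib2": Counter({"ACGTACGTACGTACGTAC": 5,
                             "TTTTGGGGCCCCAAAATT": 1}),
        })
        row = tags.set_index("sequence").loc["ACGTACGTACGTACGTAC"]
        assert (row["lib1"], row["lib2"], row["total"]) == (3, 5, 8)
        assert list(tags["sequence"]) == sorted(tags["sequence"])

    def test_empty_input_gives_empty_table_with_headers(self):
        tags = collapse_tags({"lib1": {}})
        assert list(tags.columns) == ["sequence", "lib1", "total"]
        assert len(tags) == 0


class TestContaminants:
    CATALOG = [("rRNA", "r1", "G" * 10 + "ACGTACGTACGTACGTACGTAC" + "G" * 10),
               ("tRNA", "t1", "ACGTACGTACGTACGTACGTAC" + "T" * 30)]

    def _tags(self, seqs):
        from collections import Counter
        return collapse_tags({"lib1": Counter(dict.fromkeys(seqs, 2))})

    def test_matching_tag_removed_with_family(self):
        tags = self._tags(["ACGTACGTACGTACGTACGTAC", "TTGCATGCATGCATGCATGC"])
        out = filter_contaminants(tags, [self.CATALOG[1]])
        assert list(out["sequence"]) == ["TTGCATGCATGCATGCATGC"]

    def test_tie_goes_to_higher_priority_family(self):
        from mirforge.preprocess import FilterReport
        tags = self._tags(["ACGTACGTACGTACGTACGTAC"])
        reports = {"lib1": FilterReport("lib1", input_reads=2, surviving=2)}
        out = filter_contaminants(tags, self.CATALOG, reports)
        assert len(out) == 0
        assert reports["lib1"].removed["rRNA"] == 2
        assert reports["lib1"].removed.get("tRNA", 0) == 0

    def test_empty_catalog_warns_and_keeps_everything(self):
        tags = self._tags(["ACGTACGTACGTACGTACGTAC"])
        with pytest.warns(UserWarning):
            out = filter_contaminants(tags, [])
        assert len(out) == 1


class TestEndToEnd:
    def test_read_conservation_and_count_preservation(self, pipeline_run):
        report = pipeline_run.report
        total_removed = report[FILTER_CATEGORIES].sum(axis=1)
        assert (report["input_reads"] == report["surviving"] + total_removed).all()
        lib_cols = [c for c in pipeline_run.tags.columns
                    if c not in ("sequence", "total")]
        assert (pipeline_run.tags[lib_cols].sum(axis=1)
                == pipeline_run.tags["total"]).all()
        per_lib = pipeline_run.tags[lib_cols].sum(axis=0)
        surviving = report.set_index("library")["surviving"]
        for lib in lib_cols:
            assert per_lib[lib] == surviving[lib]

    def test_tag_lengths_within_bounds(self, pipeline_run):
        lens = pipeline_run.tags["sequence"].str.len()
        assert lens.between(18, 26).all()

    def test_planted_dimers_removed_in_proportion(self, tmp_path):
        from mirforge.synthetic import SimulationConfig, generate_dataset
        cfg = SimulationConfig(seed=6, n_known_mirnas=4, n_novel_loci=0,
                               n_decoy_loci=0, n_homolog_mirnas=0,
                               genome_length=5_000, reads_per_library=4_000,
                               n_genes=10, contamination_fraction=0.4,
                               groups=("CON",), replicates_per_group=1)
        bundle, counts, truth, _ = generate_dataset(cfg, tmp_path)
        tags, report = run_preprocess(
            {"CON_1": tmp_path / "reads" / "CON_1.fastq"},
            cfg.adapter_sequence, bundle.contaminants)
        frac = report["adapter_dimer"][0] / report["input_reads"][0]
        assert abs(frac - 0.10) < 0.02  # 25% of the 40% contaminated share
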