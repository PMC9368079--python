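import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from mirforge.annotate import (MappingResult, NameParseError, PrecursorRecord,
                               format_mirna_name, locate_genomic_candidates,
                               map_homologs, map_to_precursors,
                               parse_mirna_name, revcomp)

# a designed precursor: 5' arm, loop, 3' arm; mature = positions 4..26
ARM5 = "GCGTACGATCGGCATTGCAGCTAGGT"
PREC_SEQ = "ACGA" + ARM5 + "TTTCGTTT" + revcomp(ARM5) + "TGCA"
MATURE = (4, 4 + len(ARM5))
PREC = PrecursorRecord("ssc-mir-1", "ssc", PREC_SEQ, {"5p": MATURE},
                       {"5p": "ssc-miR-1-5p"})


def _mature():
    return PREC_SEQ[MATURE[0]:MATURE[1]]


class TestPrecursorMapping:
    def test_exact_mature_maps_with_zero_offsets(self):
        res = map_to_precursors([_mature()], [PREC])[0]
        assert res.category == "known_species"
        assert (res.left_offset, res.right_offset) == (0, 0)
        assert res.mismatch is None
        assert res.name == "ssc-miR-1-5p"

    def test_three_prime_extension_named_R_plus_1(self):
        tag = PREC_SEQ[MATURE[0]:MATURE[1] + 1]
        res = map_to_precursors([tag], [PREC])[0]
        assert (res.left_offset, res.right_offset) == (0, 1)
        assert res.name == "ssc-miR-1-5p_R+1"

    def test_five_prime_ext_and_three_prime_trim(self):
        tag = PREC_SEQ[MATURE[0] - 2:MATURE[1] - 1]
        res = map_to_precursors([tag], [PREC])[0]
        assert (res.left_offset, res.right_offset) == (2, -1)
        assert res.name == "ssc-miR-1-5p_L+2R-1"

    def test_single_substitution_annotated_1ss(self):
        m = _mature()
        pos = 9  # 0-based
        alt = {"A": "G", "G": "A", "C": "T", "T": "C"}[m[pos]]
        tag = m[:pos] + alt + m[pos + 1:]
        res = map_to_precursors([tag], [PREC])[0]
        assert res.mismatch == (10, m[pos], alt)
        assert res.name.endswith(f"_1ss10{m[pos]}{alt}")

    def test_two_substitutions_not_a_hit(self):
        m = _mature()
        tag = "TT" + m[2:]
        assert m[:2] != "TT"
        res = map_to_precursors([tag], [PREC])[0]
        assert res.category == "unassigned"

    def test_offset_beyond_window_not_a_hit(self):
        tag = PREC_SEQ[MATURE[0] - 3:MATURE[1]]
        res = map_to_precursors([tag], [PREC], window=2)[0]
        assert res.category == "unassigned"

    def test_cascade_is_a_partition(self, bundle, pipeline_run):
        cats = pipeline_run.mapping["category"]
        assert set(cats) <= {"known_species", "known_homolog",
                             "novel_candidate", "unassigned"}
        assert len(pipeline_run.mapping) == len(pipeline_run.tags)


class TestHomologs:
    def test_homolog_requires_precursor_in_genome(self):
        genome = "T" * 50 + PREC_SEQ + "G" * 50
        other = [PrecursorRecord("hsa-mir-9", "hsa", PREC_SEQ, {"5p": MATURE},
                                 {"5p": "hsa-miR-9-5p"})]
        res = [MappingResult(_mature(), "unassigned")]
        out = map_homologs(res, other, genome)[0]
        assert out.category == "known_homolog"
        assert out.interval == (50, 50 + len(PREC_SEQ))

    def test_precursor_absent_from_genome_stays_unassigned(self):
        other = [PrecursorRecord("hsa-mir-9", "hsa", PREC_SEQ, {"5p": MATURE},
                                 {"5p": "hsa-miR-9-5p"})]
        res = [MappingResult(_mature(), "unassigned")]
        out = map_homologs(res, other, "A" * 200)[0]
        assert out.category == "unassigned"

    def test_no_catalog_passes_through(self):
        res = [MappingResult(_mature(), "unassigned")]
        assert map_homologs(res, [], "ACGT")[0].category == "unassigned"


class TestGenomicCandidates:
    TAG = "GCATTGCAGCTAGGTCATCGAA"

    def test_forward_placement_recovered(self):
        genome = "C" * 100 + self.TAG + "C" * 100
        res, loci = locate_genomic_candidates(
            [MappingResult(self.TAG, "unassigned")], genome)
        assert res[0].category == "novel_candidate"
        assert loci[0].start == 100 and loci[0].strand == "+"
        assert loci[0].context == genome[20:100 + len(self.TAG) + 80]

    def test_reverse_strand_context_is_reverse_complemented(self):
        genome = "C" * 100 + revcomp(self.TAG) + "C" * 100
        res, loci = locate_genomic_candidates(
            [MappingResult(self.TAG, "unassigned")], genome)
        assert loci[0].strand == "-"
        ms, me = loci[0].mature_in_context
        assert loci[0].context[ms:me] == self.TAG

    def test_absent_tag_has_no_locus(self):
        res, loci = locate_genomic_candidates(
            [MappingResult(self.TAG, "unassigned")], "A" * 500)
        assert res[0].category == "unassigned" and loci == []

    def test_repetitive_tag_discarded(self):
        genome = ("T" * 30 + self.TAG) * 12
        res, loci = locate_genomic_candidates(
            [MappingResult(self.TAG, "unassigned")], genome, max_loci=10)
        assert res[0].category == "unassigned"
        assert loci == []


class TestNameGrammar:
    @pytest.mark.parametrize("base,lo,ro,mm,expected", [
        ("hsa-miR-141-3p", 0, 1, None, "hsa-miR-141-3p_R+1"),
        ("hsa-miR-222-5p", 2, -1, None, "hsa-miR-222-5p_L+2R-1"),
        ("ssc-miR-194b-5p", 0, 0, (10, "G", "A"), "ssc-miR-194b-5p_1ss10GA"),
        ("ssc-miR-1839-3p", 0, 2, None, "ssc-miR-1839-3p_R+2"),
        ("ssc-miR-190b", 0, 0, None, "ssc-miR-190b"),
    ])
    def test_published_style_names_format(self, base, lo, ro, mm, expected):
        assert format_mirna_name(base, lo, ro, mm) == expected

    def test_candidate_name_parses(self):
        parsed = parse_mirna_name("PC-5p-9551_196")
        assert parsed == {"kind": "candidate", "arm": "5p", "serial": 9551,
                          "total": 196}

    def test_malformed_name_raises(self):
        with pytest.raises(NameParseError):
            parse_mirna_name("")

    @settings(max_examples=500, deadline=None)
    @given(
        base=st.sampled_from(["ssc-miR-7134-3p", "hsa-miR-141-3p",
                              "ssc-miR-190b", "sha-mir-24-1-p3",
                              "ssc-miR-9840-5p"]),
        lo=st.integers(-4, 4), ro=st.integers(-4, 4),
        mm=st.one_of(st.none(), st.tuples(st.integers(1, 26),
                                          st.sampled_from("ACGT"),
                                          st.sampled_from("ACGT"))),
    )
    def test_round_trip_identity(self, base, lo, ro, mm):
        name = format_mirna_name(base, lo, ro, mm)
        parsed = parse_mirna_name(name)
        assert parsed["base"] == base
        assert parsed["left_offset"] == lo
        assert parsed["right_offset"] == ro
        assert parsed["mismatch"] == mm

    def test_emitted_pipeline_names_all_parse(self, pipeline_run):
        named = pipeline_run.mapping.loc[
            pipeline_run.mapping["name"] != "", "name"]
        assert len(named) > 100
        for name in named:
            parse_mirna_name(name)  # raises on failure
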