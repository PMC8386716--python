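"""Genetic codes, strand orientation and CDS start/stop analysis."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import mitotbl as m
from mitotbl.assembly_io import GeneInterval

DNA = st.text(alphabet="ACGT", min_size=1, max_size=120)


class TestGeneticCodes:
    def test_vertebrate_mito_stops_include_aga_agg(self, code2):
        # independently known: table 2 reassigns AGA/AGG from Arg to stop
        assert {"AGA", "AGG", "TAA", "TAG"} == set(code2.stop_codons)

    def test_invertebrate_mito_tga_is_trp(self, code5):
        assert code5.translate_codon("TGA") == "W"
        assert "TGA" not in code5.stop_codons

    def test_unsupported_table_rejected(self):
        with pytest.raises(m.CodonError, match="999"):
            m.load_code(999)

    @pytest.mark.parametrize("table_id", [2, 4, 5, 9, 13, 14])
    def test_table_partitions_64_codons(self, table_id):
        code = m.load_code(table_id)
        assert len(code.codon_to_aa) == 64
        coding = {c for c, aa in code.codon_to_aa.items() if aa != "*"}
        assert len(code.stop_codons) + len(coding) == 64
        assert set(code.stop_codons) == {c for c, aa in code.codon_to_aa.items() if aa == "*"}
        assert code.start_codons


class TestOrient:
    def test_forward_is_identity(self):
        assert m.orient("ATGAAATAA", GeneInterval(1, 9), True) == "ATGAAATAA"

    def test_reverse_complement_by_hand(self):
        assert m.orient("TTATTTCAT", GeneInterval(1, 9), False) == "ATGAAATAA"

    @settings(derandomize=True, max_examples=50)
    @given(seq=DNA)
    def test_reverse_matches_double_reversal_oracle(self, seq):
        interval = GeneInterval(1, len(seq))
        # oracle: complement base-by-base, then reverse — written independently
        comp = {"A": "T", "T": "A", "G": "C", "C": "G"}
        oracle = "".join(comp[b] for b in seq)[::-1]
        assert m.orient(seq, interval, False) == oracle
        # double application of reverse orientation restores the substring
        assert m.reverse_complement(m.orient(seq, interval, False)) == seq


class TestAnalyzeCds:
    @pytest.mark.parametrize(
        "seq, start, stop",
        [
            ("ATGAAATAA", "canonical", "full_stop"),
            ("ATGAAAT", "canonical", "truncated_T"),
            ("ATGAAATA", "canonical", "truncated_TA"),
            ("ATGAAACCC", "canonical", "invalid"),
            ("ATGAAAC", "canonical", "invalid"),  # remainder 1, not T
            ("ATGAAACG", "canonical", "invalid"),  # remainder 2, not TA
            ("CCTAAATAA", "non_canonical", "full_stop"),
            ("GTGAAATAA", "canonical", "full_stop"),  # GTG canonical under table 5
        ],
    )
    def test_start_stop_classification(self, seq, start, stop, code5):
        report = m.analyze_cds(seq, code5)
        assert (report.start_status, report.stop_status) == (start, stop)
        assert report.remainder == len(seq) % 3

    def test_table_dependent_stop(self, code2, code5):
        # AGA: stop under vertebrate mito, Ser (coding) under invertebrate mito
        assert m.analyze_cds("ATGAAAAGA", code2).stop_status == "full_stop"
        assert m.analyze_cds("ATGAAAAGA", code5).stop_status == "invalid"

    def test_ambiguous_bases_never_guessed(self, code5):
        assert m.analyze_cds("ATGAAANNN", code5).stop_status == "invalid"
        assert m.analyze_cds("NTGAAATAA", code5).start_status == "non_canonical"

    def test_short_sequence_rejected(self, code5):
        with pytest.raises(m.CodonError, match="too short"):
            m.analyze_cds("ATGAA", code5)

    @settings(derandomize=True, max_examples=80)
    @given(seq=st.text(alphabet="ACGT", min_size=6, max_size=60))
    def test_classification_exhaustive_and_exclusive(self, seq, code5):
        report = m.analyze_cds(seq, code5)
        assert report.stop_status in {"full_stop", "truncated_T", "truncated_TA", "invalid"}
        if report.stop_status == "truncated_T":
            assert report.remainder == 1 and seq[-1] == "T"
        elif report.stop_status == "truncated_TA":
            assert report.remainder == 2 and seq[-2:] == "TA"
        elif report.stop_status == "full_stop":
            assert report.remainder == 0 and seq[-3:] in code5.stop_codons
        else:  # invalid: anything else, whatever the remainder
            assert not (report.remainder == 1 and seq[-1] == "T")
            assert not (report.remainder == 2 and seq[-2:] == "TA")
            assert not (report.remainder == 0 and seq[-3:] in code5.stop_codons)


class TestTranslExcept:
    def test_truncated_t_forward_verbatim_strings(self, code5):
        # forward CDS occupying 11650..11922, ending on a bare T
        report = m.analyze_cds("ATG" + "AAA" * 89 + "GGGT", code5)
        assert report.stop_status == "truncated_T"
        quals = m.transl_except_qualifiers(report, GeneInterval(11650, 11922), True)
        assert ("transl_except", "(pos:11922,aa:TERM)") in quals
        assert (
            "note",
            "TAA stop codon is completed by the addition of 3' A residues to the mRNA",
        ) in quals

    def test_truncated_ta_forward_range(self, code5):
        report = m.analyze_cds("ATGAAATA", code5)
        quals = m.transl_except_qualifiers(report, GeneInterval(11, 18), True)
        assert ("transl_except", "(pos:17..18,aa:TERM)") in quals

    def test_truncated_t_reverse_maps_to_interval_low_end(self, code5):
        # oracle: enumerate genomic positions of the reverse-complemented
        # slice in coding order; the terminal coding base is the last one
        interval = GeneInterval(100, 200)
        coding_positions = list(range(interval.end, interval.start - 1, -1))
        assert coding_positions[-1] == 100
        report = m.analyze_cds("ATG" + "AAA" * 32 + "GGGT", code5)
        quals = m.transl_except_qualifiers(report, interval, False)
        assert ("transl_except", "(pos:100,aa:TERM)") in quals

    def test_truncated_ta_reverse_coding_order(self, code5):
        report = m.analyze_cds("ATGAAATA", code5)
        quals = m.transl_except_qualifiers(report, GeneInterval(100, 107), False)
        assert ("transl_except", "(pos:101..100,aa:TERM)") in quals

    def test_non_canonical_start_spans_first_codon(self, code5):
        report = m.analyze_cds("CCTAAATAA", code5)
        fwd = m.transl_except_qualifiers(report, GeneInterval(10, 18), True)
        assert ("transl_except", "(pos:10..12,aa:Met)") in fwd
        assert any(n == "note" and "CCT" in v for n, v in fwd)
        rev = m.transl_except_qualifiers(report, GeneInterval(10, 18), False)
        assert ("transl_except", "(pos:18..16,aa:Met)") in rev

    def test_start_annotation_can_be_disabled(self, code5):
        report = m.analyze_cds("CCTAAATAA", code5)
        assert m.transl_except_qualifiers(report, GeneInterval(1, 9), True,
                                          annotate_start=False) == []

    def test_clean_cds_yields_no_qualifiers(self, code5):
        report = m.analyze_cds("ATGAAATAA", code5)
        assert m.transl_except_qualifiers(report, GeneInterval(1, 9), True) == []

    def test_excepts_precede_notes(self, code5):
        report = m.analyze_cds("CCTAAAT", code5)  # bad start AND truncated T
        quals = m.transl_except_qualifiers(report, GeneInterval(1, 7), True)
        names = [n for n, _ in quals]
        assert names == ["transl_except", "transl_except", "note", "note"]
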