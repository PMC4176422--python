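"""Recognizer families: documented hits and misses, parses, span invariants."""
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from varlit.errors import ConfigError, NormalizationError
from varlit.extractors import (
    RecognizerConfig,
    classify_variant_type,
    extract_all,
    extract_dna_extended,
    extract_hgvs,
    extract_protein_point,
    extract_rsid,
)
from varlit.types import Family, Level, VariantType

FAITHFUL = RecognizerConfig.faithful()
EXTENDED = RecognizerConfig.extended()


class TestProteinPoint:
    def test_parenthesized_substitution_found(self):
        ms = extract_protein_point("a protein substitution (V600E)", FAITHFUL)
        assert [m.span.surface for m in ms] == ["V600E"]
        m = ms[0]
        assert (m.wild, m.position, m.mutated) == ("V", 600, "E")
        assert m.level is Level.PROTEIN

    def test_empty_text(self):
        assert extract_protein_point("", FAITHFUL) == []

    def test_three_letter_and_bare_one_letter(self):
        text = "p.Pro622Thr and M23A were found"
        surfaces = [m.span.surface for m in extract_protein_point(text, FAITHFUL)]
        assert surfaces == ["p.Pro622Thr", "M23A"]

    def test_span_covers_prefix(self):
        text = "mutation p.Lys618Ala observed"
        (m,) = extract_protein_point(text, FAITHFUL)
        assert m.span.surface == "p.Lys618Ala"
        assert text[m.span.start : m.span.end] == "p.Lys618Ala"

    def test_residue_position_without_target_suppressed(self):
        text = "expression A1796 resembles a variant"
        assert extract_protein_point(text, FAITHFUL) == []
        # with the requirement lifted the token fires
        relaxed = RecognizerConfig(require_mutated_residue=False)
        assert [m.span.surface for m in extract_protein_point(text, relaxed)] == ["A1796"]

    def test_stop_written_as_x(self):
        (m,) = extract_protein_point("carrying p.Arg226X allele", FAITHFUL)
        assert (m.wild, m.position, m.mutated) == ("Arg", 226, "X")

    def test_parenthesized_suppressed_when_toggled_off(self):
        cfg = RecognizerConfig(allow_parenthesized=False)
        assert extract_protein_point("substitution (V600E) here", cfg) == []


class TestHgvsStrict:
    @pytest.mark.parametrize(
        "text, surface, op, level",
        [
            ("a DNA deletion (c.2700_2701delTC)", "c.2700_2701delTC", "del", Level.DNA),
            ("c.4236del8ins13 was seen", "c.4236del8ins13", "delins", Level.DNA),
            ("c.1668C>T in exon 16", "c.1668C>T", "sub", Level.DNA),
            ("variant c.1704_1705delAG found", "c.1704_1705delAG", "del", Level.DNA),
            (
                "complex c.423-6delAAATAGGTinsGAAGCAAGATCAG here",
                "c.423-6delAAATAGGTinsGAAGCAAGATCAG",
                "delins",
                Level.DNA,
            ),
        ],
    )
    def test_dna_forms(self, text, surface, op, level):
        hits = [m for m in extract_hgvs(text, FAITHFUL) if m.span.surface == surface]
        assert len(hits) == 1
        assert hits[0].op_kind_raw == op
        assert hits[0].level is level

    def test_nonstandard_deletion_outside_grammar(self):
        assert extract_hgvs("del exon 3 was observed", FAITHFUL) == []

    @pytest.mark.parametrize(
        "missed",
        ["codon 41: A←G", "codon 33: C>A", "del exon 3", "G:C to A:T transition", "exon 10"],
    )
    def test_universally_missed_forms_never_fire(self, missed):
        assert extract_hgvs(f"we note {missed} in text", FAITHFUL) == []

    def test_underspecified_forms_accepted_unresolved(self):
        ms = extract_hgvs("reported as c.? and also p.?", FAITHFUL)
        assert [m.span.surface for m in ms] == ["c.?", "p.?"]
        assert all(m.op_kind_raw == "unknown" and m.position == "?" for m in ms)


class TestDnaExtended:
    def test_range_substitution(self):
        (m,) = extract_dna_extended("substitutions such as c.1852_1853AA>GC", FAITHFUL)
        assert m.span.surface == "c.1852_1853AA>GC"
        assert (m.wild, m.position, m.mutated) == ("AA", (1852, 1853), "GC")

    def test_whitespace_corrupted_sub_needs_tolerance(self):
        text = "the variant C1668 C > T was reported"
        assert extract_dna_extended(text, FAITHFUL) == []
        (m,) = extract_dna_extended(text, EXTENDED)
        assert (m.position, m.wild, m.mutated) == (1668, "C", "T")

    def test_deletion_with_internal_space_needs_tolerance(self):
        text = "deletion c.3927_3931del AAAGA segregated"
        assert extract_dna_extended(text, FAITHFUL) == []
        (m,) = extract_dna_extended(text, EXTENDED)
        assert m.span.surface == "c.3927_3931del AAAGA"

    def test_verbose_form_is_a_known_gap(self):
        assert extract_dna_extended("carrying 1799T to A mutation", FAITHFUL) == []
        assert extract_dna_extended("codon 41: A←G", EXTENDED) == []

    def test_bare_position_deletion_substring(self):
        (m,) = extract_dna_extended("deletion 1705delAG reported", FAITHFUL)
        assert m.span.surface == "1705delAG"


class TestRsid:
    def test_basic_accession(self):
        (m,) = extract_rsid("rs123456 was genotyped")
        assert m.span.surface == "rs123456"
        assert m.family is Family.RSID

    @pytest.mark.parametrize("text", ["rs alone", "Mrs1234 spoke", "RS123", "rs123x"])
    def test_token_boundaries_and_case(self, text):
        assert extract_rsid(text) == []


class TestFamilyInvariants:
    @pytest.mark.parametrize("cfg", [FAITHFUL, EXTENDED], ids=["faithful", "extended"])
    def test_catalog_surfaces_spans_and_order(self, catalog, cfg):
        """Spans equal text slices, no within-family overlap, sorted output."""
        text = "Start. " + " and then ".join(e.surface for e in catalog) + " end."
        for fam, mentions in extract_all(text, cfg).items():
            for m in mentions:
                assert m.span.surface == text[m.span.start : m.span.end]
            for a, b in zip(mentions, mentions[1:]):
                assert a.span.end <= b.span.start, f"{fam}: overlapping mentions"
            assert mentions == sorted(mentions, key=lambda m: (m.span.start, m.span.end))

    def test_determinism(self, catalog):
        text = " ".join(e.surface for e in catalog)
        assert extract_all(text, FAITHFUL) == extract_all(text, FAITHFUL)

    def test_longest_match_wins_within_family(self):
        # the bare deletion is a substring of the full range deletion
        (m,) = extract_dna_extended("found c.1704-1705delAG here", FAITHFUL)
        assert m.span.surface == "c.1704-1705delAG"

    def test_config_requires_a_family(self):
        with pytest.raises(ConfigError):
            RecognizerConfig(families=frozenset())

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(
        st.lists(
            st.sampled_from(
                ["c.1668C>T", "V600E", "rs4242", "p.Lys618Ala", "words", "A1796", "exon 10"]
            ),
            min_size=0,
            max_size=6,
        )
    )
    def test_span_slice_property_on_generated_text(self, tokens):
        text = " , ".join(tokens)
        if not text:
            return
        for mentions in extract_all(text, FAITHFUL).values():
            for m in mentions:
                assert m.span.surface == text[m.span.start : m.span.end]


class TestVariantTyping:
    @pytest.mark.parametrize(
        "key, vtype",
        [
            ("c.1704_1705delAG", VariantType.DELETION),
            ("c.?", VariantType.UNKNOWN),
            ("p.?", VariantType.UNKNOWN),
            ("p.H776_C777>QS", VariantType.UNKNOWN),
            ("L280FfsX4", VariantType.UNKNOWN),
            ("A140T", VariantType.SUBSTITUTION),
            ("R226X", VariantType.SUBSTITUTION),
            ("c.1668C>T", VariantType.SUBSTITUTION),
            ("c.1852_1853AA>GC", VariantType.SUBSTITUTION),
            ("c.4236del8ins13", VariantType.DELETION_INSERTION),
            ("c.100_102insAT", VariantType.INSERTION),
            ("c.100_103dup", VariantType.DUPLICATION),
            ("p.Leu280Phefs*4", VariantType.FRAMESHIFT),
            ("del exon 3", VariantType.UNKNOWN),
            ("IVS17(+5)G>C", VariantType.UNKNOWN),
        ],
    )
    def test_typing(self, key, vtype):
        assert classify_variant_type(key) is vtype

    def test_empty_input_is_a_usage_error(self):
        with pytest.raises(NormalizationError):
            classify_variant_type("")
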