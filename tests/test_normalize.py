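"""Normalization to canonical keys: worked examples and invariants."""
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from varlit.errors import NormalizationError
from varlit.extractors import classify_variant_type, RecognizerConfig, extract_all
from varlit.normalize import (
    AMINO_ACIDS_3TO1,
    canonicalize_range,
    codon_candidate_keys,
    codon_to_nucleotide_positions,
    expand_rsid,
    filter_unlocatable,
    normalize_dna_sub,
    normalize_mention,
    normalize_protein_sub,
    single_letter,
)
from varlit.types import Family, Level, MentionSpan, VariantMention, VariantType


def _mention(surface, family=Family.HGVS_STRICT, level=Level.DNA, **kw):
    span = MentionSpan(doc_id="d", start=0, end=len(surface), surface=surface)
    return VariantMention(span=span, family=family, level=level, **kw)


class TestAminoAcidTable:
    def test_bijective_and_total(self):
        assert len(AMINO_ACIDS_3TO1) == 20
        assert len(set(AMINO_ACIDS_3TO1.values())) == 20

    @pytest.mark.parametrize("tok, expected", [("Ala", "A"), ("a", "A"), ("Ter", "X"), ("*", "X"), ("X", "X")])
    def test_single_letter(self, tok, expected):
        assert single_letter(tok) == expected

    def test_unknown_residue_names_token(self):
        with pytest.raises(NormalizationError, match="Xyz"):
            single_letter("Xyz")


class TestProteinSub:
    @pytest.mark.parametrize(
        "wild, pos, mut, key",
        [("Ala", 140, "Thr", "A140T"), ("V", 600, "E", "V600E"), ("Arg", 226, "X", "R226X")],
    )
    def test_examples(self, wild, pos, mut, key):
        nv = normalize_protein_sub(wild, pos, mut)
        assert nv.key == key
        assert nv.level is Level.PROTEIN
        assert nv.variant_type is VariantType.SUBSTITUTION


class TestDnaSub:
    @pytest.mark.parametrize(
        "pos, w, m, key",
        [(1668, "C", "T", "c.1668C>T"), (1, "a", "g", "c.1A>G"), (1799, "T", "A", "c.1799T>A")],
    )
    def test_examples(self, pos, w, m, key):
        assert normalize_dna_sub(pos, w, m).key == key

    def test_non_acgt_base_rejected(self):
        with pytest.raises(NormalizationError):
            normalize_dna_sub(10, "C", "U")


class TestCanonicalizeRange:
    def test_hyphen_range_becomes_underscore(self):
        assert canonicalize_range("c.597-598delGA") == "c.597_598delGA"

    def test_already_canonical_is_fixed_point(self):
        assert canonicalize_range("c.1704_1705delAG") == "c.1704_1705delAG"

    def test_intron_offset_hyphen_preserved(self):
        # a decreasing pair is an offset, not a range: brute-force check that a
        # range reading would be decreasing
        key = "c.423-6delAAATAGGTinsGAAGCAAGATCAG"
        a, b = 423, 6
        assert not a < b  # the range reading is rejected
        assert canonicalize_range(key) == key

    def test_internal_whitespace_removed(self):
        assert canonicalize_range("c. 597 -598delGA") == "c.597_598delGA"

    def test_unparseable_input_errors(self):
        with pytest.raises(NormalizationError):
            canonicalize_range("del exon 3")

    @settings(max_examples=80, deadline=None, derandomize=True)
    @given(
        a=st.integers(1, 5000),
        span=st.integers(-10, 10),
        op=st.sampled_from(["delGA", "del", "insAT", "dup"]),
        sep=st.sampled_from(["-", "_"]),
    )
    def test_idempotence(self, a, span, op, sep):
        b = a + span
        if b < 1 or b == a:
            return
        raw = f"c.{a}{sep}{b}{op}"
        try:
            once = canonicalize_range(raw)
        except NormalizationError:
            return
        assert canonicalize_range(once) == once
        assert " " not in once
        # a canonical key never contains a range hyphen (increasing pair)
        if a < b:
            assert "-" not in once

    def test_every_canonical_key_is_typeable(self, catalog):
        for e in catalog:
            if e.key:
                assert classify_variant_type(e.key) is not None


class TestCodonConversion:
    def test_first_codon(self):
        assert codon_to_nucleotide_positions(1) == frozenset({1, 2, 3})

    def test_codon_41_against_enumeration_oracle(self):
        # oracle: lay a coding sequence out codon by codon and read positions off
        positions_by_codon = {}
        pos = 1
        for codon in range(1, 50):
            positions_by_codon[codon] = {pos, pos + 1, pos + 2}
            pos += 3
        assert codon_to_nucleotide_positions(41) == frozenset(positions_by_codon[41])
        assert codon_to_nucleotide_positions(41) == frozenset({121, 122, 123})

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.integers(1, 10**6))
    def test_always_three_candidates(self, k):
        assert len(codon_to_nucleotide_positions(k)) == 3

    def test_non_positive_rejected(self):
        with pytest.raises(NormalizationError):
            codon_to_nucleotide_positions(0)

    def test_candidate_keys(self):
        keys = codon_candidate_keys(41, "A", "G")
        assert keys == frozenset({"c.121A>G", "c.122A>G", "c.123A>G"})


class TestFilterUnlocatable:
    def test_exon_mention_removed(self):
        kept = filter_unlocatable(
            [_mention("c.1668C>T", op_kind_raw="sub", wild="C", mutated="T", position=1668),
             _mention("exon 10", family=Family.DNA_EXTENDED)]
        )
        assert [m.span.surface for m in kept] == ["c.1668C>T"]

    def test_empty(self):
        assert filter_unlocatable([]) == []

    def test_ivs_mention_keeps_no_key(self):
        (nv,) = normalize_mention(_mention("IVS17(+5)G>C", family=Family.DNA_EXTENDED))
        assert nv.key is None
        assert nv.variant_type is VariantType.UNKNOWN


class TestExpandRsid:
    LOOKUP = {"rs123": [("DNA", "c.1668C>T"), ("PROTEIN", "R226X")]}

    def test_passthrough(self):
        keys = [nv.key for nv in expand_rsid("rs123", self.LOOKUP)]
        assert keys == ["c.1668C>T", "R226X"]

    def test_absent_id_yields_empty(self):
        assert expand_rsid("rs999", {}) == []

    def test_malformed_id_rejected(self):
        with pytest.raises(NormalizationError):
            expand_rsid("xs123", self.LOOKUP)


class TestNormalizeMentionRoundTrip:
    def test_keys_reaccepted_by_typing(self, catalog):
        """Every emitted canonical key is inside the variant grammar."""
        cfg = RecognizerConfig.extended()
        for e in catalog:
            if e.key is None:
                continue
            for fam, mentions in extract_all(f"x {e.surface} y", cfg).items():
                for m in mentions:
                    lookup = {m.span.surface: [("DNA", e.key)]} if fam is Family.RSID else None
                    for nv in normalize_mention(m, rsid_lookup=lookup):
                        if nv.key:
                            assert classify_variant_type(nv.key) is not VariantType.UNKNOWN or nv.key in ("c.?", "p.?")

    def test_genome_level_never_emitted(self, small_corpus):
        cfg = RecognizerConfig.extended()
        for doc in small_corpus.documents[:20]:
            for mentions in extract_all(doc.text, cfg).values():
                for m in mentions:
                    for nv in normalize_mention(m, rsid_lookup=small_corpus.rsid_lookup):
                        assert nv.level in (Level.DNA, Level.PROTEIN)
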