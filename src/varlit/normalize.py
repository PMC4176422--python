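"""Normalization of raw variant mentions to canonical HGVS-like keys.

Canonical forms, chosen to be directly comparable with curated-database
entries:

* protein substitutions: single-letter wild type + position + single-letter
  mutated residue, e.g. ``A140T``; stop/"any" is written ``X`` (``R226X``).
* DNA substitutions: ``c.<position><wild>><mutated>``, e.g. ``c.1668C>T``.
* ranges: the two coordinates joined by an underscore (``c.597_598delGA``);
  a hyphen between a coordinate and a small trailing number is an intron
  offset and is preserved (``c.423-6del...``).

Mentions whose only locational information is an exon/intron number, and
legacy intron notations (``IVS17(+5)G>C``), yield no key: no coding position
can be derived for them without transcript structure.
"""
from __future__ import annotations

import logging
import re
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

from .errors import NormalizationError
from .extractors import AA1_CODES, AA3_CODES, classify_variant_type
from .types import Family, Level, NormalizedVariant, VariantMention, VariantType

logger = logging.getLogger(__name__)

# Three-letter -> one-letter table for the 20 standard residues; the stop /
# unspecified residue is rendered X in database style, accepting Ter and *
# spellings on input.
AMINO_ACIDS_3TO1: Dict[str, str] = {
    "Ala": "A", "Arg": "R", "Asn": "N", "Asp": "D", "Cys": "C",
    "Gln": "Q", "Glu": "E", "Gly": "G", "His": "H", "Ile": "I",
    "Leu": "L", "Lys": "K", "Met": "M", "Phe": "F", "Pro": "P",
    "Ser": "S", "Thr": "T", "Trp": "W", "Tyr": "Y", "Val": "V",
}
assert set(AMINO_ACIDS_3TO1) == set(AA3_CODES)
assert set(AMINO_ACIDS_3TO1.values()) == set(AA1_CODES)
_STOP_TOKENS = {"X", "Ter", "TER", "*"}


def single_letter(residue: str) -> str:
    """Map a one- or three-letter residue token to its single-letter form."""
    if not residue:
        raise NormalizationError("empty residue token")
    if residue in _STOP_TOKENS:
        return "X"
    if len(residue) == 1 and residue.upper() in AA1_CODES:
        return residue.upper()
    title = residue[:1].upper() + residue[1:].lower()
    if title in AMINO_ACIDS_3TO1:
        return AMINO_ACIDS_3TO1[title]
    raise NormalizationError(f"unknown residue token: {residue!r}")


def normalize_protein_sub(wild: str, position: int, mutated: str) -> NormalizedVariant:
    """``(Ala, 140, Thr)`` -> key ``A140T``."""
    if position < 1:
        raise NormalizationError(f"protein position must be >= 1, got {position}")
    key = f"{single_letter(wild)}{position}{single_letter(mutated)}"
    return NormalizedVariant(
        level=Level.PROTEIN, key=key, variant_type=VariantType.SUBSTITUTION
    )


def normalize_dna_sub(position: int, wild_base: str, mutated_base: str) -> NormalizedVariant:
    """``(1668, C, T)`` -> key ``c.1668C>T``."""
    if position < 1:
        raise NormalizationError(f"DNA position must be >= 1, got {position}")
    w, m = wild_base.upper(), mutated_base.upper()
    for base in (w, m):
        if base not in {"A", "C", "G", "T"}:
            raise NormalizationError(f"not a DNA base: {base!r}")
    return NormalizedVariant(
        level=Level.DNA,
        key=f"c.{position}{w}>{m}",
        variant_type=VariantType.SUBSTITUTION,
    )


_HYPHEN_PAIR = re.compile(r"(?<![0-9+\-_])(\d+)-(\d+)")


def canonicalize_range(raw_key: str, strict: bool = True) -> str:
    """Canonicalize a mention/key string: strip whitespace, underscore ranges.

    A hyphen joining two coordinates is a range separator only when the pair is
    increasing (``c.597-598delGA`` -> ``c.597_598delGA``); a decreasing pair is
    an intron offset and the hyphen is preserved (``c.423-6del...ins...``).
    Idempotent. With ``strict`` (default) a string outside the recognized key
    grammar raises :class:`NormalizationError`.
    """
    if not raw_key or not raw_key.strip():
        raise NormalizationError("empty key")
    s = re.sub(r"\s+", "", raw_key)

    def _swap(m: re.Match) -> str:
        a, b = int(m.group(1)), int(m.group(2))
        return f"{a}_{b}" if a < b else m.group(0)

    s = _HYPHEN_PAIR.sub(_swap, s)
    if strict and classify_variant_type(s) is VariantType.UNKNOWN and s not in {"c.?", "p.?"}:
        raise NormalizationError(f"key outside the variant grammar: {raw_key!r}")
    return s


def codon_to_nucleotide_positions(codon_index: int) -> frozenset:
    """Codon k covers nucleotide positions {3k-2, 3k-1, 3k}."""
    if codon_index < 1:
        raise NormalizationError(f"codon index must be >= 1, got {codon_index}")
    return frozenset({3 * codon_index - 2, 3 * codon_index - 1, 3 * codon_index})


_EXON_INTRON = re.compile(r"(?i)^(?:del\s+)?(?:exon|intron)s?\s*\d+$")
_IVS = re.compile(r"(?i)^IVS\d+")


def _unlocatable(surface: str) -> bool:
    return bool(_EXON_INTRON.match(surface.strip()))


def filter_unlocatable(mentions: Sequence[VariantMention]) -> List[VariantMention]:
    """Drop mentions whose only position information is an exon/intron number."""
    return [m for m in mentions if not _unlocatable(m.span.surface)]


_RSID_PAT = re.compile(r"^rs\d+$")


def expand_rsid(
    rsid: str, lookup: Mapping[str, Sequence[Tuple[str, str]]]
) -> List[NormalizedVariant]:
    """Expand a dbSNP accession to its candidate DNA/protein keys.

    ``lookup`` is an offline table {rsid: [(level, key), ...]} injected by the
    caller; an absent accession yields an empty list with a logged warning.
    """
    if not _RSID_PAT.match(rsid):
        raise NormalizationError(f"not a dbSNP accession: {rsid!r}")
    if rsid not in lookup:
        logger.warning("rsID %s absent from the offline lookup table", rsid)
        return []
    out = []
    for level, key in lookup[rsid]:
        out.append(
            NormalizedVariant(
                level=Level(level),
                key=key,
                variant_type=classify_variant_type(key),
            )
        )
    return out


def normalize_mention(
    mention: VariantMention,
    rsid_lookup: Optional[Mapping[str, Sequence[Tuple[str, str]]]] = None,
) -> List[NormalizedVariant]:
    """Convert one located mention to zero or more normalized variants.

    Returns an empty list for mentions that cannot be located on the coding
    sequence (exon/intron-only, IVS notation) and a key-less UNKNOWN record for
    underspecified forms (``c.?`` / ``p.?``).
    """
    surface = mention.span.surface
    if _unlocatable(surface):
        return []
    if _IVS.match(surface):
        return [
            NormalizedVariant(
                level=Level.DNA, key=None, variant_type=VariantType.UNKNOWN
            )
        ]
    if mention.family is Family.RSID:
        return expand_rsid(surface, rsid_lookup or {})
    if mention.op_kind_raw == "unknown":
        return [
            NormalizedVariant(
                level=mention.level, key=None, variant_type=VariantType.UNKNOWN
            )
        ]
    if mention.op_kind_raw == "sub":
        if mention.level is Level.PROTEIN:
            return [
                normalize_protein_sub(
                    mention.wild, int(mention.position), mention.mutated
                )
            ]
        if isinstance(mention.position, int):
            return [
                normalize_dna_sub(mention.position, mention.wild, mention.mutated)
            ]
        # range substitution, e.g. c.1852_1853AA>GC
        a, b = mention.position if isinstance(mention.position, tuple) else (None, None)
        if a is None:
            key = canonicalize_range(surface)
        else:
            key = f"c.{a}_{b}{mention.wild.upper()}>{mention.mutated.upper()}"
        return [
            NormalizedVariant(
                level=Level.DNA, key=key, variant_type=VariantType.SUBSTITUTION
            )
        ]
    # deletions / insertions / duplications / delins: canonicalize the surface
    try:
        key = canonicalize_range(surface)
    except NormalizationError:
        return [
            NormalizedVariant(
                level=mention.level, key=None, variant_type=VariantType.UNKNOWN
            )
        ]
    if mention.level is Level.DNA and not key.startswith("c."):
        key = f"c.{key}"
    return [
        NormalizedVariant(
            level=mention.level,
            key=key,
            variant_type=classify_variant_type(key),
        )
    ]


def normalize_codon_sub(
    codon_index: int, wild_base: str, mutated_base: str
) -> NormalizedVariant:
    """A substitution located only by codon: three candidate nucleotide keys.

    Codon-derived mentions carry candidate positions rather than one asserted
    position; extrinsic matching treats any candidate as a match.
    """
    positions = codon_to_nucleotide_positions(codon_index)
    return NormalizedVariant(
        level=Level.DNA,
        key=None,
        variant_type=VariantType.SUBSTITUTION,
        candidate_positions=positions,
    )


def codon_candidate_keys(
    codon_index: int, wild_base: str, mutated_base: str
) -> frozenset:
    """The three candidate DNA substitution keys of a codon-located mention."""
    return frozenset(
        normalize_dna_sub(p, wild_base, mutated_base).key
        for p in codon_to_nucleotide_positions(codon_index)
    )
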