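"""Recognizer families for genetic-variant mentions in plain text.

Four rule-based families with deliberately complementary coverage:

* ``PROTEIN_POINT`` — regular-expression point-substitution recognizer
  (``V600E``, ``M23A``, ``p.Lys618Ala``, ``p.Arg226X``, ``Ala140Thr``).
* ``HGVS_STRICT`` — a strict HGVS-style grammar for coding-DNA and protein
  variants (``c.1668C>T``, ``c.2700_2701delTC``, ``c.4236del8ins13``,
  intron-offset positions such as ``c.423-6...``, underspecified ``c.?``/``p.?``).
* ``DNA_EXTENDED`` — DNA forms beyond strict HGVS: range substitutions
  (``c.1852_1853AA>GC``), hyphenated ranges (``c.597-598delGA``), bare-position
  deletions (``1705delAG``) and, with whitespace tolerance enabled, sloppy
  typography (``C1668 C > T``, ``c.3927_3931del AAAGA``).
* ``RSID`` — dbSNP accessions (lowercase ``rs`` + digits, token-bounded).

Verbose natural-language descriptions ("1799T to A", "G:C to A:T transition",
"codon 41: A<-G", "del exon 3") are intentionally outside every family in the
default configuration; they are known coverage gaps of formulaic recognizers.

Within a family, overlapping candidate matches are resolved to the longest
match (ties: smaller start). Output is ordered by (start, end) and is
deterministic for a fixed text and configuration.
"""
from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from typing import Iterable, List, Optional, Sequence, Tuple

from .errors import ConfigError, NormalizationError
from .types import Family, Level, MentionSpan, Position, VariantMention, VariantType

# Amino-acid vocabularies. The stop / "any residue" token is written X, the
# style curated databases use (p.Arg226X).
AA3_CODES = (
    "Ala Arg Asn Asp Cys Gln Glu Gly His Ile Leu Lys Met Phe Pro Ser Thr Trp Tyr Val"
).split()
AA1_CODES = "ACDEFGHIKLMNPQRSTVWY"
_AA3 = "|".join(AA3_CODES)
_AA1 = f"[{AA1_CODES}]"
_AA1M = f"[{AA1_CODES}X*]"

# Token boundaries: a mention may not continue an alphanumeric token, and may
# not be preceded by a residue prefix dot other than its own.
_B = r"(?<![A-Za-z0-9.])"
_BL = r"(?<![A-Za-z0-9._-])"  # stricter left boundary for bare-position forms
_E = r"(?![A-Za-z0-9])"

_POS = r"\d+(?:[+-]\d+)?"  # coordinate with optional intron offset
_LOC = rf"{_POS}(?:_{_POS})?"  # single coordinate or underscore range
_SEQ = r"(?:[ACGT]+|\d+)"  # explicit bases or a base count


@dataclass(frozen=True)
class RecognizerConfig:
    """Per-family toggles.

    The default is "faithful": whitespace-corrupted and verbose forms are
    NOT recognized, reproducing the documented coverage gaps of formulaic
    recognizers. :meth:`extended` switches whitespace tolerance on.
    """

    families: frozenset = frozenset(Family)
    allow_parenthesized: bool = True
    require_mutated_residue: bool = True
    whitespace_tolerant: bool = False
    three_letter: bool = True
    verbose_forms: bool = False

    def __post_init__(self) -> None:
        if not self.families:
            raise ConfigError("at least one recognizer family must be enabled")

    @classmethod
    def faithful(cls) -> "RecognizerConfig":
        return cls()

    @classmethod
    def extended(cls) -> "RecognizerConfig":
        return cls(whitespace_tolerant=True)


# ---------------------------------------------------------------------------
# internal helpers


def _resolve_overlaps(candidates: List[VariantMention]) -> List[VariantMention]:
    """Longest match wins within a family; ties broken by smaller start."""
    order = sorted(
        range(len(candidates)),
        key=lambda i: (
            -(candidates[i].span.end - candidates[i].span.start),
            candidates[i].span.start,
            i,
        ),
    )
    kept: List[VariantMention] = []
    for i in order:
        m = candidates[i]
        if not any(m.span.overlaps(k.span) for k in kept):
            kept.append(m)
    return sorted(kept, key=lambda m: (m.span.start, m.span.end))


def _in_parens(text: str, start: int, end: int) -> bool:
    return start > 0 and text[start - 1] == "(" and text[end : end + 1] == ")"


def _mk_span(text: str, doc_id: str, start: int, end: int) -> MentionSpan:
    return MentionSpan(doc_id=doc_id, start=start, end=end, surface=text[start:end])


def _finditer(pattern: re.Pattern, text: str):
    pos = 0
    while True:
        m = pattern.search(text, pos)
        if m is None:
            return
        yield m
        # advance by one so overlapping alternatives still surface; overlap
        # resolution picks the winner afterwards
        pos = m.start() + 1


# ---------------------------------------------------------------------------
# PROTEIN_POINT

_P3 = re.compile(rf"{_B}(?:p\.)?({_AA3})(\d+)({_AA3}|X){_E}")
_P1 = re.compile(rf"{_B}(?:p\.)?({_AA1})(\d+)({_AA1M}){_E}")
_P1_NOMUT = re.compile(rf"{_B}(?:p\.)?({_AA1})(\d+){_E}")


def extract_protein_point(
    text: str, cfg: RecognizerConfig = RecognizerConfig(), doc_id: str = "doc"
) -> List[VariantMention]:
    """Locate protein point-substitution mentions.

    ``require_mutated_residue`` (default on) suppresses residue-position tokens
    with no substitution target, e.g. the distractor ``A1796``.
    """
    patterns: List[re.Pattern] = [_P1]
    if cfg.three_letter:
        patterns.insert(0, _P3)
    if not cfg.require_mutated_residue:
        patterns.append(_P1_NOMUT)
    out: List[VariantMention] = []
    for pat in patterns:
        for m in _finditer(pat, text):
            if not cfg.allow_parenthesized and _in_parens(text, m.start(), m.end()):
                continue
            groups = m.groups()
            wild, pos = groups[0], int(groups[1])
            mutated = groups[2] if len(groups) > 2 else ""
            out.append(
                VariantMention(
                    span=_mk_span(text, doc_id, m.start(), m.end()),
                    family=Family.PROTEIN_POINT,
                    level=Level.PROTEIN,
                    wild=wild,
                    position=pos,
                    mutated=mutated,
                    op_kind_raw="sub" if mutated else "",
                )
            )
    return _resolve_overlaps(out)


# ---------------------------------------------------------------------------
# HGVS_STRICT

# priority order: more specific operations first; overlap resolution keeps the
# longest match anyway, the order only breaks exact ties deterministically.
_HGVS_PATTERNS: List[Tuple[re.Pattern, str, Level]] = [
    (re.compile(rf"{_B}c\.({_LOC})del{_SEQ}?ins{_SEQ}{_E}"), "delins", Level.DNA),
    (re.compile(rf"{_B}c\.({_LOC})del{_SEQ}?{_E}"), "del", Level.DNA),
    (re.compile(rf"{_B}c\.({_LOC})ins{_SEQ}{_E}"), "ins", Level.DNA),
    (re.compile(rf"{_B}c\.({_LOC})dup{_SEQ}?{_E}"), "dup", Level.DNA),
    (re.compile(rf"{_B}c\.({_POS})([ACGT])>([ACGT]){_E}"), "sub", Level.DNA),
    (re.compile(rf"{_B}c\.\?{_E}"), "unknown", Level.DNA),
    (
        re.compile(rf"{_B}p\.({_AA3})(\d+)({_AA3})fs(?:(?:\*|Ter|X)\d*)?{_E}"),
        "fs",
        Level.PROTEIN,
    ),
    (
        re.compile(
            rf"{_B}p\.({_AA3})(\d+)(?:_({_AA3})(\d+))?"
            rf"(?:del(?:{_AA3})*|dup|ins(?:{_AA3})+|delins(?:{_AA3})+){_E}"
        ),
        "del",  # refined below from the matched surface
        Level.PROTEIN,
    ),
    (re.compile(rf"{_B}p\.({_AA3})(\d+)({_AA3}|\*|Ter){_E}"), "sub", Level.PROTEIN),
    (re.compile(rf"{_B}p\.({_AA1})(\d+)({_AA1}|\*){_E}"), "sub", Level.PROTEIN),
    (re.compile(rf"{_B}p\.\?{_E}"), "unknown", Level.PROTEIN),
]

_OP_FROM_SURFACE = re.compile(r"(delins|del|dup|ins|fs)")


def _parse_location(loc: str) -> Position:
    if "_" in loc:
        a, b = loc.split("_", 1)
        if a.isdigit() and b.isdigit():
            return (int(a), int(b))
        return loc
    if loc.isdigit():
        return int(loc)
    return loc  # intron-offset coordinate kept verbatim


def extract_hgvs(
    text: str, cfg: RecognizerConfig = RecognizerConfig(), doc_id: str = "doc"
) -> List[VariantMention]:
    """Locate mentions obeying a strict HGVS-style grammar.

    Accepts c./p.-prefixed substitutions, deletions, insertions, duplications
    and deletion-insertions; positions may be integers, underscore ranges, or
    intron-offset coordinates (``423-6``). ``c.?`` / ``p.?`` are accepted with
    unresolved parts. Non-standard nomenclature ("del exon 3", "codon 41: A<-G")
    is outside the grammar by design.
    """
    out: List[VariantMention] = []
    for pat, op, level in _HGVS_PATTERNS:
        for m in _finditer(pat, text):
            if not cfg.allow_parenthesized and _in_parens(text, m.start(), m.end()):
                continue
            surface = m.group(0)
            wild = mutated = ""
            position: Position = None
            if op == "unknown":
                position = "?"
            elif level is Level.DNA:
                position = _parse_location(m.group(1))
                if op == "sub":
                    wild, mutated = m.group(2), m.group(3)
                elif op == "del" and "ins" in surface.split("del", 1)[1]:
                    op = "delins"
            else:  # protein
                wild = m.group(1)
                position = int(m.group(2))
                if op == "sub":
                    mutated = m.group(3)
                elif op == "del":
                    # the lowercase operation token cannot collide with the
                    # capitalized three-letter residue codes
                    refined = _OP_FROM_SURFACE.search(surface)
                    op = refined.group(1) if refined else op
            out.append(
                VariantMention(
                    span=_mk_span(text, doc_id, m.start(), m.end()),
                    family=Family.HGVS_STRICT,
                    level=level,
                    wild=wild,
                    position=position,
                    mutated=mutated,
                    op_kind_raw=op,
                )
            )
    return _resolve_overlaps(out)


# ---------------------------------------------------------------------------
# DNA_EXTENDED

_X_RANGE_SUB = re.compile(rf"{_B}c\.(\d+)[_-](\d+)([ACGT]+)>([ACGT]+){_E}")
_X_HYPHEN_OP = re.compile(
    rf"{_B}c\.(\d+)-(\d+)"
    rf"(del{_SEQ}?(?:ins{_SEQ})?|ins{_SEQ}|dup{_SEQ}?){_E}"
)
_X_BARE_DEL = re.compile(rf"{_BL}(\d+)(?:[_-](\d+))?del([ACGT]+){_E}")
_X_WS_SUB = re.compile(
    rf"{_B}(?:c\.\s?|C)(\d+)\s*([ACGT])\s*>\s*([ACGT]){_E}"
)
_X_WS_DEL = re.compile(rf"{_B}c\.(\d+)_(\d+)del\s+([ACGT]+){_E}")
_X_VERBOSE = re.compile(rf"{_BL}(\d+)([ACGT])\s+to\s+([ACGT]){_E}")


def extract_dna_extended(
    text: str, cfg: RecognizerConfig = RecognizerConfig(), doc_id: str = "doc"
) -> List[VariantMention]:
    """Locate DNA mentions beyond the strict grammar.

    Whitespace-corrupted forms (``C1668 C > T``, ``c.3927_3931del AAAGA``) are
    only recognized when ``whitespace_tolerant`` is on; verbose prose forms
    ("1799T to A") only when ``verbose_forms`` is on. Both default off so the
    default configuration reproduces the documented misses.
    """
    out: List[VariantMention] = []

    for m in _finditer(_X_RANGE_SUB, text):
        a, b = int(m.group(1)), int(m.group(2))
        out.append(
            VariantMention(
                span=_mk_span(text, doc_id, m.start(), m.end()),
                family=Family.DNA_EXTENDED,
                level=Level.DNA,
                wild=m.group(3),
                position=(a, b),
                mutated=m.group(4),
                op_kind_raw="sub",
            )
        )
    for m in _finditer(_X_HYPHEN_OP, text):
        opstr = m.group(3)
        op = "delins" if ("del" in opstr and "ins" in opstr) else _OP_FROM_SURFACE.search(opstr).group(1)
        out.append(
            VariantMention(
                span=_mk_span(text, doc_id, m.start(), m.end()),
                family=Family.DNA_EXTENDED,
                level=Level.DNA,
                position=f"{m.group(1)}-{m.group(2)}",
                op_kind_raw=op,
            )
        )
    for m in _finditer(_X_BARE_DEL, text):
        a = int(m.group(1))
        position: Position = (a, int(m.group(2))) if m.group(2) else a
        out.append(
            VariantMention(
                span=_mk_span(text, doc_id, m.start(), m.end()),
                family=Family.DNA_EXTENDED,
                level=Level.DNA,
                position=position,
                op_kind_raw="del",
            )
        )
    if cfg.whitespace_tolerant:
        for m in _finditer(_X_WS_SUB, text):
            out.append(
                VariantMention(
                    span=_mk_span(text, doc_id, m.start(), m.end()),
                    family=Family.DNA_EXTENDED,
                    level=Level.DNA,
                    wild=m.group(2),
                    position=int(m.group(1)),
                    mutated=m.group(3),
                    op_kind_raw="sub",
                )
            )
        for m in _finditer(_X_WS_DEL, text):
            out.append(
                VariantMention(
                    span=_mk_span(text, doc_id, m.start(), m.end()),
                    family=Family.DNA_EXTENDED,
                    level=Level.DNA,
                    position=(int(m.group(1)), int(m.group(2))),
                    op_kind_raw="del",
                )
            )
    if cfg.verbose_forms:
        for m in _finditer(_X_VERBOSE, text):
            out.append(
                VariantMention(
                    span=_mk_span(text, doc_id, m.start(), m.end()),
                    family=Family.DNA_EXTENDED,
                    level=Level.DNA,
                    wild=m.group(2),
                    position=int(m.group(1)),
                    mutated=m.group(3),
                    op_kind_raw="sub",
                )
            )
    return _resolve_overlaps(out)


# ---------------------------------------------------------------------------
# RSID

_RSID = re.compile(r"(?<![A-Za-z0-9])rs(\d+)(?![A-Za-z0-9])")


def extract_rsid(text: str, doc_id: str = "doc") -> List[VariantMention]:
    """Locate dbSNP accessions: lowercase ``rs`` + digits at token boundaries."""
    out = [
        VariantMention(
            span=_mk_span(text, doc_id, m.start(), m.end()),
            family=Family.RSID,
            level=Level.UNRESOLVED,
            position=None,
        )
        for m in _RSID.finditer(text)
    ]
    return _resolve_overlaps(out)


_EXTRACTORS = {
    Family.PROTEIN_POINT: lambda t, c, d: extract_protein_point(t, c, d),
    Family.HGVS_STRICT: lambda t, c, d: extract_hgvs(t, c, d),
    Family.DNA_EXTENDED: lambda t, c, d: extract_dna_extended(t, c, d),
    Family.RSID: lambda t, c, d: extract_rsid(t, d),
}


def extract_all(
    text: str, cfg: RecognizerConfig = RecognizerConfig(), doc_id: str = "doc"
) -> dict:
    """Run every enabled family; returns {Family: [VariantMention, ...]}."""
    return {
        fam: _EXTRACTORS[fam](text, cfg, doc_id)
        for fam in sorted(cfg.families, key=lambda f: f.value)
    }


# ---------------------------------------------------------------------------
# variant typing

_T_UNKNOWN_MARK = re.compile(r"^[cp]\.\?$")
_T_PROT_SUB = re.compile(
    rf"^(?:p\.)?(?:(?:{_AA3})\d+(?:{_AA3}|X|Ter|\*)|{_AA1}\d+{_AA1M})$"
)
_T_DNA_SUB = re.compile(rf"^(?:c\.)?{_POS}(?:[_]{_POS})?[ACGT]*>[ACGT]+$")
_T_DELINS = re.compile(rf"^(?:c\.)?{_LOC}del{_SEQ}?ins{_SEQ}$")
_T_DEL = re.compile(
    rf"^(?:(?:c\.)?{_LOC}|p\.(?:{_AA3})\d+(?:_(?:{_AA3})\d+)?)del(?:{_SEQ}|(?:{_AA3})+)?$"
)
_T_INS = re.compile(
    rf"^(?:(?:c\.)?{_LOC}|p\.(?:{_AA3})\d+(?:_(?:{_AA3})\d+)?)ins(?:{_SEQ}|(?:{_AA3})+)$"
)
_T_DUP = re.compile(
    rf"^(?:(?:c\.)?{_LOC}|p\.(?:{_AA3})\d+(?:_(?:{_AA3})\d+)?)dup(?:{_SEQ}|(?:{_AA3})+)?$"
)
_T_FS = re.compile(rf"^p\.(?:{_AA3})\d+(?:{_AA3})?fs(?:(?:\*|Ter|X)\d*)?$")


def classify_variant_type(mention_or_key: str) -> VariantType:
    """Assign exactly one variant type to a mention string or normalized key.

    Strings the grammar does not cover — underspecified ``c.?``/``p.?``,
    non-standard frameshifts like ``L280FfsX4``, protein range substitutions
    like ``p.H776_C777>QS``, prose descriptions — type as UNKNOWN.
    """
    if not mention_or_key or not mention_or_key.strip():
        raise NormalizationError("cannot type an empty mention or key")
    s = mention_or_key.strip()
    if _T_UNKNOWN_MARK.match(s):
        return VariantType.UNKNOWN
    if _T_PROT_SUB.match(s) or _T_DNA_SUB.match(s):
        return VariantType.SUBSTITUTION
    if _T_DELINS.match(s):
        return VariantType.DELETION_INSERTION
    if _T_FS.match(s):
        return VariantType.FRAMESHIFT
    if _T_DUP.match(s):
        return VariantType.DUPLICATION
    if _T_DEL.match(s):
        return VariantType.DELETION
    if _T_INS.match(s):
        return VariantType.INSERTION
    return VariantType.UNKNOWN
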