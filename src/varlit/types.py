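"""Core domain types.

Offsets are 0-based, half-open, counted in Unicode code points — the convention
of BRAT-style standoff annotation, which the gold corpora use.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Optional, Tuple, Union


class SourceKind(str, Enum):
    """Where a document's text came from, mirroring the usual curation sources."""

    ABSTRACT = "abstract"
    FULLTEXT = "fulltext"
    TABLE = "table"
    SUPPLEMENTARY = "supplementary"
    PDF_TEXT = "pdf_text"


class Family(str, Enum):
    """Recognizer families with complementary coverage.

    PROTEIN_POINT   regular-expression point-mutation recognizer (V600E, p.Lys618Ala)
    HGVS_STRICT     strict HGVS-style grammar (c./p. substitutions, del/ins/dup/delins)
    DNA_EXTENDED    DNA forms beyond strict HGVS (range subs, hyphen ranges, sloppy text)
    RSID            dbSNP accessions (rs + digits)
    """

    PROTEIN_POINT = "PROTEIN_POINT"
    HGVS_STRICT = "HGVS_STRICT"
    DNA_EXTENDED = "DNA_EXTENDED"
    RSID = "RSID"


class Level(str, Enum):
    DNA = "DNA"
    PROTEIN = "PROTEIN"
    UNRESOLVED = "UNRESOLVED"


class VariantType(str, Enum):
    SUBSTITUTION = "SUBSTITUTION"
    DELETION = "DELETION"
    INSERTION = "INSERTION"
    DUPLICATION = "DUPLICATION"
    DELETION_INSERTION = "DELETION_INSERTION"
    FRAMESHIFT = "FRAMESHIFT"
    UNKNOWN = "UNKNOWN"


# A position descriptor: a single coordinate, an (a, b) range, an intron-offset
# coordinate rendered as a string ("423-6"), "?" for underspecified, or None.
Position = Union[int, Tuple[int, int], str, None]


@dataclass(frozen=True)
class Document:
    doc_id: str
    source_kind: SourceKind
    text: str

    def __post_init__(self) -> None:
        if not self.doc_id:
            raise ValueError("doc_id must be non-empty")


@dataclass(frozen=True)
class MentionSpan:
    """A located slice of a document; ``surface`` must equal ``text[start:end]``."""

    doc_id: str
    start: int
    end: int
    surface: str

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(f"invalid span [{self.start}, {self.end})")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "MentionSpan") -> bool:
        return (
            self.doc_id == other.doc_id
            and self.start < other.end
            and other.start < self.end
        )


@dataclass(frozen=True)
class VariantMention:
    """A raw variant mention located by one recognizer family."""

    span: MentionSpan
    family: Family
    level: Level
    wild: str = ""
    position: Position = None
    mutated: str = ""
    op_kind_raw: str = ""  # sub | del | ins | dup | delins | fs | "" (unparsed)

    def __post_init__(self) -> None:
        if self.op_kind_raw == "sub" and not (self.wild and self.mutated):
            raise ValueError("substitution mentions require wild and mutated tokens")


@dataclass(frozen=True)
class NormalizedVariant:
    """A canonical HGVS-like key (or no key, for unlocatable/underspecified forms).

    ``candidate_positions`` is set for codon-derived DNA mentions, where a codon
    index maps to three candidate nucleotide positions rather than one assertion.
    """

    level: Level
    key: Optional[str]
    variant_type: VariantType
    candidate_positions: Optional[frozenset] = None


@dataclass(frozen=True)
class CurationTriple:
    """The unit of extrinsic matching: {article, gene, variant key}.

    ``gene`` is empty for gene-relaxed triples from gene-free documents.
    ``alt_keys`` carries the alternative keys of codon-derived candidates.
    """

    doc_id: str
    gene: str
    variant_key: Optional[str]
    alt_keys: frozenset = frozenset()

    def keys(self) -> frozenset:
        keys = set(self.alt_keys)
        if self.variant_key:
            keys.add(self.variant_key)
        return frozenset(keys)


@dataclass(frozen=True)
class GeneMention:
    span: MentionSpan
    gene: str


@dataclass(frozen=True)
class ReferenceRow:
    """One curated-database row: an article, a gene, and DNA and/or protein keys."""

    pmid: str
    gene: str
    dna_key: str = ""
    protein_key: str = ""

    def keys(self) -> frozenset:
        return frozenset(k for k in (self.dna_key, self.protein_key) if k)


@dataclass(frozen=True)
class StandoffAnnotation:
    """One BRAT-dialect text-bound annotation line."""

    ann_id: str
    label: str
    start: int
    end: int
    surface: str

    def to_line(self) -> str:
        return f"{self.ann_id}\t{self.label} {self.start} {self.end}\t{self.surface}"
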