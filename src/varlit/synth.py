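"""Seeded synthetic corpus generator and the frozen fixture catalog.

The generator emulates the conditions under which variant-mention recognizers
are really used: documents mixing narrative sentences, tab-separated table
blocks (where much curated variant information actually lives) and distractor
tokens, with planted mentions drawn from the surface-form families the
recognizers cover — plus verbose known-gap forms no formulaic recognizer
matches. A matched synthetic curated database is produced alongside: a
configurable fraction of plantings is curated (``curation_rate``) and a
configurable fraction of curated rows is a "phantom" with no recognizable
mention in the text (``phantom_rate``), emulating variants curated from
supplementary files the text-mining pipeline never sees. A perfect extractor
therefore recovers 1 − phantom_rate of the reference in expectation.

It does not attempt natural-language realism: sentences are templated, and
document-level discourse (coreference, anaphora, figure callouts) is absent.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .errors import ConfigError
from .extractors import AA1_CODES, AA3_CODES
from .normalize import AMINO_ACIDS_3TO1
from .types import (
    Document,
    Family,
    Level,
    MentionSpan,
    ReferenceRow,
    SourceKind,
    VariantType,
)

_BASES = "ACGT"


# ---------------------------------------------------------------------------
# surface-form families

FORM_FAMILIES = (
    "strict_sub",
    "strict_del",
    "strict_ins",
    "strict_dup",
    "strict_delins",
    "protein_one",
    "protein_three",
    "hyphen_range",
    "ws_dna",
    "rsid",
    "verbose",
)

DEFAULT_FAMILY_MIX: Dict[str, float] = {
    "strict_sub": 0.20,
    "strict_del": 0.10,
    "strict_ins": 0.05,
    "strict_dup": 0.05,
    "strict_delins": 0.05,
    "protein_one": 0.20,
    "protein_three": 0.10,
    "hyphen_range": 0.10,
    "ws_dna": 0.05,
    "rsid": 0.05,
    "verbose": 0.05,
}

DEFAULT_GENE_VOCAB = ("MLH1", "MSH2", "MSH6", "PMS2", "APC", "BRAF", "KRAS", "TP53")

DISTRACTORS = (
    "A1796",
    "exon 10",
    "somatic mutation",
    "truncating mutation",
    "APC+",
    "del exon 3",
    "G:C to A:T transition",
    "Lynch syndrome",
)


@dataclass(frozen=True)
class Planted:
    """One generated surface form with its expected downstream behaviour."""

    surface: str
    level: Level
    key: Optional[str]
    family: Optional[Family]  # family expected to recognize it, None = known gap
    variant_type: VariantType
    extended_only: bool = False  # recognized only with whitespace tolerance on
    rsid: Optional[str] = None


def _pick(rng: np.random.Generator, seq: Sequence):
    return seq[int(rng.integers(0, len(seq)))]


def _two_bases(rng: np.random.Generator) -> Tuple[str, str]:
    w = _pick(rng, _BASES)
    m = _pick(rng, [b for b in _BASES if b != w])
    return w, m


def _seq(rng: np.random.Generator, lo: int, hi: int) -> str:
    return "".join(_pick(rng, _BASES) for _ in range(int(rng.integers(lo, hi + 1))))


def _make_form(name: str, rng: np.random.Generator) -> Planted:
    pos = int(rng.integers(50, 5000))
    if name == "strict_sub":
        w, m = _two_bases(rng)
        key = f"c.{pos}{w}>{m}"
        return Planted(key, Level.DNA, key, Family.HGVS_STRICT, VariantType.SUBSTITUTION)
    if name == "strict_del":
        b = pos + int(rng.integers(1, 4))
        key = f"c.{pos}_{b}del{_seq(rng, b - pos + 1, b - pos + 1)}"
        return Planted(key, Level.DNA, key, Family.HGVS_STRICT, VariantType.DELETION)
    if name == "strict_ins":
        key = f"c.{pos}_{pos + 1}ins{_seq(rng, 1, 4)}"
        return Planted(key, Level.DNA, key, Family.HGVS_STRICT, VariantType.INSERTION)
    if name == "strict_dup":
        b = pos + int(rng.integers(1, 4))
        key = f"c.{pos}_{b}dup"
        return Planted(key, Level.DNA, key, Family.HGVS_STRICT, VariantType.DUPLICATION)
    if name == "strict_delins":
        b = pos + int(rng.integers(1, 4))
        key = f"c.{pos}_{b}delins{_seq(rng, 2, 5)}"
        return Planted(
            key, Level.DNA, key, Family.HGVS_STRICT, VariantType.DELETION_INSERTION
        )
    if name == "protein_one":
        w = _pick(rng, AA1_CODES)
        m = _pick(rng, [a for a in AA1_CODES if a != w])
        p = int(rng.integers(2, 999))
        key = f"{w}{p}{m}"
        surface = f"p.{key}" if rng.random() < 0.3 else key
        return Planted(
            surface, Level.PROTEIN, key, Family.PROTEIN_POINT, VariantType.SUBSTITUTION
        )
    if name == "protein_three":
        w3 = _pick(rng, AA3_CODES)
        m3 = _pick(rng, [a for a in AA3_CODES if a != w3])
        p = int(rng.integers(2, 999))
        surface = f"p.{w3}{p}{m3}" if rng.random() < 0.5 else f"{w3}{p}{m3}"
        key = f"{AMINO_ACIDS_3TO1[w3]}{p}{AMINO_ACIDS_3TO1[m3]}"
        return Planted(
            surface, Level.PROTEIN, key, Family.PROTEIN_POINT, VariantType.SUBSTITUTION
        )
    if name == "hyphen_range":
        b = pos + int(rng.integers(1, 3))
        seq = _seq(rng, b - pos + 1, b - pos + 1)
        surface = f"c.{pos}-{b}del{seq}"
        key = f"c.{pos}_{b}del{seq}"
        return Planted(surface, Level.DNA, key, Family.DNA_EXTENDED, VariantType.DELETION)
    if name == "ws_dna":
        w, m = _two_bases(rng)
        surface = f"C{pos} {w} > {m}"
        key = f"c.{pos}{w}>{m}"
        return Planted(
            surface,
            Level.DNA,
            key,
            Family.DNA_EXTENDED,
            VariantType.SUBSTITUTION,
            extended_only=True,
        )
    if name == "rsid":
        rsid = f"rs{int(rng.integers(1000, 10_000_000))}"
        w, m = _two_bases(rng)
        key = f"c.{pos}{w}>{m}"
        return Planted(
            rsid, Level.DNA, key, Family.RSID, VariantType.SUBSTITUTION, rsid=rsid
        )
    if name == "verbose":
        w, m = _two_bases(rng)
        surface = _pick(
            rng,
            [
                f"{pos}{w} to {m}",
                f"codon {int(rng.integers(1, 200))}: {w}>{m}",
                "del exon " + str(int(rng.integers(1, 20))),
            ],
        )
        return Planted(surface, Level.DNA, None, None, VariantType.UNKNOWN)
    raise ConfigError(f"unknown surface-form family: {name}")


# ---------------------------------------------------------------------------
# corpus specification and generation


@dataclass(frozen=True)
class CorpusSpec:
    seed: int = 0
    n_docs: int = 100
    family_mix: Tuple[Tuple[str, float], ...] = tuple(DEFAULT_FAMILY_MIX.items())
    distractor_rate: float = 1.0
    gene_vocab: Tuple[str, ...] = DEFAULT_GENE_VOCAB
    table_block_fraction: float = 0.3
    curation_rate: float = 0.9
    phantom_rate: float = 0.1
    mean_mentions_per_doc: float = 3.0

    def __post_init__(self) -> None:
        mix = dict(self.family_mix)
        if not mix or all(w == 0 for w in mix.values()):
            raise ConfigError("at least one surface-form family must have weight > 0")
        if any(w < 0 for w in mix.values()):
            raise ConfigError("family weights must be non-negative")
        for rate in (self.table_block_fraction, self.curation_rate, self.phantom_rate):
            if not 0.0 <= rate <= 1.0:
                raise ConfigError("rates must lie in [0, 1]")
        unknown = set(mix) - set(FORM_FAMILIES)
        if unknown:
            raise ConfigError(f"unknown surface-form families: {sorted(unknown)}")


@dataclass(frozen=True)
class GoldRecord:
    doc_id: str
    span: MentionSpan
    level: Level
    key: Optional[str]
    family: Optional[Family]
    variant_type: VariantType
    planted: bool = True
    extended_only: bool = False


@dataclass
class SyntheticCorpus:
    spec: CorpusSpec
    documents: List[Document]
    gold: List[GoldRecord]
    reference: List[ReferenceRow]
    rsid_lookup: Dict[str, List[Tuple[str, str]]]
    doc_genes: Dict[str, List[str]]
    n_phantom_rows: int


_SENTENCES = (
    ("We identified the variant ", " in affected members of the family."),
    ("Screening revealed ", " in two unrelated probands."),
    ("The mutation ", " segregated with the disease phenotype."),
    ("Sequence analysis detected ", " in the index patient."),
)


def _weighted_choice(rng: np.random.Generator, mix: Dict[str, float]) -> str:
    names = [n for n in FORM_FAMILIES if mix.get(n, 0.0) > 0]
    weights = np.array([mix[n] for n in names], dtype=float)
    weights /= weights.sum()
    return names[int(rng.choice(len(names), p=weights))]


def generate_corpus(spec: CorpusSpec) -> SyntheticCorpus:
    """Generate documents, gold records and a matched synthetic reference DB.

    Deterministic for a fixed spec: one root seed, with per-document
    substreams derived from (seed, document index) so documents are
    reproducible independently of generation order.
    """
    mix = dict(spec.family_mix)
    documents: List[Document] = []
    gold: List[GoldRecord] = []
    reference: List[ReferenceRow] = []
    rsid_lookup: Dict[str, List[Tuple[str, str]]] = {}
    doc_genes: Dict[str, List[str]] = {}
    n_phantoms = 0

    for idx in range(spec.n_docs):
        rng = np.random.default_rng([spec.seed, idx])
        doc_id = f"synth{idx:05d}"
        genes = sorted(
            {_pick(rng, spec.gene_vocab) for _ in range(int(rng.integers(1, 3)))}
        )
        doc_genes[doc_id] = genes
        n_mentions = 1 + int(rng.poisson(max(spec.mean_mentions_per_doc - 1, 0)))
        planted = [_make_form(_weighted_choice(rng, mix), rng) for _ in range(n_mentions)]
        use_table = rng.random() < spec.table_block_fraction

        parts: List[str] = [f"Mutation analysis of the {' and '.join(genes)} genes.\n"]
        cursor = len(parts[0])
        spans: List[Tuple[Planted, int, int]] = []

        def _emit(chunk: str) -> None:
            nonlocal cursor
            parts.append(chunk)
            cursor += len(chunk)

        n_table = n_mentions // 2 if use_table else 0
        for p in planted[: n_mentions - n_table]:
            pre, post = _SENTENCES[int(rng.integers(0, len(_SENTENCES)))]
            _emit(pre)
            start = cursor
            _emit(p.surface)
            spans.append((p, start, cursor))
            _emit(post + "\n")
        n_distract = int(rng.poisson(spec.distractor_rate))
        for _ in range(n_distract):
            _emit(f"Note the report of {_pick(rng, DISTRACTORS)} in earlier work.\n")
        if n_table:
            _emit("Gene\tVariant\tClassification\n")
            for p in planted[n_mentions - n_table :]:
                _emit(f"{_pick(rng, genes)}\t")
                start = cursor
                _emit(p.surface)
                spans.append((p, start, cursor))
                _emit("\tpathogenic\n")

        text = "".join(parts)
        documents.append(
            Document(
                doc_id=doc_id,
                source_kind=SourceKind.TABLE if use_table else SourceKind.FULLTEXT,
                text=text,
            )
        )
        for p, start, end in spans:
            assert text[start:end] == p.surface
            gold.append(
                GoldRecord(
                    doc_id=doc_id,
                    span=MentionSpan(doc_id=doc_id, start=start, end=end, surface=p.surface),
                    level=p.level,
                    key=p.key,
                    family=p.family,
                    variant_type=p.variant_type,
                    extended_only=p.extended_only,
                )
            )
            if p.rsid and p.key:
                rsid_lookup[p.rsid] = [(Level.DNA.value, p.key)]
            if p.key is not None and rng.random() < spec.curation_rate:
                gene = _pick(rng, genes)
                if rng.random() < spec.phantom_rate:
                    w, m = _two_bases(rng)
                    phantom_key = f"c.{int(rng.integers(6000, 9000))}{w}>{m}"
                    reference.append(
                        ReferenceRow(pmid=doc_id, gene=gene, dna_key=phantom_key)
                    )
                    n_phantoms += 1
                elif p.level is Level.PROTEIN:
                    reference.append(
                        ReferenceRow(pmid=doc_id, gene=gene, protein_key=p.key)
                    )
                else:
                    reference.append(
                        ReferenceRow(pmid=doc_id, gene=gene, dna_key=p.key)
                    )

    return SyntheticCorpus(
        spec=spec,
        documents=documents,
        gold=gold,
        reference=reference,
        rsid_lookup=rsid_lookup,
        doc_genes=doc_genes,
        n_phantom_rows=n_phantoms,
    )


def write_gold(gold: Sequence[GoldRecord], path) -> None:
    """Write gold records as BRAT-dialect .ann files, one per document."""
    from .io import write_standoff

    write_standoff([g.span for g in gold], path)


# ---------------------------------------------------------------------------
# frozen in-text fixture catalog


@dataclass(frozen=True)
class FixtureEntry:
    """One real-world surface form with its documented expected outcome.

    ``hit_families`` is the expected coverage under the default (faithful)
    configuration; ``hit_families_extended`` under whitespace tolerance. A
    ``key`` of None means no canonical key can be derived. Negative entries are
    mutation-adjacent tokens that must never fire.
    """

    surface: str
    level: Optional[Level]
    key: Optional[str]
    variant_type: VariantType
    hit_families: frozenset
    hit_families_extended: frozenset
    negative: bool = False
    note: str = ""


def _fs(*families: Family) -> frozenset:
    return frozenset(families)


def fixture_catalog() -> List[FixtureEntry]:
    """The frozen catalog of documented hits, misses and distractors."""
    PP, HS, DX, RS = (
        Family.PROTEIN_POINT,
        Family.HGVS_STRICT,
        Family.DNA_EXTENDED,
        Family.RSID,
    )
    S, D, DI, U = (
        VariantType.SUBSTITUTION,
        VariantType.DELETION,
        VariantType.DELETION_INSERTION,
        VariantType.UNKNOWN,
    )
    P, N = Level.PROTEIN, Level.DNA
    e = FixtureEntry
    return [
        e("p.Lys618Ala", P, "K618A", S, _fs(PP, HS), _fs(PP, HS)),
        e("V600E", P, "V600E", S, _fs(PP), _fs(PP)),
        e("M23A", P, "M23A", S, _fs(PP), _fs(PP)),
        e("p.Pro622Thr", P, "P622T", S, _fs(PP, HS), _fs(PP, HS)),
        e("p.Arg226X", P, "R226X", S, _fs(PP), _fs(PP),
          note="X is not a strict-grammar residue; the point-mutation patterns cover it"),
        e("Ala140Thr", P, "A140T", S, _fs(PP), _fs(PP)),
        e("A1796", None, None, U, _fs(), _fs(), negative=True,
          note="residue+position token with no substitution target"),
        e("c.2700_2701delTC", N, "c.2700_2701delTC", D, _fs(HS), _fs(HS)),
        e("c.1852_1853AA>GC", N, "c.1852_1853AA>GC", S, _fs(DX), _fs(DX),
          note="range substitution, outside the strict grammar"),
        e("c.597-598delGA", N, "c.597_598delGA", D, _fs(HS, DX), _fs(HS, DX),
          note="hyphen range; strict grammar reads it syntactically as an offset, "
               "normalization resolves the increasing pair to a range"),
        e("c.1704_1705delAG", N, "c.1704_1705delAG", D, _fs(HS), _fs(HS)),
        e("1705delAG", N, "c.1705delAG", D, _fs(DX), _fs(DX),
          note="bare-position deletion substring"),
        e("C1668 C > T", N, "c.1668C>T", S, _fs(), _fs(DX),
          note="whitespace-corrupted substitution; a miss unless tolerance is on"),
        e("c.4236del8ins13", N, "c.4236del8ins13", DI, _fs(HS), _fs(HS)),
        e("c.423-6delAAATAGGTinsGAAGCAAGATCAG", N,
          "c.423-6delAAATAGGTinsGAAGCAAGATCAG", DI, _fs(HS, DX), _fs(HS, DX),
          note="intron-offset position: the hyphen is preserved (decreasing pair)"),
        e("IVS17(+5)G>C", N, None, U, _fs(), _fs(),
          note="legacy intron notation; no coding position derivable"),
        e("1799T to A", N, None, U, _fs(), _fs(),
          note="verbose prose form; recognizable only via the off-by-default verbose toggle"),
        e("codon 41: A←G", N, None, U, _fs(), _fs()),
        e("codon 33: C>A", N, None, U, _fs(), _fs()),
        e("del exon 3", N, None, U, _fs(), _fs()),
        e("exon 10", None, None, U, _fs(), _fs(),
          note="location only, no specific change; removed before key emission"),
        e("L280FfsX4", P, None, U, _fs(), _fs(),
          note="non-standard frameshift, outside the strict grammar"),
        e("p.H776_C777>QS", P, None, U, _fs(), _fs(),
          note="protein range substitution, outside the strict grammar"),
        e("c.?", N, None, U, _fs(HS), _fs(HS),
          note="underspecified; accepted with unresolved parts, no key"),
        e("p.?", P, None, U, _fs(HS), _fs(HS),
          note="underspecified; accepted with unresolved parts, no key"),
        e("G:C to A:T transition", None, None, U, _fs(), _fs()),
        e("APC+", None, None, U, _fs(), _fs(), negative=True,
          note="mutated-gene term, not a sequence change"),
        e("somatic mutation", None, None, U, _fs(), _fs(), negative=True,
          note="mutation-type term, dictionary territory"),
        e("rs123456", N, None, U, _fs(RS), _fs(RS),
          note="dbSNP accession; key requires the offline lookup table"),
    ]
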