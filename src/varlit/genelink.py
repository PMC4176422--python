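"""Gene tagging and gene-variant linking.

A filtered synonym dictionary is matched in text with ConceptMapper-style
semantics — case-insensitive, tokens in order, tokens adjacent, longest match
only — and tagged genes are linked to the document's variants by co-occurrence
(the cross product), yielding curation triples {document, gene, variant key}.

Filtering removes misleading or ambiguous synonyms: those ending with
"disease", "syndrome" or "susceptibility" (which name phenotypes, not genes)
and stopwords. For the mismatch-repair genes commonly written with a leading
"h" for human (hMSH2 etc.), configured h-prefixed synonyms are added.
"""
from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Sequence, Set, Tuple

from .errors import ConfigError
from .types import CurationTriple, GeneMention, MentionSpan

logger = logging.getLogger(__name__)

BANNED_SUFFIXES = ("disease", "syndrome", "susceptibility")

# A compact standard stopword list; enough to drop synonyms that collide with
# ordinary prose tokens.
DEFAULT_STOPWORDS = frozenset(
    """a an and are as at be but by for from had has have in is it its not of on
    or that the this to was were which with all can who when where why how what
    up down out if then than so no yes does did doing done most more""".split()
)

DEFAULT_H_PREFIX_GENES = ("MSH2", "MSH6", "PMS2")

_TOKEN = re.compile(r"[A-Za-z0-9]+")


def _tokens(text: str) -> List[str]:
    return [t.lower() for t in _TOKEN.findall(text)]


@dataclass
class GeneDictionary:
    """Filtered synonym -> gene-symbol map plus its matching configuration."""

    entries: Dict[str, str]  # synonym (verbatim) -> symbol
    h_prefix_genes: Tuple[str, ...] = DEFAULT_H_PREFIX_GENES
    # derived: lowercase token tuple -> symbol, and max synonym token length
    _index: Dict[Tuple[str, ...], str] = field(default_factory=dict, repr=False)
    _max_tokens: int = field(default=1, repr=False)

    def __post_init__(self) -> None:
        for synonym, symbol in self.entries.items():
            toks = tuple(_tokens(synonym))
            if toks:
                self._index.setdefault(toks, symbol)
        self._max_tokens = max((len(t) for t in self._index), default=1)

    def __len__(self) -> int:
        return len(self.entries)


def build_gene_dictionary(
    synonym_rows: Iterable[Tuple[str, str]],
    stopwords: frozenset = DEFAULT_STOPWORDS,
    h_prefix_genes: Sequence[str] = DEFAULT_H_PREFIX_GENES,
) -> GeneDictionary:
    """Build a filtered dictionary from (symbol, synonym) rows.

    Drops synonyms ending (case-insensitively) with a banned phenotype suffix,
    stopword synonyms and duplicates; adds "h"+symbol synonyms for the
    configured human-prefixed genes. Raises if nothing survives filtering.
    """
    entries: Dict[str, str] = {}
    seen: Set[str] = set()
    n_suffix = n_stop = n_dup = 0
    for symbol, synonym in synonym_rows:
        synonym = synonym.strip()
        if not synonym:
            continue
        low = synonym.lower()
        if any(low.endswith(suffix) for suffix in BANNED_SUFFIXES):
            n_suffix += 1
            continue
        if low in stopwords:
            n_stop += 1
            continue
        if low in seen:
            n_dup += 1
            continue
        seen.add(low)
        entries[synonym] = symbol
    symbols = set(entries.values())
    for gene in h_prefix_genes:
        if gene in symbols and ("h" + gene).lower() not in seen:
            entries["h" + gene] = gene
            seen.add(("h" + gene).lower())
    if not entries:
        raise ConfigError("gene dictionary is empty after filtering")
    logger.info(
        "gene dictionary built: %d entries (filtered %d banned-suffix, %d stopword, %d duplicate)",
        len(entries), n_suffix, n_stop, n_dup,
    )
    return GeneDictionary(entries=entries, h_prefix_genes=tuple(h_prefix_genes))


def tag_genes(text: str, gdict: GeneDictionary, doc_id: str = "doc") -> List[GeneMention]:
    """Tag gene names: case-insensitive, token order preserved, tokens adjacent,
    longest match only. Returned spans never overlap."""
    token_spans = [(m.group(0), m.start(), m.end()) for m in _TOKEN.finditer(text)]
    mentions: List[GeneMention] = []
    i = 0
    n = len(token_spans)
    while i < n:
        best = None
        upper = min(gdict._max_tokens, n - i)
        for width in range(upper, 0, -1):
            window = tuple(t[0].lower() for t in token_spans[i : i + width])
            symbol = gdict._index.get(window)
            if symbol is not None:
                best = (width, symbol)
                break
        if best is None:
            i += 1
            continue
        width, symbol = best
        start = token_spans[i][1]
        end = token_spans[i + width - 1][2]
        mentions.append(
            GeneMention(
                span=MentionSpan(doc_id=doc_id, start=start, end=end, surface=text[start:end]),
                gene=symbol,
            )
        )
        i += width
    return mentions


def link_by_cooccurrence(
    doc_genes: Set[str], doc_variants: Iterable, doc_id: str
) -> Set[CurationTriple]:
    """Cross product of a document's genes and variant keys.

    A gene-free document emits gene-empty triples so gene-relaxed matching
    remains possible. ``doc_variants`` elements are either key strings or
    ``(key, alt_keys)`` pairs for codon-derived candidates.
    """
    triples: Set[CurationTriple] = set()
    genes = sorted(doc_genes) if doc_genes else [""]
    for variant in doc_variants:
        if isinstance(variant, tuple):
            key, alt = variant
            alt = frozenset(alt)
        else:
            key, alt = variant, frozenset()
        for gene in genes:
            triples.add(
                CurationTriple(doc_id=doc_id, gene=gene, variant_key=key, alt_keys=alt)
            )
    return triples
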