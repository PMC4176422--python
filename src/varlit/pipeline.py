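"""End-to-end convenience pipeline: documents -> mentions -> keys -> triples."""
from __future__ import annotations

from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Set, Tuple

from .extractors import RecognizerConfig, extract_all
from .genelink import GeneDictionary, link_by_cooccurrence, tag_genes
from .normalize import filter_unlocatable, normalize_mention
from .types import CurationTriple, Document, Family, VariantMention


def extract_documents(
    documents: Sequence[Document], cfg: RecognizerConfig = RecognizerConfig()
) -> Dict[Family, List[VariantMention]]:
    """Run every enabled recognizer family over a document collection."""
    out: Dict[Family, List[VariantMention]] = {f: [] for f in sorted(cfg.families, key=lambda x: x.value)}
    for doc in documents:
        for fam, mentions in extract_all(doc.text, cfg, doc_id=doc.doc_id).items():
            out[fam].extend(mentions)
    return out


def mentions_to_keys(
    mentions: Iterable[VariantMention],
    rsid_lookup: Optional[Mapping] = None,
) -> Set[Tuple[str, str]]:
    """Normalize mentions to a set of (doc_id, canonical key) pairs."""
    keys: Set[Tuple[str, str]] = set()
    for m in filter_unlocatable(list(mentions)):
        for nv in normalize_mention(m, rsid_lookup=rsid_lookup):
            if nv.key:
                keys.add((m.span.doc_id, nv.key))
    return keys


def documents_to_triples(
    documents: Sequence[Document],
    cfg: RecognizerConfig = RecognizerConfig(),
    gene_dictionary: Optional[GeneDictionary] = None,
    rsid_lookup: Optional[Mapping] = None,
) -> Set[CurationTriple]:
    """Extract, normalize and link: the full curation-support pipeline."""
    triples: Set[CurationTriple] = set()
    for doc in documents:
        mentions = [m for fam in extract_all(doc.text, cfg, doc_id=doc.doc_id).values() for m in fam]
        doc_keys = {k for _, k in mentions_to_keys(mentions, rsid_lookup)}
        genes = (
            {g.gene for g in tag_genes(doc.text, gene_dictionary, doc_id=doc.doc_id)}
            if gene_dictionary
            else set()
        )
        if doc_keys:
            triples |= link_by_cooccurrence(genes, sorted(doc_keys), doc.doc_id)
    return triples
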