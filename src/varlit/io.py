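"""Readers and writers for the external plain-text formats.

Formats:

* corpus: a directory of UTF-8 ``.txt`` files (doc id = file stem) or a TSV
  with columns ``doc_id, source_kind, text`` where tabs/newlines in the text
  are backslash-escaped;
* gold annotations: BRAT-dialect standoff ``.ann`` files, one per document,
  lines ``T<n>\t<label> <start> <end>\t<surface>``;
* mentions, triples, gene-dictionary, rsID-lookup and reference-database TSVs
  with fixed headers.

All files are UTF-8 without BOM; newlines are normalized on read.
"""
from __future__ import annotations

import html
import logging
from pathlib import Path
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import pandas as pd
import yaml

from .errors import CorruptAnnotationError, FormatError, NormalizationError
from .normalize import canonicalize_range
from .types import (
    Document,
    Family,
    Level,
    MentionSpan,
    CurationTriple,
    ReferenceRow,
    SourceKind,
    StandoffAnnotation,
    VariantMention,
)

logger = logging.getLogger(__name__)

MENTION_COLUMNS = ["doc_id", "start", "end", "surface", "family", "level", "op_kind_raw"]
NORMALIZED_COLUMNS = ["doc_id", "level", "key", "variant_type", "family"]
TRIPLE_COLUMNS = ["pmid", "gene", "variant_key"]
REFERENCE_COLUMNS = ["pmid", "gene", "dna_variant", "protein_variant"]
DICTIONARY_COLUMNS = ["gene_symbol", "synonym"]
RSID_COLUMNS = ["rsid", "level", "key"]


def _read_text(path: Path) -> str:
    raw = path.read_bytes()
    if raw.startswith(b"\xef\xbb\xbf"):
        raise FormatError(f"{path}: UTF-8 BOM not allowed")
    text = raw.decode("utf-8")
    return text.replace("\r\n", "\n").replace("\r", "\n")


def _escape(text: str) -> str:
    return text.replace("\\", "\\\\").replace("\t", "\\t").replace("\n", "\\n")


def _unescape(text: str) -> str:
    out, i = [], 0
    while i < len(text):
        c = text[i]
        if c == "\\" and i + 1 < len(text):
            nxt = text[i + 1]
            out.append({"t": "\t", "n": "\n", "\\": "\\"}.get(nxt, "\\" + nxt))
            i += 2
        else:
            out.append(c)
            i += 1
    return "".join(out)


def _read_tsv(path: Path, required: Sequence[str]) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required columns {missing}")
    extra = [c for c in df.columns if c not in required]
    if extra:
        logger.warning("%s: ignoring unknown columns %s", path, extra)
    return df


# ---------------------------------------------------------------------------
# corpus


def read_corpus(path, decode_entities: bool = False) -> List[Document]:
    """Read a corpus from a directory of .txt files or a corpus TSV.

    ``decode_entities`` converts residual XML escapes to their characters
    (``A&gt;T`` to ``A>T``), as needed for text exported from article XML.
    """
    path = Path(path)
    docs: List[Document] = []
    seen: set = set()
    if path.is_dir():
        for f in sorted(path.glob("*.txt")):
            doc_id = f.stem
            if doc_id in seen:
                raise FormatError(f"duplicate doc_id: {doc_id}")
            seen.add(doc_id)
            text = _read_text(f)
            if decode_entities:
                text = html.unescape(text)
            docs.append(Document(doc_id=doc_id, source_kind=SourceKind.FULLTEXT, text=text))
        return docs
    _read_text(path)  # BOM / encoding check
    df = _read_tsv(path, ["doc_id", "source_kind", "text"])
    for row in df.itertuples(index=False):
        if row.doc_id in seen:
            raise FormatError(f"duplicate doc_id: {row.doc_id}")
        seen.add(row.doc_id)
        text = _unescape(row.text)
        if decode_entities:
            text = html.unescape(text)
        docs.append(
            Document(doc_id=row.doc_id, source_kind=SourceKind(row.source_kind), text=text)
        )
    return docs


def write_corpus(documents: Sequence[Document], path) -> None:
    df = pd.DataFrame(
        {
            "doc_id": [d.doc_id for d in documents],
            "source_kind": [d.source_kind.value for d in documents],
            "text": [_escape(d.text) for d in documents],
        }
    )
    df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# standoff annotations


def parse_standoff_line(line: str) -> Optional[StandoffAnnotation]:
    """Parse one text-bound annotation line; returns None for non-T lines."""
    if not line or not line.startswith("T"):
        return None
    try:
        ann_id, middle, surface = line.split("\t", 2)
        label, start, end = middle.split(" ")
        return StandoffAnnotation(
            ann_id=ann_id, label=label, start=int(start), end=int(end), surface=surface
        )
    except ValueError as exc:
        raise CorruptAnnotationError(f"malformed standoff line: {line!r}") from exc


def read_standoff(
    path, documents: Sequence[Document], label: str = "mutation"
) -> List[MentionSpan]:
    """Read gold spans from .ann files next to their documents.

    ``path`` is a directory of ``<doc_id>.ann`` files. Annotations with other
    entity labels are ignored (counted in a log line); an annotation whose
    surface disagrees with the document slice raises, naming the line.
    """
    path = Path(path)
    by_id = {d.doc_id: d for d in documents}
    spans: List[MentionSpan] = []
    n_ignored = 0
    for f in sorted(path.glob("*.ann")):
        doc = by_id.get(f.stem)
        if doc is None:
            logger.warning("no document loaded for annotation file %s", f.name)
            continue
        for line in _read_text(f).splitlines():
            ann = parse_standoff_line(line)
            if ann is None:
                continue
            if ann.label != label:
                n_ignored += 1
                continue
            piece = doc.text[ann.start : ann.end]
            if piece != ann.surface:
                raise CorruptAnnotationError(
                    f"{f.name}: surface {ann.surface!r} != text slice {piece!r} "
                    f"in line {line!r}"
                )
            spans.append(
                MentionSpan(doc_id=doc.doc_id, start=ann.start, end=ann.end, surface=ann.surface)
            )
    if n_ignored:
        logger.info("ignored %d annotations with other entity labels", n_ignored)
    return spans


def write_standoff(spans: Sequence[MentionSpan], path, label: str = "mutation") -> None:
    """Write spans as one .ann file per document (empty docs get empty files)."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    by_doc: Dict[str, List[MentionSpan]] = {}
    for s in spans:
        by_doc.setdefault(s.doc_id, []).append(s)
    for doc_id, doc_spans in sorted(by_doc.items()):
        lines = []
        for i, s in enumerate(sorted(doc_spans, key=lambda x: (x.start, x.end)), 1):
            if "\n" in s.surface:
                raise CorruptAnnotationError(
                    f"{doc_id}: span surface contains a newline"
                )
            lines.append(
                StandoffAnnotation(
                    ann_id=f"T{i}", label=label, start=s.start, end=s.end, surface=s.surface
                ).to_line()
            )
        (path / f"{doc_id}.ann").write_text(
            "\n".join(lines) + ("\n" if lines else ""), encoding="utf-8"
        )


# ---------------------------------------------------------------------------
# tabular formats


def write_mentions(mentions: Sequence[VariantMention], path) -> None:
    df = pd.DataFrame(
        [
            {
                "doc_id": m.span.doc_id,
                "start": m.span.start,
                "end": m.span.end,
                "surface": _escape(m.span.surface),
                "family": m.family.value,
                "level": m.level.value,
                "op_kind_raw": m.op_kind_raw,
            }
            for m in mentions
        ],
        columns=MENTION_COLUMNS,
    )
    df.to_csv(path, sep="\t", index=False)


def read_mentions(path) -> List[VariantMention]:
    df = _read_tsv(Path(path), MENTION_COLUMNS)
    out = []
    for row in df.itertuples(index=False):
        surface = _unescape(row.surface)
        out.append(
            VariantMention(
                span=MentionSpan(
                    doc_id=row.doc_id, start=int(row.start), end=int(row.end), surface=surface
                ),
                family=Family(row.family),
                level=Level(row.level),
                op_kind_raw=row.op_kind_raw,
                wild="?" if row.op_kind_raw == "sub" else "",
                mutated="?" if row.op_kind_raw == "sub" else "",
            )
        )
    return out


def read_reference_db(path) -> List[ReferenceRow]:
    """Read a curated-database TSV: pmid, gene, dna_variant, protein_variant.

    Keys are canonicalized; keys outside the variant grammar (legacy IVS
    notation and the like) are kept verbatim with a warning — they will simply
    never be matched. Rows with both variant cells empty are skipped.
    """
    df = _read_tsv(Path(path), REFERENCE_COLUMNS)
    rows: List[ReferenceRow] = []
    for row in df.itertuples(index=False):
        dna, prot = row.dna_variant.strip(), row.protein_variant.strip()
        if not dna and not prot:
            logger.warning("skipping reference row with no variant: pmid=%s", row.pmid)
            continue

        def _canon(key: str) -> str:
            if not key:
                return ""
            try:
                return canonicalize_range(key)
            except NormalizationError:
                logger.warning("reference key outside grammar kept verbatim: %r", key)
                return key

        rows.append(
            ReferenceRow(pmid=row.pmid, gene=row.gene, dna_key=_canon(dna), protein_key=_canon(prot))
        )
    return rows


def write_reference_db(rows: Sequence[ReferenceRow], path) -> None:
    pd.DataFrame(
        [
            {
                "pmid": r.pmid,
                "gene": r.gene,
                "dna_variant": r.dna_key,
                "protein_variant": r.protein_key,
            }
            for r in rows
        ],
        columns=REFERENCE_COLUMNS,
    ).to_csv(path, sep="\t", index=False)


def write_triples(triples: Iterable[CurationTriple], path) -> None:
    rows = sorted(
        {(t.doc_id, t.gene, k) for t in triples for k in (t.keys() or {""}) if k or t.gene}
    )
    pd.DataFrame(rows, columns=TRIPLE_COLUMNS).to_csv(path, sep="\t", index=False)


def read_triples(path) -> List[CurationTriple]:
    df = _read_tsv(Path(path), TRIPLE_COLUMNS)
    return [
        CurationTriple(doc_id=row.pmid, gene=row.gene, variant_key=row.variant_key)
        for row in df.itertuples(index=False)
    ]


def read_gene_dictionary_rows(path) -> List[Tuple[str, str]]:
    df = _read_tsv(Path(path), DICTIONARY_COLUMNS)
    return [(row.gene_symbol, row.synonym) for row in df.itertuples(index=False)]


def write_gene_dictionary_rows(rows: Sequence[Tuple[str, str]], path) -> None:
    pd.DataFrame(rows, columns=DICTIONARY_COLUMNS).to_csv(path, sep="\t", index=False)


def read_rsid_lookup(path) -> Dict[str, List[Tuple[str, str]]]:
    """rsID lookup TSV: rsid, level, key — one row per candidate variant."""
    df = _read_tsv(Path(path), RSID_COLUMNS)
    lookup: Dict[str, List[Tuple[str, str]]] = {}
    for row in df.itertuples(index=False):
        lookup.setdefault(row.rsid, []).append((row.level, row.key))
    return lookup


def write_rsid_lookup(lookup: Mapping[str, Sequence[Tuple[str, str]]], path) -> None:
    rows = [
        {"rsid": rsid, "level": level, "key": key}
        for rsid in sorted(lookup)
        for level, key in lookup[rsid]
    ]
    pd.DataFrame(rows, columns=RSID_COLUMNS).to_csv(path, sep="\t", index=False)


def load_config(path) -> dict:
    """Flat key-value configuration file (YAML mapping); CLI flags override."""
    with open(path, "r", encoding="utf-8") as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise FormatError(f"{path}: configuration must be a flat mapping")
    return cfg
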