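"""Combining the annotations of multiple recognizers.

Two combination levels:

* span level ("intrinsic"): overlapping mentions across recognizers are
  grouped into connected components of the span-overlap graph (transitively
  closed); a combination strategy keeps either every distinct span (union) or
  one representative member span per component (longest / shortest).
* normalized-key level ("extrinsic"): a plain per-document set union — the
  combination that raises curated-database coverage, since the recognizers
  have complementary scope.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Sequence, Set, Tuple

from .types import VariantMention

STRATEGIES = ("longest", "shortest", "union")


@dataclass(frozen=True)
class AnnotationSet:
    """One recognizer's (or combination's) mentions, sorted, non-overlapping
    within a document for single recognizers."""

    extractor_id: str
    mentions: Tuple[VariantMention, ...]

    @classmethod
    def from_mentions(
        cls, extractor_id: str, mentions: Iterable[VariantMention]
    ) -> "AnnotationSet":
        ordered = tuple(
            sorted(mentions, key=lambda m: (m.span.doc_id, m.span.start, m.span.end))
        )
        return cls(extractor_id=extractor_id, mentions=ordered)


def _components(
    items: List[Tuple[str, VariantMention]]
) -> List[List[Tuple[str, VariantMention]]]:
    """Connected components of the pairwise span-overlap graph, per document.

    Implemented by a sweep: after sorting by start, a component extends while
    the next span starts before the running maximum end (transitive closure of
    pairwise character overlap).
    """
    by_doc: Dict[str, List[Tuple[str, VariantMention]]] = {}
    for eid, m in items:
        by_doc.setdefault(m.span.doc_id, []).append((eid, m))
    components: List[List[Tuple[str, VariantMention]]] = []
    for doc_id in sorted(by_doc):
        group = sorted(by_doc[doc_id], key=lambda t: (t[1].span.start, t[1].span.end, t[0]))
        current: List[Tuple[str, VariantMention]] = []
        max_end = -1
        for eid, m in group:
            if current and m.span.start >= max_end:
                components.append(current)
                current = []
                max_end = -1
            current.append((eid, m))
            max_end = max(max_end, m.span.end)
        if current:
            components.append(current)
    return components


def merge_spans(
    sets: Sequence[AnnotationSet], strategy: str = "longest"
) -> AnnotationSet:
    """Merge span annotations across recognizers.

    ``longest`` / ``shortest`` keep, per overlap component, the member span of
    maximal / minimal length (not the hull); ties are broken by smaller start,
    then by lexicographically smaller extractor id. ``union`` keeps all
    distinct spans, deduplicating identical ones.
    """
    if not sets:
        raise ValueError("merge_spans requires at least one annotation set")
    if strategy not in STRATEGIES:
        raise ValueError(f"unknown strategy {strategy!r}; expected one of {STRATEGIES}")
    items = [(s.extractor_id, m) for s in sets for m in s.mentions]
    if strategy == "union":
        seen: Set[Tuple[str, int, int]] = set()
        kept: List[VariantMention] = []
        for eid, m in sorted(items, key=lambda t: (t[1].span.doc_id, t[1].span.start, t[1].span.end, t[0])):
            sig = (m.span.doc_id, m.span.start, m.span.end)
            if sig not in seen:
                seen.add(sig)
                kept.append(m)
        return AnnotationSet.from_mentions("combined_union", kept)
    sign = -1 if strategy == "longest" else 1
    kept = []
    for component in _components(items):
        eid, rep = min(
            component,
            key=lambda t: (
                sign * (t[1].span.end - t[1].span.start),
                t[1].span.start,
                t[0],
            ),
        )
        kept.append(rep)
    return AnnotationSet.from_mentions(f"combined_{strategy}", kept)


def merge_keys(per_extractor_keys: Iterable[Iterable[tuple]]) -> set:
    """Per-document key union across recognizers.

    Each element is a set of ``(doc_id, key)`` (or richer) tuples; the
    combination is their plain union, so combined coverage can never fall
    below any single recognizer's.
    """
    out: set = set()
    for keys in per_extractor_keys:
        out |= set(keys)
    return out
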