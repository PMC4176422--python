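"""Intrinsic (span-level) and extrinsic (curated-coverage) evaluation.

Span matching is a maximum one-to-one bipartite matching between predicted and
gold spans under the mode's compatibility relation — identical spans (exact)
or any character overlap (partial). A maximum matching makes the TP count
well-defined and independent of input order. Metrics follow the usual
definitions P = TP/(TP+FP), R = TP/(TP+FN), F1 = 2PR/(P+R); the character
overlap column is the mean character-level Jaccard over matched pairs (which
is exactly 100.00 in exact mode).

Coverage evaluation matches curated triples {PMID, gene, variant key}: a
reference row is recovered when the article matches, the extracted key equals
the row's DNA or protein key (either level counts), and — unless gene matching
is relaxed — the gene matches too.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Set, Tuple

import networkx as nx
import pandas as pd

from .extractors import classify_variant_type
from .types import CurationTriple, MentionSpan, ReferenceRow, VariantType

MODES = ("exact", "partial")


def _round4(x: float) -> float:
    return float(Decimal(repr(x)).quantize(Decimal("0.0001"), rounding=ROUND_HALF_UP))


def _round2(x: float) -> float:
    return float(Decimal(repr(x)).quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class MatchResult:
    mode: str
    pairs: Tuple[Tuple[MentionSpan, MentionSpan], ...]
    unmatched_pred: Tuple[MentionSpan, ...]
    unmatched_gold: Tuple[MentionSpan, ...]

    @property
    def tp(self) -> int:
        return len(self.pairs)

    @property
    def fp(self) -> int:
        return len(self.unmatched_pred)

    @property
    def fn(self) -> int:
        return len(self.unmatched_gold)


@dataclass(frozen=True)
class EvalReport:
    """Span-level scores; ratios reported rounded half-up to 4 decimals."""

    mode: str
    tp: int
    fp: int
    fn: int
    precision: float
    recall: float
    f1: float
    char_overlap_pct: float
    degenerate: bool = False  # all counts zero, or no matched pairs to average

    def to_dict(self) -> dict:
        return {
            "mode": self.mode,
            "tp": self.tp,
            "fp": self.fp,
            "fn": self.fn,
            "precision": self.precision,
            "recall": self.recall,
            "f1": self.f1,
            "char_overlap_pct": self.char_overlap_pct,
        }


@dataclass(frozen=True)
class CoverageReport:
    """Curated-database coverage: matched/total with and without the gene."""

    data_set: str
    total: int
    matched: int
    recall: float
    matched_no_gene: int
    recall_no_gene: float

    def to_dict(self) -> dict:
        return {
            "data_set": self.data_set,
            "total": self.total,
            "matched": self.matched,
            "recall": self.recall,
            "matched_no_gene": self.matched_no_gene,
            "recall_no_gene": self.recall_no_gene,
        }


def _compatible(pred: MentionSpan, gold: MentionSpan, mode: str) -> bool:
    if pred.doc_id != gold.doc_id:
        return False
    if mode == "exact":
        return pred.start == gold.start and pred.end == gold.end
    return pred.start < gold.end and gold.start < pred.end


def match_spans(
    pred: Sequence[MentionSpan], gold: Sequence[MentionSpan], mode: str = "exact"
) -> MatchResult:
    """Maximum one-to-one matching between predicted and gold spans."""
    if mode not in MODES:
        raise ValueError(f"unknown mode {mode!r}; expected one of {MODES}")
    graph = nx.Graph()
    p_nodes = [("p", i) for i in range(len(pred))]
    g_nodes = [("g", j) for j in range(len(gold))]
    graph.add_nodes_from(p_nodes, bipartite=0)
    graph.add_nodes_from(g_nodes, bipartite=1)
    for i, p in enumerate(pred):
        for j, g in enumerate(gold):
            if _compatible(p, g, mode):
                graph.add_edge(("p", i), ("g", j))
    matching = nx.bipartite.hopcroft_karp_matching(graph, top_nodes=p_nodes) if graph.edges else {}
    pairs = []
    matched_p, matched_g = set(), set()
    for i in range(len(pred)):
        partner = matching.get(("p", i))
        if partner is not None:
            j = partner[1]
            pairs.append((pred[i], gold[j]))
            matched_p.add(i)
            matched_g.add(j)
    return MatchResult(
        mode=mode,
        pairs=tuple(pairs),
        unmatched_pred=tuple(p for i, p in enumerate(pred) if i not in matched_p),
        unmatched_gold=tuple(g for j, g in enumerate(gold) if j not in matched_g),
    )


def _char_jaccard(a: MentionSpan, b: MentionSpan) -> float:
    inter = min(a.end, b.end) - max(a.start, b.start)
    union = max(a.end, b.end) - min(a.start, b.start)
    return inter / union if union else 0.0


def score_counts(
    tp: int, fp: int, fn: int, mode: str = "exact", char_overlap_pct: Optional[float] = None
) -> EvalReport:
    """Compute an EvalReport from raw counts.

    F1 is computed from the unrounded precision and recall; rounding half-up to
    4 decimals is applied only for reporting.
    """
    if min(tp, fp, fn) < 0:
        raise ValueError("counts must be non-negative")
    degenerate = tp == 0
    precision = tp / (tp + fp) if tp + fp else 0.0
    recall = tp / (tp + fn) if tp + fn else 0.0
    f1 = 2 * precision * recall / (precision + recall) if precision + recall else 0.0
    if char_overlap_pct is None:
        char_overlap_pct = 100.0 if (mode == "exact" and tp > 0) else 0.0
    return EvalReport(
        mode=mode,
        tp=tp,
        fp=fp,
        fn=fn,
        precision=_round4(precision),
        recall=_round4(recall),
        f1=_round4(f1),
        char_overlap_pct=_round2(char_overlap_pct),
        degenerate=degenerate,
    )


def score(result: MatchResult) -> EvalReport:
    """Score a span-matching result; exact mode reports 100.00 char overlap."""
    if result.mode == "exact":
        overlap = 100.0 if result.pairs else 0.0
    elif result.pairs:
        overlap = 100.0 * sum(_char_jaccard(p, g) for p, g in result.pairs) / len(result.pairs)
    else:
        overlap = 0.0
    return score_counts(
        result.tp, result.fp, result.fn, mode=result.mode, char_overlap_pct=overlap
    )


def evaluate_coverage(
    pred_triples: Iterable[CurationTriple],
    reference_rows: Sequence[ReferenceRow],
    relax_gene: bool = False,
    data_set: str = "all",
) -> CoverageReport:
    """Fraction of curated reference rows recovered by the extracted triples.

    Both the strict (gene must match) and gene-relaxed counts are reported;
    with ``relax_gene`` the headline matched/recall are the relaxed ones.
    """
    if not reference_rows:
        raise ValueError("empty reference set")
    # per-document index: key -> set of uppercased genes asserting that key
    by_doc: Dict[str, Dict[str, Set[str]]] = {}
    for t in pred_triples:
        index = by_doc.setdefault(t.doc_id, {})
        for key in t.keys():
            index.setdefault(key, set()).add(t.gene.upper() if t.gene else "")
    matched_strict = matched_relaxed = 0
    for row in reference_rows:
        index = by_doc.get(row.pmid, {})
        genes: Set[str] = set()
        hit = False
        for key in row.keys():
            if key in index:
                hit = True
                genes |= index[key]
        if hit:
            matched_relaxed += 1
            if row.gene.upper() in genes:
                matched_strict += 1
    total = len(reference_rows)
    matched = matched_relaxed if relax_gene else matched_strict
    return CoverageReport(
        data_set=data_set,
        total=total,
        matched=matched,
        recall=_round4(matched / total),
        matched_no_gene=matched_relaxed,
        recall_no_gene=_round4(matched_relaxed / total),
    )


def common_set_filter(
    docs: Iterable[str],
    pred_triples: Iterable[CurationTriple],
    reference_rows: Iterable[ReferenceRow],
) -> List[str]:
    """Documents with at least one extracted variant AND one reference row.

    Restricting coverage to this "common set" separates extraction misses from
    document-access misses.
    """
    have_pred = {t.doc_id for t in pred_triples if t.variant_key or t.alt_keys}
    have_ref = {r.pmid for r in reference_rows}
    return sorted(set(docs) & have_pred & have_ref)


def overlap_matrix(per_extractor_matched: Mapping[str, Set]) -> pd.DataFrame:
    """Pairwise overlap: cell (i, j) = |matched_i ∩ matched_j| / |matched_i|.

    The diagonal is 1.0 by convention; an extractor with an empty matched set
    gets a row of zeros and is flagged in ``df.attrs["empty_extractors"]``.
    """
    if len(per_extractor_matched) < 2:
        raise ValueError("overlap matrix needs at least two extractors")
    ids = sorted(per_extractor_matched)
    empty = [i for i in ids if not per_extractor_matched[i]]
    data = []
    for i in ids:
        mi = per_extractor_matched[i]
        row = []
        for j in ids:
            if i == j:
                row.append(1.0 if mi else 0.0)
            elif not mi:
                row.append(0.0)
            else:
                row.append(len(mi & per_extractor_matched[j]) / len(mi))
        data.append(row)
    df = pd.DataFrame(data, index=ids, columns=ids)
    df.attrs["empty_extractors"] = empty
    return df


def per_type_breakdown(
    key_pairs: Iterable[Tuple[Optional[str], Optional[str]]]
) -> pd.DataFrame:
    """Frequency table over (DNA variant type, protein variant type) pairs.

    Each reference row contributes one pair; an absent or untypeable key
    contributes UNKNOWN. Sorted by descending frequency.
    """
    counts: Dict[Tuple[str, str], int] = {}
    for dna_key, prot_key in key_pairs:
        dt = classify_variant_type(dna_key).value if dna_key else VariantType.UNKNOWN.value
        pt = classify_variant_type(prot_key).value if prot_key else VariantType.UNKNOWN.value
        counts[(dt, pt)] = counts.get((dt, pt), 0) + 1
    rows = [
        {"frequency": n, "dna_type": dt, "protein_type": pt}
        for (dt, pt), n in counts.items()
    ]
    df = pd.DataFrame(rows, columns=["frequency", "dna_type", "protein_type"])
    if len(df):
        df = df.sort_values(
            ["frequency", "dna_type", "protein_type"], ascending=[False, True, True]
        ).reset_index(drop=True)
    return df
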