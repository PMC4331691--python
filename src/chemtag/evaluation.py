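"""Micro-averaged scoring for the CDI and CEM subtasks.

CDI (chemical document indexing) scores the set of unique chemical strings
retrieved per document, case-sensitively.  CEM (chemical entity mention)
scores every mention by exact (section, start, end) span, class-blind.
Precision, recall and the balanced F-score (harmonic mean) are computed from
corpus-wide TP/FP/FN counts so that every annotated entity weighs equally;
a macro mode averages per-document scores instead.  Ranked average precision
follows the per-document definition: each correctly retrieved item
contributes its precision-at-rank, unretrieved gold items contribute zero,
and documents are pooled weighted by their gold counts.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass
from decimal import Decimal, ROUND_HALF_UP
from typing import Hashable, Iterable, Mapping, Sequence

from .corpus_io import Mention, PredictionItem
from .errors import ChemtagError
from .postprocess import FilterSet, clean_surface

__all__ = [
    "EvalResult",
    "round2",
    "fscore",
    "cdi_reduce",
    "cem_reduce",
    "micro_prf",
    "macro_prf",
    "average_precision",
    "union_merge",
]


def round2(x: float) -> float:
    """Round half-up to 2 decimals (reporting convention)."""
    return float(Decimal(repr(float(x))).quantize(Decimal("0.01"), ROUND_HALF_UP))


@dataclass(frozen=True)
class EvalResult:
    """TP/FP/FN counts with percentages rounded to 2 decimals."""

    tp: int
    fp: int
    fn: int
    precision: float
    recall: float
    fscore: float
    average_precision: float | None = None

    @classmethod
    def from_counts(
        cls, tp: int, fp: int, fn: int, average_precision: float | None = None
    ) -> "EvalResult":
        p = 100.0 * tp / (tp + fp) if tp + fp else 0.0
        r = 100.0 * tp / (tp + fn) if tp + fn else 0.0
        f = 2 * p * r / (p + r) if p + r else 0.0
        ap = round2(average_precision) if average_precision is not None else None
        return cls(tp, fp, fn, round2(p), round2(r), round2(f), ap)


def fscore(p: float, r: float) -> float:
    """Balanced F-score (harmonic mean of precision and recall, both in %)."""
    if not (0 <= p <= 100 and 0 <= r <= 100):
        raise ValueError("precision and recall must be percentages in [0, 100]")
    if p + r == 0:
        return 0.0
    return round2(2 * p * r / (p + r))


def cdi_reduce(mentions: Iterable[Mention]) -> set[tuple[str, str]]:
    """Unique (doc_id, surface) pairs; exact, case-sensitive strings."""
    return {(m.doc_id, m.surface) for m in mentions}


def cem_reduce(mentions: Iterable[Mention]) -> set[tuple[str, str, int, int]]:
    """Unique (doc_id, section, start, end) span keys, class-blind."""
    return {(m.doc_id, m.section, m.start, m.end) for m in mentions}


def micro_prf(gold: set, pred: set) -> EvalResult:
    """Corpus-wide set comparison: tp = |gold & pred| etc."""
    tp = len(gold & pred)
    return EvalResult.from_counts(tp, len(pred) - tp, len(gold) - tp)


def macro_prf(
    gold_by_doc: Mapping[str, set], pred_by_doc: Mapping[str, set]
) -> tuple[float, float, float]:
    """Unweighted mean of per-document P/R/F over the union of documents."""
    docs = sorted(set(gold_by_doc) | set(pred_by_doc))
    if not docs:
        return 0.0, 0.0, 0.0
    ps, rs, fs = [], [], []
    for d in docs:
        res = micro_prf(gold_by_doc.get(d, set()), pred_by_doc.get(d, set()))
        ps.append(res.precision)
        rs.append(res.recall)
        fs.append(res.fscore)
    n = len(docs)
    return round2(sum(ps) / n), round2(sum(rs) / n), round2(sum(fs) / n)


def average_precision(
    ranked_pred: Sequence[tuple[str, Hashable]], gold: set
) -> float:
    """Ranked retrieval quality in percent.

    ``ranked_pred`` lists (doc_id, item_key) pairs; within each document the
    listed order is the rank order (descending confidence).  Per document,
    AP = mean over gold items of the precision at the rank where each was
    retrieved (0 for unretrieved gold); the corpus value weighs every gold
    item equally.
    """
    gold_by_doc: dict[str, set] = defaultdict(set)
    for doc_id, key in gold:
        gold_by_doc[doc_id].add(key)
    ranked_by_doc: dict[str, list] = defaultdict(list)
    for doc_id, key in ranked_pred:
        ranked_by_doc[doc_id].append(key)
    total_gold = sum(len(v) for v in gold_by_doc.values())
    if total_gold == 0:
        return 0.0
    weighted = 0.0
    for doc_id, gold_keys in gold_by_doc.items():
        hits = 0
        ap_sum = 0.0
        for rank, key in enumerate(ranked_by_doc.get(doc_id, ()), 1):
            if key in gold_keys:
                hits += 1
                ap_sum += hits / rank
        weighted += ap_sum  # each gold item contributes ap/|gold_doc| * |gold_doc|
    return round2(100.0 * weighted / total_gold)


def union_merge(
    prediction_sets: Sequence[Sequence[PredictionItem]],
    filters: FilterSet | None = None,
) -> dict[tuple, float]:
    """Ensemble union of prediction files from several taggers.

    Each input set is individually passed through the post-processing
    pipeline (for CDI items the surface string is cleaned; items whose
    surface is rejected disappear), then the sets are unioned with
    confidences combined by maximum.  Keys of the result are
    ``(doc_id, surface)`` for CDI or ``(doc_id, section, start, end)`` for
    CEM.  Mixing CDI and CEM inputs is an error.
    """
    if filters is None:
        filters = FilterSet()
    tasks = {item.task for items in prediction_sets for item in items}
    if len(tasks) > 1:
        raise ChemtagError(f"mixed CDI/CEM prediction inputs: {sorted(tasks)}")
    merged: dict[tuple, float] = {}
    for items in prediction_sets:
        for item in items:
            if item.task == "CDI":
                surface = clean_surface(item.key[0], filters)
                if surface is None:
                    continue
                key = (item.doc_id, surface)
            else:
                key = (item.doc_id, *item.key)
            merged[key] = max(merged.get(key, 0.0), item.confidence)
    return merged
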