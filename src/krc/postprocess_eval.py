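"""Document-level merging, fallback heuristics, and P/R/F1 evaluation.

Instance decisions for the same (document, head, tail) triple are merged
disjunctively: the pair is positive if any instance (intra- or
inter-sentential) was judged positive.  Documents that produced no candidate
instances at all fall back to the cross-product heuristic: every chemical in
the title is paired with every disease in the abstract.  Evaluation compares
predicted positive concept-ID pairs against gold pairs per document, overall
and restricted to the intra/inter levels.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping

from .corpus_io import Document, UNRESOLVED_ID
from .train_predict import PairPrediction

DOCUMENT, FALLBACK = "document", "fallback"


def merge_predictions(instance_decisions: Iterable[PairPrediction],
                      ) -> list[PairPrediction]:
    """One record per (doc, head, tail): positive iff any decision is
    positive; provenance joins the levels that fired (or that exist, for
    all-negative pairs)."""
    grouped: dict[tuple[str, str, str], list[PairPrediction]] = {}
    for d in instance_decisions:
        grouped.setdefault((d.doc_id, d.head_id, d.tail_id), []).append(d)
    merged = []
    for (doc_id, head, tail), ds in grouped.items():
        positive = any(d.positive for d in ds)
        levels = sorted({d.provenance for d in ds
                         if d.positive or not positive})
        merged.append(PairPrediction(doc_id, head, tail, positive,
                                     "+".join(levels)))
    merged.sort(key=lambda p: (p.doc_id, p.head_id, p.tail_id))
    return merged


def apply_fallback(docs: Iterable[Document],
                   merged: list[PairPrediction],
                   candidate_counts: Mapping[str, int],
                   ) -> list[PairPrediction]:
    """Add title-chemical x abstract-disease positives for documents with
    zero candidate instances after preprocessing; never removes a pair."""
    out = list(merged)
    have = {(p.doc_id, p.head_id, p.tail_id) for p in merged}
    for doc in docs:
        if candidate_counts.get(doc.doc_id, 0) > 0:
            continue
        title_end = len(doc.title)
        title_chems = {m.concept_id for m in doc.mentions
                       if m.etype == "chemical" and m.start < title_end
                       and m.concept_id != UNRESOLVED_ID}
        abstract_dis = {m.concept_id for m in doc.mentions
                        if m.etype == "disease" and m.start >= title_end
                        and m.concept_id != UNRESOLVED_ID}
        for c in sorted(title_chems):
            for d in sorted(abstract_dis):
                if (doc.doc_id, c, d) not in have:
                    out.append(PairPrediction(doc.doc_id, c, d, True,
                                              FALLBACK))
                    have.add((doc.doc_id, c, d))
    return out


@dataclass(frozen=True)
class LevelMetrics:
    tp: int
    fp: int
    fn: int

    @property
    def precision(self) -> float:
        return self.tp / (self.tp + self.fp) if (self.tp + self.fp) else 0.0

    @property
    def recall(self) -> float:
        return self.tp / (self.tp + self.fn) if (self.tp + self.fn) else 0.0

    @property
    def f1(self) -> float:
        p, r = self.precision, self.recall
        return 2 * p * r / (p + r) if (p + r) else 0.0

    def as_dict(self) -> dict:
        return {"tp": self.tp, "fp": self.fp, "fn": self.fn,
                "precision": self.precision, "recall": self.recall,
                "f1": self.f1}


@dataclass(frozen=True)
class EvalReport:
    document: LevelMetrics
    intra: LevelMetrics
    inter: LevelMetrics

    def as_dict(self) -> dict:
        return {lvl: getattr(self, lvl).as_dict()
                for lvl in ("document", "intra", "inter")}


def _score(pred: set, gold: set) -> LevelMetrics:
    tp = len(pred & gold)
    return LevelMetrics(tp=tp, fp=len(pred) - tp, fn=len(gold) - tp)


def evaluate(predictions: Iterable[PairPrediction],
             gold_pairs: Iterable[tuple[str, str, str]],
             level_map: Mapping[tuple[str, str, str], str] | None = None,
             ) -> EvalReport:
    """Set comparison of positive predictions vs gold (doc, head, tail)
    triples; intra/inter metrics restrict both sides to pairs whose
    candidate level matches.

    ``gold_pairs`` holds (doc_id, head_id, tail_id); ``level_map`` maps such
    triples to "intra"/"inter" per their candidate instances.
    """
    gold_list = list(gold_pairs)
    gold = set(gold_list)
    if len(gold_list) != len(gold):
        warnings.warn("duplicate gold pairs collapsed", stacklevel=2)
    pred = {(p.doc_id, p.head_id, p.tail_id)
            for p in predictions if p.positive}
    level_map = level_map or {}

    report = {"document": _score(pred, gold)}
    for lvl in ("intra", "inter"):
        keys = {k for k, v in level_map.items() if v == lvl}
        report[lvl] = _score(pred & keys, gold & keys)
    return EvalReport(**report)


__all__ = ["merge_predictions", "apply_fallback", "evaluate",
           "LevelMetrics", "EvalReport", "PairPrediction"]
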