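"""Turn annotated documents into reading-comprehension instances.

Each candidate (head chemical, tail entity) pair becomes a question/context
instance: the context is the containing sentence (intra-sentential) or the
sentence window spanning the closest mention pair (inter-sentential, sentence
distance 1..3); other tail-type mentions are masked; the query asks for the
tail entity; the gold answer is the earliest unmasked tail mention, or null
for negative pairs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterable

from .corpus_io import ConceptHierarchy, Document, Mention, UNRESOLVED_ID

MASK_TOKEN = "UNK"

INTRA = "intra"
INTER = "inter"

NATURAL_TEMPLATES = {
    "disease": "what disease does {head} {relation}",
    "chemical": "what chemical does {head} {relation}",
}


@dataclass
class CandidateInstance:
    """One (chemical, target) pair rendered as a span-extraction question."""

    doc_id: str
    head_id: str
    tail_id: str
    level: str                       # "intra" or "inter"
    sentence_window: tuple[int, int]  # [first, last] sentence indices
    distance: int                    # minimal sentence distance (0 for intra)
    context: str = ""
    # (masked_start, masked_end, doc_start, doc_end) for unmasked segments
    offset_map: list[tuple[int, int, int, int]] = field(default_factory=list)
    query: str = ""
    answer_start: int | None = None  # char offsets into context; None = null
    answer_end: int | None = None
    label: bool = False

    @property
    def is_null(self) -> bool:
        return self.answer_start is None

    def to_document_span(self, start: int, end: int) -> tuple[int, int] | None:
        """Map a context char span back to document offsets, or None if it
        crosses a masked region."""
        for ms, me, ds, de in self.offset_map:
            if ms <= start and end <= me:
                return ds + (start - ms), ds + (end - ms)
        return None


# ---------------------------------------------------------------------------
# Candidate extraction

def _mention_pairs(doc: Document, head_type: str, tail_type: str):
    heads = [m for m in doc.mentions
             if m.etype == head_type and m.concept_id != UNRESOLVED_ID]
    tails = [m for m in doc.mentions
             if m.etype == tail_type and m.concept_id != UNRESOLVED_ID]
    pairs: dict[tuple[str, str], list[tuple[Mention, Mention]]] = {}
    for h in heads:
        for t in tails:
            if head_type == tail_type and h.concept_id == t.concept_id:
                continue
            pairs.setdefault((h.concept_id, t.concept_id), []).append((h, t))
    return pairs


def extract_candidates(doc: Document, max_inter_distance: int = 3,
                       head_type: str = "chemical",
                       tail_type: str = "disease",
                       full_document_context: bool = False,
                       ) -> list[CandidateInstance]:
    """Enumerate candidate pairs with intra/inter level and context window.

    A pair whose mentions co-occur in some sentence is intra-sentential (the
    earliest such sentence is the context); otherwise, if the minimal
    sentence distance between a head and a tail mention is within
    ``max_inter_distance``, the pair is inter-sentential with the window
    spanning the closest mention pair.  Intra pairs are never also emitted
    as inter.  With ``full_document_context`` (the chemical-reaction task
    convention) the context window is the whole title+abstract and no
    distance cut is applied.
    """
    if not doc.sentences:
        raise ValueError(f"{doc.doc_id}: sentences not populated")
    out: list[CandidateInstance] = []
    for (head_id, tail_id), mpairs in _mention_pairs(
            doc, head_type, tail_type).items():
        best: tuple | None = None  # (distance, h.start, t.start, si, sj)
        for h, t in mpairs:
            si = doc.sentence_index(h.start)
            sj = doc.sentence_index(t.start)
            key = (abs(si - sj), h.start, t.start, si, sj)
            if best is None or key < best:
                best = key
        dist = best[0]
        if full_document_context:
            window = (0, len(doc.sentences) - 1)
            level = INTRA if dist == 0 else INTER
        elif dist == 0:
            # earliest sentence containing both mentions
            co = min(s for h, t in mpairs
                     for s in [doc.sentence_index(h.start)]
                     if doc.sentence_index(t.start) == s)
            window, level = (co, co), INTRA
        elif dist <= max_inter_distance:
            si, sj = best[3], best[4]
            window, level = (min(si, sj), max(si, sj)), INTER
        else:
            continue
        out.append(CandidateInstance(
            doc_id=doc.doc_id, head_id=head_id, tail_id=tail_id,
            level=level, sentence_window=window, distance=dist,
            label=_is_gold(doc, head_id, tail_id)))
    out.sort(key=lambda c: (c.head_id, c.tail_id))
    return out


def _is_gold(doc: Document, head_id: str, tail_id: str) -> bool:
    return any(h == head_id and t == tail_id
               for h, t, _rel in doc.gold_pairs)


# ---------------------------------------------------------------------------
# Masking

def mask_context(doc: Document, candidate: CandidateInstance,
                 mask_token: str = MASK_TOKEN,
                 tail_type: str = "disease",
                 mask_other_tails: bool = True) -> CandidateInstance:
    """Build the masked context string and the offset map.

    Every tail-type mention whose concept differs from both the candidate's
    tail (and, for same-type tasks, its head) is replaced by ``mask_token``.
    The offset map records, for each unmasked segment, its span in the masked
    context and in the document, so predicted spans can be mapped back.
    """
    first, last = candidate.sentence_window
    win_start = doc.sentences[first][0]
    win_end = doc.sentences[last][1]
    text = doc.text

    to_mask: list[tuple[int, int]] = []
    if mask_other_tails:
        keep = {candidate.tail_id, candidate.head_id}
        masked_ids = set()
        for m in doc.mentions:
            if (m.etype == tail_type and m.concept_id not in keep
                    and not (win_start > m.start or m.end > win_end)):
                masked_ids.add((m.start, m.end))
        # composite mentions share spans; mask a span only if no kept concept
        # is annotated on it
        kept_spans = {(m.start, m.end) for m in doc.mentions
                      if m.etype == tail_type and m.concept_id in keep}
        to_mask = sorted(masked_ids - kept_spans)

    pieces: list[str] = []
    offset_map: list[tuple[int, int, int, int]] = []
    pos = win_start
    out_pos = 0
    for ms, me in to_mask:
        if pos < ms:
            seg = text[pos:ms]
            pieces.append(seg)
            offset_map.append((out_pos, out_pos + len(seg), pos, ms))
            out_pos += len(seg)
        pieces.append(mask_token)
        out_pos += len(mask_token)
        pos = me
    if pos < win_end:
        seg = text[pos:win_end]
        pieces.append(seg)
        offset_map.append((out_pos, out_pos + len(seg), pos, win_end))

    candidate.context = "".join(pieces)
    candidate.offset_map = offset_map
    return candidate


def unmasked_tail_spans(doc: Document, candidate: CandidateInstance,
                        ) -> list[tuple[int, int]]:
    """Context char spans of the candidate's tail mentions, in order."""
    spans = []
    for m in doc.mentions:
        if m.concept_id != candidate.tail_id:
            continue
        for ms, me, ds, de in candidate.offset_map:
            if ds <= m.start and m.end <= de:
                off = ms + (m.start - ds)
                spans.append((off, off + (m.end - m.start)))
                break
    return sorted(spans)


# ---------------------------------------------------------------------------
# Hypernym filtering

def filter_hypernyms(candidates: Iterable[CandidateInstance],
                     hierarchy: ConceptHierarchy,
                     doc: Document) -> list[CandidateInstance]:
    """Drop candidates whose head or tail is an ancestor of a more specific
    same-type concept mentioned in the same document."""
    present: dict[str, set[str]] = {}
    for m in doc.mentions:
        if m.concept_id != UNRESOLVED_ID:
            present.setdefault(m.etype, set()).add(m.concept_id)
    type_of = {m.concept_id: m.etype for m in doc.mentions}

    def is_hyper(concept_id: str) -> bool:
        etype = type_of.get(concept_id)
        if etype is None:
            return False
        others = present.get(etype, set()) - {concept_id}
        return any(hierarchy.is_ancestor(concept_id, o) for o in others)

    return [c for c in candidates
            if not is_hyper(c.head_id) and not is_hyper(c.tail_id)]


# ---------------------------------------------------------------------------
# Query construction & answers

def build_query(head_mention_text: str, relation_description: str,
                tail_type: str, style: str = "natural") -> str:
    """Render the question for a candidate head entity and relation.

    ``natural`` fills a per-task template ("what disease does X induce");
    ``pseudo`` concatenates head text, relation description and tail type.
    """
    if not head_mention_text:
        raise ValueError("empty head mention text")
    if style == "natural":
        template = NATURAL_TEMPLATES.get(tail_type)
        if template is None:
            raise ValueError(f"no natural template for tail type {tail_type!r}")
        return template.format(head=head_mention_text,
                               relation=relation_description)
    if style == "pseudo":
        return " ".join([head_mention_text, relation_description, tail_type])
    raise ValueError(f"unknown query style {style!r}")


def assign_answer(candidate: CandidateInstance, doc: Document,
                  ) -> CandidateInstance:
    """Attach the gold answer: earliest unmasked tail mention for positive
    pairs, the null marker otherwise."""
    if candidate.label:
        spans = unmasked_tail_spans(doc, candidate)
        if not spans:
            raise RuntimeError(
                f"{doc.doc_id}: positive candidate ({candidate.head_id}, "
                f"{candidate.tail_id}) has no tail mention in context")
        candidate.answer_start, candidate.answer_end = spans[0]
    else:
        candidate.answer_start = candidate.answer_end = None
    return candidate


# ---------------------------------------------------------------------------
# Pipeline & serialization

def build_instances(doc: Document, relation_description: str = "induce",
                    query_style: str = "natural",
                    max_inter_distance: int = 3,
                    head_type: str = "chemical",
                    tail_type: str = "disease",
                    hierarchy: ConceptHierarchy | None = None,
                    mask_token: str = MASK_TOKEN,
                    mask_other_tails: bool = True,
                    full_document_context: bool = False,
                    ) -> list[CandidateInstance]:
    """Full preprocessing for one document: candidates, hypernym filter,
    masking, query construction and gold-answer assignment."""
    cands = extract_candidates(
        doc, max_inter_distance=max_inter_distance, head_type=head_type,
        tail_type=tail_type, full_document_context=full_document_context)
    if hierarchy is not None:
        cands = filter_hypernyms(cands, hierarchy, doc)
    head_texts = {m.concept_id: m.text for m in reversed(doc.mentions)
                  if m.etype == head_type}
    for c in cands:
        mask_context(doc, c, mask_token=mask_token, tail_type=tail_type,
                     mask_other_tails=mask_other_tails)
        c.query = build_query(head_texts[c.head_id], relation_description,
                              tail_type, style=query_style)
        assign_answer(c, doc)
    return cands


def instances_to_squad(instances: Iterable[CandidateInstance]) -> dict:
    """Serialize instances as SQuAD-v2-style JSON (is_impossible for null)."""
    paragraphs = []
    for c in instances:
        answers = [] if c.is_null else [{
            "text": c.context[c.answer_start:c.answer_end],
            "answer_start": c.answer_start,
        }]
        paragraphs.append({
            "context": c.context,
            "qas": [{
                "id": f"{c.doc_id}:{c.head_id}:{c.tail_id}",
                "question": c.query,
                "answers": answers,
                "is_impossible": c.is_null,
                "level": c.level,
            }],
        })
    return {"version": "v2.0", "data": [{"title": "", "paragraphs": paragraphs}]}


def write_squad_json(instances: Iterable[CandidateInstance], path) -> None:
    with open(path, "w") as fh:
        json.dump(instances_to_squad(instances), fh, indent=1)


__all__ = [
    "CandidateInstance", "extract_candidates", "mask_context",
    "filter_hypernyms", "build_query", "assign_answer", "build_instances",
    "unmasked_tail_spans", "instances_to_squad", "write_squad_json",
    "MASK_TOKEN", "INTRA", "INTER",
]
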