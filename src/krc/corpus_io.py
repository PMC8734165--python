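"""PubTator corpus reading/writing and the in-memory document model.

A document is the concatenation ``title + "\n" + abstract`` and all mention
offsets are 0-based half-open character offsets into that string, counted
continuously across the title boundary (the PubTator convention used by the
BioCreative V CDR distribution).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, TextIO

ENTITY_TYPES = ("chemical", "disease")
UNRESOLVED_ID = "-1"

#: Abbreviations after which a period never ends a sentence.
DEFAULT_ABBREVIATIONS = (
    "i.e.", "e.g.", "etc.", "vs.", "cf.", "al.", "fig.", "dr.", "mg.", "no.",
)


class PubTatorError(ValueError):
    """Raised when a corpus block fails validation."""


@dataclass(frozen=True)
class Mention:
    """An offset-anchored entity mention carrying a concept identifier."""

    start: int
    end: int
    text: str
    etype: str          # "chemical" or "disease"
    concept_id: str     # e.g. a MeSH ID; "-1" marks an unresolved mention

    def overlaps(self, start: int, end: int) -> bool:
        return self.start < end and start < self.end


@dataclass
class Document:
    doc_id: str
    title: str
    abstract: str
    mentions: list[Mention] = field(default_factory=list)
    gold_pairs: set[tuple[str, str, str]] = field(default_factory=set)
    sentences: list[tuple[int, int]] = field(default_factory=list)

    @property
    def text(self) -> str:
        return self.title + "\n" + self.abstract

    def validate(self) -> None:
        n = len(self.text)
        for m in self.mentions:
            if not (0 <= m.start < m.end <= n):
                raise PubTatorError(
                    f"{self.doc_id}: mention offsets [{m.start},{m.end}) "
                    f"outside text of length {n}")
            actual = self.text[m.start:m.end]
            if actual != m.text:
                raise PubTatorError(
                    f"{self.doc_id}: mention text {m.text!r} does not match "
                    f"document substring {actual!r} at [{m.start},{m.end})")
            if m.etype not in ENTITY_TYPES:
                raise PubTatorError(
                    f"{self.doc_id}: unknown entity type {m.etype!r}")

    def sentence_index(self, offset: int) -> int:
        """Index of the sentence span containing character ``offset``."""
        for i, (s, e) in enumerate(self.sentences):
            if s <= offset < e:
                return i
        raise ValueError(f"offset {offset} not inside any sentence span")

    def concept_ids(self, etype: str) -> list[str]:
        """Distinct resolvable concept IDs of a type, in order of appearance."""
        seen: list[str] = []
        for m in self.mentions:
            if m.etype == etype and m.concept_id != UNRESOLVED_ID \
                    and m.concept_id not in seen:
                seen.append(m.concept_id)
        return seen


@dataclass(frozen=True)
class ConceptHierarchy:
    """Parent→child concept edges with transitive ancestor queries."""

    edges: frozenset[tuple[str, str]]

    def __post_init__(self):
        children: dict[str, list[str]] = {}
        for p, c in self.edges:
            children.setdefault(p, []).append(c)
        # cycle check by DFS colouring
        colour: dict[str, int] = {}
        def visit(node: str, stack: tuple) -> None:
            if node in stack:
                raise ValueError(f"hierarchy contains a cycle through {node!r}")
            if colour.get(node):
                return
            colour[node] = 1
            for ch in children.get(node, ()):
                visit(ch, stack + (node,))
        for p in children:
            visit(p, ())
        object.__setattr__(self, "_children", children)

    def descendants(self, concept_id: str) -> set[str]:
        out: set[str] = set()
        stack = list(self._children.get(concept_id, ()))
        while stack:
            node = stack.pop()
            if node not in out:
                out.add(node)
                stack.extend(self._children.get(node, ()))
        return out

    def is_ancestor(self, ancestor: str, descendant: str) -> bool:
        return descendant in self.descendants(ancestor)


# ---------------------------------------------------------------------------
# PubTator format

def read_pubtator(stream: TextIO | Iterable[str]) -> list[Document]:
    """Parse a PubTator stream into validated documents.

    Blocks are ``<id>|t|<title>`` and ``<id>|a|<abstract>`` lines followed by
    tab-separated mention lines (id, start, end, text, type, concept_id) and
    relation lines (id, relation, id1, id2), separated by blank lines.
    Composite concept annotations (pipe-joined IDs) are expanded into one
    mention per ID over the same span.
    """
    docs: list[Document] = []
    current: Document | None = None

    def flush():
        nonlocal current
        if current is not None:
            current.validate()
            docs.append(current)
            current = None

    for lineno, raw in enumerate(stream, start=1):
        line = raw.rstrip("\n")
        if not line.strip():
            flush()
            continue
        if "|t|" in line or "|a|" in line:
            doc_id, kind, text = line.split("|", 2)
            if current is None or current.doc_id != doc_id:
                flush()
                current = Document(doc_id=doc_id, title="", abstract="")
            if kind == "t":
                current.title = text
            else:
                current.abstract = text
            continue
        fields = line.split("\t")
        if current is None or fields[0] != current.doc_id:
            raise PubTatorError(f"line {lineno}: annotation outside a block")
        if len(fields) == 4:
            _, relation, id1, id2 = fields
            current.gold_pairs.add((id1, id2, relation))
        elif len(fields) >= 6:
            _, start, end, text, etype, concept = fields[:6]
            try:
                s, e = int(start), int(end)
            except ValueError as exc:
                raise PubTatorError(f"line {lineno}: bad offsets") from exc
            etype_l = etype.lower()
            if etype_l not in ENTITY_TYPES:
                raise PubTatorError(
                    f"line {lineno}: unknown entity type {etype!r} "
                    f"in document {current.doc_id}")
            for cid in concept.split("|"):
                current.mentions.append(
                    Mention(start=s, end=e, text=text, etype=etype_l,
                            concept_id=cid))
        else:
            raise PubTatorError(f"line {lineno}: unparseable line {line!r}")
    flush()
    return docs


def write_pubtator(docs: Iterable[Document]) -> str:
    """Serialize documents back to PubTator text (inverse of read)."""
    blocks: list[str] = []
    for doc in docs:
        lines = [f"{doc.doc_id}|t|{doc.title}", f"{doc.doc_id}|a|{doc.abstract}"]
        # re-merge composite mentions that share a span and type
        grouped: dict[tuple[int, int, str, str], list[str]] = {}
        for m in doc.mentions:
            grouped.setdefault((m.start, m.end, m.text, m.etype), []).append(
                m.concept_id)
        for (s, e, text, etype), cids in grouped.items():
            lines.append(f"{doc.doc_id}\t{s}\t{e}\t{text}\t"
                         f"{etype.capitalize()}\t{'|'.join(cids)}")
        for id1, id2, rel in sorted(doc.gold_pairs,
                                    key=lambda p: (p[2], p[0], p[1])):
            lines.append(f"{doc.doc_id}\t{rel}\t{id1}\t{id2}")
        blocks.append("\n".join(lines))
    return "\n\n".join(blocks) + ("\n" if blocks else "")


def read_hierarchy(stream: TextIO | Iterable[str]) -> ConceptHierarchy:
    """Read a 2-column TSV (parent_id, child_id) concept hierarchy."""
    edges = set()
    for line in stream:
        line = line.strip()
        if not line:
            continue
        parent, child = line.split("\t")
        edges.add((parent, child))
    return ConceptHierarchy(edges=frozenset(edges))


def write_hierarchy(hierarchy: ConceptHierarchy) -> str:
    return "".join(f"{p}\t{c}\n" for p, c in sorted(hierarchy.edges))


# ---------------------------------------------------------------------------
# Sentence segmentation

_TERMINATOR_RE = re.compile(r"[.!?]+(?=\s|$)")


def split_sentences(doc: Document,
                    abbreviations: Iterable[str] = DEFAULT_ABBREVIATIONS,
                    ) -> Document:
    """Populate sentence spans: the title is one sentence; the abstract is
    split at sentence-final punctuation followed by whitespace, with an
    abbreviation guard.  Boundaries are moved so no mention straddles one.
    """
    if not doc.title:
        raise ValueError(f"{doc.doc_id}: empty title")
    text = doc.text
    offset0 = len(doc.title) + 1  # abstract start in document text
    abbrevs = tuple(a.lower() for a in abbreviations)

    boundaries: list[int] = []
    for match in _TERMINATOR_RE.finditer(doc.abstract):
        end = match.end()
        prefix = doc.abstract[:end].lower()
        if any(prefix.endswith(a) for a in abbrevs):
            continue
        boundaries.append(offset0 + end)

    # drop boundaries that would split a mention
    def splits_mention(b: int) -> bool:
        return any(m.start < b < m.end for m in doc.mentions)

    boundaries = [b for b in boundaries if not splits_mention(b)]

    spans: list[tuple[int, int]] = [(0, len(doc.title))]
    prev = offset0
    for b in boundaries:
        if b > prev:
            spans.append((prev, b))
            prev = b
    if prev < len(text):
        spans.append((prev, len(text)))

    # trim leading whitespace from each abstract sentence
    trimmed = [spans[0]]
    for s, e in spans[1:]:
        while s < e and text[s].isspace():
            s += 1
        if s < e:
            trimmed.append((s, e))
    doc.sentences = trimmed
    return doc


def segment_corpus(docs: Iterable[Document], **kwargs) -> list[Document]:
    return [split_sentences(d, **kwargs) for d in docs]


__all__ = [
    "Mention", "Document", "ConceptHierarchy", "PubTatorError",
    "read_pubtator", "write_pubtator", "read_hierarchy", "write_hierarchy",
    "split_sentences", "segment_corpus", "ENTITY_TYPES", "UNRESOLVED_ID",
    "DEFAULT_ABBREVIATIONS",
]
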