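"""Knowledge-base triples and translation-based (TransE) embeddings.

Triples are (head concept, relation label, tail concept).  For the
chemical-induced disease task the closed label set is marker/mechanism,
therapeutic, inferred-association, plus the reserved label ``null`` assigned
to corpus pairs absent from the knowledge base.  TransE scores a triple by
the translation energy ||h + r - t||_2 and is trained with a margin ranking
loss against uniformly corrupted negatives.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

NULL_RELATION = "null"
CID_RELATIONS = ("inferred-association", "marker/mechanism", "therapeutic")
POSITIVE_RELATION = "marker/mechanism"  # the label indicating induction


@dataclass(frozen=True)
class KBTriple:
    head_id: str
    relation: str
    tail_id: str


def read_triples(stream) -> list[KBTriple]:
    """Read a 3-column TSV (head_id, relation, tail_id)."""
    out = []
    for line in stream:
        line = line.rstrip("\n")
        if not line:
            continue
        head, relation, tail = line.split("\t")
        out.append(KBTriple(head, relation, tail))
    return out


def write_triples(triples: Iterable[KBTriple]) -> str:
    return "".join(f"{t.head_id}\t{t.relation}\t{t.tail_id}\n"
                   for t in triples)


def assemble_triples(corpus_pairs: Iterable[tuple[str, str]],
                     kb_triples: Iterable[KBTriple]) -> list[KBTriple]:
    """Union of knowledge-base triples with ``null``-labelled triples for
    corpus candidate pairs the knowledge base does not cover."""
    kb = list(dict.fromkeys(kb_triples))
    covered = {(t.head_id, t.tail_id) for t in kb}
    extra = [KBTriple(h, NULL_RELATION, t)
             for h, t in dict.fromkeys(corpus_pairs)
             if (h, t) not in covered]
    return kb + extra


@dataclass
class KnowledgeEmbeddings:
    """Entity and relation vectors of a shared dimension ``d2``."""

    entity_vectors: dict[str, np.ndarray]
    relation_vectors: dict[str, np.ndarray]
    d2: int

    def energy(self, head_id: str, relation: str, tail_id: str) -> float:
        """Translation energy ||h + r - t||_2 of a triple."""
        h = self.entity_vectors[head_id]
        r = self.relation_vectors[relation]
        t = self.entity_vectors[tail_id]
        return float(np.linalg.norm(h + r - t))

    def save_tsv(self, path) -> None:
        with open(path, "w") as fh:
            for kind, table in (("entity", self.entity_vectors),
                                ("relation", self.relation_vectors)):
                for name, vec in table.items():
                    vals = "\t".join(repr(float(v)) for v in vec)
                    fh.write(f"{kind}\t{name}\t{vals}\n")

    @classmethod
    def load_tsv(cls, path) -> "KnowledgeEmbeddings":
        ent: dict[str, np.ndarray] = {}
        rel: dict[str, np.ndarray] = {}
        with open(path) as fh:
            for line in fh:
                kind, name, *vals = line.rstrip("\n").split("\t")
                vec = np.array([float(v) for v in vals])
                (ent if kind == "entity" else rel)[name] = vec
        d2 = len(next(iter(ent.values())))
        return cls(entity_vectors=ent, relation_vectors=rel, d2=d2)


def train_transe(triples: Sequence[KBTriple], d2: int = 256,
                 epochs: int = 1000, margin: float = 1.0,
                 learning_rate: float = 0.01, seed: int = 0,
                 track_loss: bool = False,
                 ) -> KnowledgeEmbeddings | tuple[KnowledgeEmbeddings, list[float]]:
    """Learn TransE embeddings by seeded stochastic gradient descent.

    Each epoch corrupts every triple once (head or tail, Bernoulli-0.5,
    uniform replacement entity) and takes a gradient step on the margin
    ranking loss max(0, margin + E(pos) - E(neg)) with E the L2 translation
    energy.  Entity vectors are renormalised to unit norm at the start of
    every epoch.  With ``track_loss`` the margin loss is also evaluated after
    each epoch on a corruption sample fixed up front, giving a loss curve
    for a constant objective.
    """
    triples = list(triples)
    if not triples:
        raise ValueError("empty triple set")
    rng = np.random.default_rng(seed)
    entities = sorted({t.head_id for t in triples}
                      | {t.tail_id for t in triples})
    relations = sorted({t.relation for t in triples})
    ent_idx = {e: i for i, e in enumerate(entities)}
    rel_idx = {r: i for i, r in enumerate(relations)}
    n_ent = len(entities)

    E = rng.normal(size=(n_ent, d2)) / np.sqrt(d2)
    R = rng.normal(size=(len(relations), d2)) / np.sqrt(d2)

    H = np.array([ent_idx[t.head_id] for t in triples])
    L = np.array([rel_idx[t.relation] for t in triples])
    T = np.array([ent_idx[t.tail_id] for t in triples])
    n = len(triples)

    def energies(E, heads, rels, tails):
        diff = E[heads] + R[rels] - E[tails]
        return np.linalg.norm(diff, axis=1), diff

    # fixed evaluation corruption for the tracked loss curve
    if track_loss:
        ev_head = rng.random(n) < 0.5
        ev_repl = rng.integers(n_ent, size=n)
        evH = np.where(ev_head, ev_repl, H)
        evT = np.where(ev_head, T, ev_repl)
        curve: list[float] = []

    for _ in range(epochs):
        E /= np.maximum(np.linalg.norm(E, axis=1, keepdims=True), 1e-12)
        corrupt_head = rng.random(n) < 0.5
        repl = rng.integers(n_ent, size=n)
        nH = np.where(corrupt_head, repl, H)
        nT = np.where(corrupt_head, T, repl)

        pos_e, pos_d = energies(E, H, L, T)
        neg_e, neg_d = energies(E, nH, L, nT)
        active = (margin + pos_e - neg_e) > 0
        if active.any():
            # d||v||/dv = v/||v||
            gp = pos_d[active] / np.maximum(pos_e[active, None], 1e-12)
            gn = neg_d[active] / np.maximum(neg_e[active, None], 1e-12)
            dE = np.zeros_like(E)
            dR = np.zeros_like(R)
            idx = np.nonzero(active)[0]
            np.add.at(dE, H[idx], gp)
            np.add.at(dE, T[idx], -gp)
            np.add.at(dR, L[idx], gp - gn)
            np.add.at(dE, nH[idx], -gn)
            np.add.at(dE, nT[idx], gn)
            E -= learning_rate * dE
            R -= learning_rate * dR

        if track_loss:
            pe, _ = energies(E, H, L, T)
            ne, _ = energies(E, evH, L, evT)
            curve.append(float(np.maximum(0.0, margin + pe - ne).mean()))

    emb = KnowledgeEmbeddings(
        entity_vectors={e: E[i].copy() for e, i in ent_idx.items()},
        relation_vectors={r: R[i].copy() for r, i in rel_idx.items()},
        d2=d2)
    if track_loss:
        return emb, curve
    return emb


def lookup_pair_relations(head_id: str, tail_id: str,
                          triples: Iterable[KBTriple],
                          embeddings: KnowledgeEmbeddings,
                          ) -> list[np.ndarray]:
    """Relation vectors linking a pair, in lexicographic label order.

    Non-null labels from the triple store are returned; a pair without any
    falls back to the single ``null`` relation vector, so the result is
    never empty (length 1 to 3 for the CID label set).
    """
    labels = sorted({t.relation for t in triples
                     if t.head_id == head_id and t.tail_id == tail_id
                     and t.relation != NULL_RELATION})
    if not labels:
        labels = [NULL_RELATION]
    out = []
    for lab in labels:
        if lab not in embeddings.relation_vectors:
            raise KeyError(f"unknown relation label {lab!r}")
        out.append(embeddings.relation_vectors[lab])
    return out


class PairRelationIndex:
    """Precomputed (head, tail) -> relation-vector lookup over a triple store."""

    def __init__(self, triples: Iterable[KBTriple],
                 embeddings: KnowledgeEmbeddings):
        self.embeddings = embeddings
        self._labels: dict[tuple[str, str], list[str]] = {}
        for t in triples:
            if t.relation == NULL_RELATION:
                continue
            key = (t.head_id, t.tail_id)
            labs = self._labels.setdefault(key, [])
            if t.relation not in labs:
                labs.append(t.relation)

    def relations(self, head_id: str, tail_id: str) -> list[np.ndarray]:
        labels = sorted(self._labels.get((head_id, tail_id), ())) \
            or [NULL_RELATION]
        return [self.embeddings.relation_vectors[lab] for lab in labels]


__all__ = [
    "KBTriple", "KnowledgeEmbeddings", "read_triples", "write_triples",
    "assemble_triples", "train_transe", "lookup_pair_relations",
    "PairRelationIndex", "NULL_RELATION", "CID_RELATIONS", "POSITIVE_RELATION",
]
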