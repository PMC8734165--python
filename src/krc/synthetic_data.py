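"""Seeded generators for toy corpora, concept hierarchies and knowledge bases.

The generator emulates the shape of title+abstract relation-extraction
corpora: each document names one (or more) chemicals in its title and an
administration sentence, and places each disease either in the same sentence
as a chemical (intra-sentential) or 1-3 sentences downstream
(inter-sentential), with filler sentences in between.  Chemical-induced
pairs are expressed with an unambiguous trigger pattern ("induced" /
"emerged shortly afterwards") and negative co-occurrences with neutral or
negated phrasing, so that a small encoder can learn the task at desk scale.
Every mention's offsets, sentence index and the complete expected candidate
inventory are recorded, making the generator the oracle for the
preprocessing pipeline.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass

import numpy as np

from .corpus_io import ConceptHierarchy, Document, Mention
from .encoder import TinyEncoderConfig
from .kb_embeddings import (CID_RELATIONS, KBTriple, POSITIVE_RELATION)

GOLD_RELATION = "CID"

_CHEM_PARTS = (("vexo", "dora", "mino", "calo", "zupra", "teli", "ranto",
                "bexi", "nolo", "quari"),
               ("zine", "phen", "mycin", "pril", "sartan", "olol", "caine",
                "micin", "profen", "statin"))
_DIS_PARTS = (("neuro", "cardio", "derma", "hepato", "nephro", "myo",
               "arthro", "encephalo", "gastro", "pneumo"),
              ("pathy", "itis", "algia", "osis", "edema", "plegia",
               "trophy", "sclerosis", "spasm", "rrhage"))


def _make_names(parts, n: int) -> list[str]:
    names = ["".join(p) for p in itertools.product(*parts)]
    if n > len(names):
        raise ValueError(f"vocabulary supports at most {len(names)} names")
    return names[:n]


@dataclass
class SynthConfig:
    n_docs: int = 30
    n_chemicals: int = 10
    n_diseases: int = 20
    sentences_per_abstract: int = 6
    p_positive_pair: float = 0.5
    p_cooccur_same_sentence: float = 0.5
    kb_coverage: float = 1.0
    kb_noise: float = 0.0
    hierarchy_depth: int = 2
    seed: int = 0
    # shape knobs beyond the corpus statistics above
    diseases_per_doc: int = 3
    p_distant_disease: float = 0.1   # disease beyond the distance cut
    p_no_candidate_doc: float = 0.0  # documents left for the fallback rule

    def __post_init__(self):
        for name in ("p_positive_pair", "p_cooccur_same_sentence",
                     "kb_coverage", "kb_noise", "p_distant_disease",
                     "p_no_candidate_doc"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")


@dataclass(frozen=True)
class InventoryEntry:
    """A candidate the preprocessing pipeline is expected to emit."""

    doc_id: str
    head_id: str
    tail_id: str
    level: str          # "intra" or "inter"
    distance: int
    label: bool


@dataclass
class SyntheticCorpus:
    documents: list[Document]
    gold_pairs: set[tuple[str, str, str]]          # (doc-scoped via docs)
    inventory: list[InventoryEntry]
    sentence_boundaries: dict[str, list[tuple[int, int]]]
    chemical_names: dict[str, str]                 # concept id -> surface
    disease_names: dict[str, str]

    def all_gold(self) -> set[tuple[str, str, str]]:
        """(doc_id, head_id, tail_id) triples over the whole corpus."""
        return {(d.doc_id, h, t) for d in self.documents
                for h, t, _ in d.gold_pairs}


def _positive_intra(chem, dis):
    return f"Treatment with {chem} induced severe {dis} in most patients."


def _negative_intra(chem, dis):
    return f"Treatment with {chem} showed no link to {dis} in this cohort."


def _positive_inter(dis):
    return f"Severe {dis} emerged shortly afterwards."


def _negative_inter(dis):
    return f"No {dis} was recorded during the follow up."


_FILLERS = (
    "Patients were monitored throughout the study.",
    "Laboratory values remained within normal limits.",
    "The dosing schedule followed standard practice.",
    "Clinical records were reviewed independently.",
    "Outcomes were assessed at regular intervals.",
)


def gen_corpus(config: SynthConfig) -> SyntheticCorpus:
    """Generate a seeded corpus with exact offsets and candidate inventory."""
    rng = np.random.default_rng(config.seed)
    chem_names = _make_names(_CHEM_PARTS, config.n_chemicals)
    dis_names = _make_names(_DIS_PARTS, config.n_diseases)
    chem_ids = {f"C{i:03d}": n for i, n in enumerate(chem_names)}
    dis_ids = {f"D{i:03d}": n for i, n in enumerate(dis_names)}
    chem_keys = list(chem_ids)
    dis_keys = list(dis_ids)

    documents: list[Document] = []
    inventory: list[InventoryEntry] = []
    boundaries: dict[str, list[tuple[int, int]]] = {}
    corpus_gold: set[tuple[str, str, str]] = set()

    for di in range(config.n_docs):
        doc_id = f"doc{di:04d}"
        chem = chem_keys[int(rng.integers(len(chem_keys)))]
        n_dis = min(config.diseases_per_doc, len(dis_keys))
        diseases = [dis_keys[i] for i in
                    rng.choice(len(dis_keys), size=n_dis, replace=False)]
        fallback_doc = rng.random() < config.p_no_candidate_doc

        # sentence plan: list of (text, [(surface, etype, concept_id)])
        title = (f"Study of {chem_ids[chem]} therapy.",
                 [(chem_ids[chem], "chemical", chem)])
        plan: list[tuple[str, list]] = []
        if not fallback_doc:
            plan.append((f"Patients received {chem_ids[chem]} daily.",
                         [(chem_ids[chem], "chemical", chem)]))

        intra_slots: list[tuple[str, list]] = []
        inter_specs: list[tuple[str, bool, int]] = []  # (dis, pos, gap)
        free_gaps = [1, 2, 3]
        for dis in diseases:
            positive = rng.random() < config.p_positive_pair
            if fallback_doc:
                inter_specs.append((dis, positive, 4 + len(inter_specs)))
                continue
            distant = rng.random() < config.p_distant_disease
            if distant:
                # beyond the distance cut no trigger pattern is realized,
                # so the pair cannot be gold
                positive = False
            intra = (not distant and free_gaps
                     and rng.random() < config.p_cooccur_same_sentence) \
                or (not distant and not free_gaps)
            if intra:
                text = (_positive_intra(chem_ids[chem], dis_ids[dis])
                        if positive else
                        _negative_intra(chem_ids[chem], dis_ids[dis]))
                intra_slots.append((text, [
                    (chem_ids[chem], "chemical", chem),
                    (dis_ids[dis], "disease", dis)]))
            else:
                if distant or not free_gaps:
                    gap = 4 + sum(1 for s in inter_specs if s[2] > 3)
                else:
                    gap = free_gaps.pop(int(rng.integers(len(free_gaps))))
                inter_specs.append((dis, positive, gap))
            if positive:
                corpus_gold.add((doc_id, chem, dis))

        plan.extend(intra_slots)
        last_chem_sent = len(plan)  # abstract sentence index of last chem
        # lay out inter/distant diseases by gap, fillers in between
        max_gap = max((g for _, _, g in inter_specs), default=0)
        slots: dict[int, tuple[str, list]] = {}
        for dis, positive, gap in inter_specs:
            text = (_positive_inter(dis_ids[dis]) if positive
                    else _negative_inter(dis_ids[dis]))
            slots[gap] = (text, [(dis_ids[dis], "disease", dis)])
        for gap in range(1, max_gap + 1):
            if gap in slots:
                plan.append(slots[gap])
            else:
                plan.append((_FILLERS[int(rng.integers(len(_FILLERS)))], []))
        while len(plan) < config.sentences_per_abstract:
            plan.append((_FILLERS[int(rng.integers(len(_FILLERS)))], []))

        # realise text and mentions with exact offsets
        doc = Document(doc_id=doc_id, title=title[0], abstract="")
        sent_spans: list[tuple[int, int]] = [(0, len(title[0]))]
        mentions: list[Mention] = []
        chem_sents: dict[str, list[int]] = {}
        dis_sents: dict[str, int] = {}

        def place(sent_idx: int, base: int, text: str, anns) -> None:
            for surface, etype, cid in anns:
                off = text.index(surface)
                mentions.append(Mention(base + off, base + off + len(surface),
                                        surface, etype, cid))
                if etype == "chemical":
                    chem_sents.setdefault(cid, []).append(sent_idx)
                else:
                    dis_sents[cid] = sent_idx

        place(0, 0, title[0], title[1])
        abstract_parts: list[str] = []
        base = len(title[0]) + 1
        for si, (text, anns) in enumerate(plan, start=1):
            sent_spans.append((base, base + len(text)))
            place(si, base, text, anns)
            abstract_parts.append(text)
            base += len(text) + 1
        doc.abstract = " ".join(abstract_parts)
        doc.mentions = mentions
        doc.gold_pairs = {(chem, dis, GOLD_RELATION)
                          for (d_id, chem, dis) in corpus_gold
                          if d_id == doc_id}
        doc.validate()
        boundaries[doc_id] = sent_spans
        documents.append(doc)

        # expected candidate inventory from placements
        for dis, ds in dis_sents.items():
            css = chem_sents.get(chem, [])
            if not css:
                continue
            dist = min(abs(cs - ds) for cs in css)
            if dist == 0:
                level = "intra"
            elif dist <= 3:
                level = "inter"
            else:
                continue
            inventory.append(InventoryEntry(
                doc_id, chem, dis, level, dist,
                (doc_id, chem, dis) in corpus_gold))

    return SyntheticCorpus(
        documents=documents, gold_pairs=corpus_gold, inventory=inventory,
        sentence_boundaries=boundaries, chemical_names=chem_ids,
        disease_names=dis_ids)


def gen_hierarchy(config: SynthConfig, corpus: SyntheticCorpus,
                  ) -> tuple[ConceptHierarchy, list[tuple[str, str, str]]]:
    """A disease concept tree of the configured depth plus the list of
    (doc_id, ancestor, descendant) co-occurrences planted in the corpus."""
    dis = list(corpus.disease_names)
    edges: set[tuple[str, str]] = set()
    if config.hierarchy_depth > 0 and len(dis) > 1:
        # chain the first depth+1 diseases root->...->leaf, attach the rest
        # to the root as siblings of the chain
        depth = min(config.hierarchy_depth, len(dis) - 1)
        for i in range(depth):
            edges.add((dis[i], dis[i + 1]))
        for other in dis[depth + 1:]:
            edges.add((dis[0], other))
    hierarchy = ConceptHierarchy(edges=frozenset(edges))

    planted: list[tuple[str, str, str]] = []
    for doc in corpus.documents:
        present = {m.concept_id for m in doc.mentions if m.etype == "disease"}
        for anc in present:
            for desc in hierarchy.descendants(anc) & (present - {anc}):
                planted.append((doc.doc_id, anc, desc))
    return hierarchy, planted


def gen_kb(gold_pairs: set[tuple[str, str, str]], config: SynthConfig,
           ) -> tuple[list[KBTriple], dict]:
    """A knowledge base covering ``kb_coverage`` of the gold pairs with the
    induction label, mislabelling ``kb_noise`` of those, plus non-gold
    distractor triples.  Returns (triples, ground-truth table)."""
    rng = np.random.default_rng(config.seed + 1)
    pairs = sorted({(h, t) for _, h, t in gold_pairs})
    triples: list[KBTriple] = []
    truth = {"covered": [], "noisy": [], "distractors": []}
    other_labels = [r for r in CID_RELATIONS if r != POSITIVE_RELATION]
    for h, t in pairs:
        if rng.random() >= config.kb_coverage:
            continue
        if rng.random() < config.kb_noise:
            lab = other_labels[int(rng.integers(len(other_labels)))]
            triples.append(KBTriple(h, lab, t))
            truth["noisy"].append((h, t, lab))
        else:
            triples.append(KBTriple(h, POSITIVE_RELATION, t))
            truth["covered"].append((h, t))
    # distractors: therapeutic/inferred links on non-gold pairs
    gold_set = set(pairs)
    n_distract = max(1, len(pairs) // 2)
    chems = sorted({h for h, _ in pairs}) or ["C000"]
    dis = sorted({t for _, t in pairs}) or ["D000"]
    tries = 0
    while len(truth["distractors"]) < n_distract and tries < 1000:
        tries += 1
        h = chems[int(rng.integers(len(chems)))]
        t = dis[int(rng.integers(len(dis)))]
        if (h, t) in gold_set:
            continue
        lab = other_labels[int(rng.integers(len(other_labels)))]
        if (h, t, lab) not in truth["distractors"]:
            triples.append(KBTriple(h, lab, t))
            truth["distractors"].append((h, t, lab))
    return triples, truth


def gen_planted_kb(n_entities: int = 20, n_relations: int = 3,
                   seed: int = 0) -> list[KBTriple]:
    """A translation-consistent knowledge base for embedding sanity checks.

    Entities are points of a small integer lattice and each relation is a
    unit step along one axis, so a perfect embedding exists in which the
    tail vector is exactly head + relation (the discrete analogue of tails
    generated as h + r).  Triples connect every in-lattice neighbour pair.
    """
    del seed  # the lattice is deterministic; kept for interface symmetry
    side = 1
    while side ** n_relations < n_entities:
        side += 1
    points = list(itertools.product(range(side), repeat=n_relations))
    points = points[:n_entities]
    index = {p: i for i, p in enumerate(points)}
    triples: list[KBTriple] = []
    for p, i in index.items():
        for axis in range(n_relations):
            q = tuple(c + (1 if a == axis else 0) for a, c in enumerate(p))
            j = index.get(q)
            if j is not None:
                triples.append(KBTriple(f"e{i}", f"r{axis}", f"e{j}"))
    return sorted(triples, key=lambda t: (t.relation, t.head_id))


def tiny_encoder_spec(vocab_size: int, seed: int = 0) -> TinyEncoderConfig:
    """The 2-layer, 2-head, d1=32 test encoder configuration."""
    return TinyEncoderConfig(vocab_size=vocab_size, d1=32, n_layers=2,
                             n_heads=2, d_ff=64, seed=seed)


def write_manifest(corpus: SyntheticCorpus, path) -> None:
    """Ground-truth manifest (gold pairs, inventory, boundaries) as JSON."""
    payload = {
        "gold_pairs": sorted(corpus.all_gold()),
        "inventory": [vars(e) for e in corpus.inventory],
        "sentence_boundaries": corpus.sentence_boundaries,
        "chemicals": corpus.chemical_names,
        "diseases": corpus.disease_names,
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1)


__all__ = [
    "SynthConfig", "SyntheticCorpus", "InventoryEntry", "gen_corpus",
    "gen_hierarchy", "gen_kb", "gen_planted_kb", "tiny_encoder_spec",
    "write_manifest", "GOLD_RELATION",
]
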