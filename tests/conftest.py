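import pytest

from krc.corpus_io import Document, Mention, split_sentences


def make_doc(doc_id, title, abstract, mention_specs, gold=()):
    """Build a document from (surface, etype, concept_id) specs, annotating
    every occurrence of each surface string."""
    doc = Document(doc_id=doc_id, title=title, abstract=abstract)
    text = doc.text
    for surface, etype, cid in mention_specs:
        start = 0
        while True:
            idx = text.find(surface, start)
            if idx < 0:
                break
            doc.mentions.append(
                Mention(idx, idx + len(surface), surface, etype, cid))
            start = idx + len(surface)
    doc.mentions.sort(key=lambda m: m.start)
    doc.gold_pairs = set(gold)
    doc.validate()
    return doc


@pytest.fixture
def toy_doc():
    """Aspirin document: one intra pair, inter pairs at distance 1 and 3."""
    doc = make_doc(
        "d1",
        "Aspirin and headache.",
        "Aspirin causes headache. Nausea was seen. Patients improved. "
        "Dizziness occurred later.",
        [("Aspirin", "chemical", "C1"),
         ("headache", "disease", "D1"),
         ("Nausea", "disease", "D2"),
         ("Dizziness", "disease", "D3")],
        gold=[("C1", "D1", "CID"), ("C1", "D2", "CID")],
    )
    return split_sentences(doc)


@pytest.fixture
def toy_doc_distance4():
    """Same document with the dizziness mention pushed to distance 4."""
    doc = make_doc(
        "d2",
        "Aspirin and headache.",
        "Aspirin causes headache. Nausea was seen. Patients improved. "
        "More tests ran. Dizziness occurred later.",
        [("Aspirin", "chemical", "C1"),
         ("headache", "disease", "D1"),
         ("Nausea", "disease", "D2"),
         ("Dizziness", "disease", "D3")],
    )
    return split_sentences(doc)
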