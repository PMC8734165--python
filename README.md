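# krc — document-level relation extraction as reading comprehension

`krc` extracts document-level relations between chemicals and diseases (or
between chemicals) from title+abstract biomedical articles by recasting
relation extraction as span-extraction question answering. Instead of
classifying an entity pair, the system asks a question built from the head
entity and the relation — *"what disease does flunitrazepam induce"* — and
reads the document for an answer span naming the tail entity, with an
explicit *no-answer* option for negative pairs. Prior knowledge from a
triple store (e.g. curated chemical–disease associations) is folded into the
reader through translation-based relation embeddings and a two-step
bilinear attention.

It is aimed at biomedical text-mining practitioners working with
PubTator-style corpora (BioCreative V CDR-like data: gold entity mentions
with concept IDs and document-level relation pairs) who want a
reading-comprehension relation extractor that is fully testable offline:
the package ships a seeded synthetic-corpus generator that emulates the
corpus, the concept hierarchy and the knowledge base, so every stage runs
end to end without downloads.

## The model

For a candidate pair the context `C` and query `Q` are packed as
`[CLS] Q [SEP] C [SEP]` and encoded into hidden states `h_1..h_k` by a
pluggable sequence encoder (a pretrained LM in production; a small trainable
transformer, 2 layers / 2 heads / d₁ = 32, for desk-scale runs and tests).
The candidate's knowledge-base relation vectors `r_1..r_T` (T ≤ 3, learned
by TransE over corpus ∪ KB triples, with a reserved `null` relation for
uncovered pairs) enter through two attention steps:

1. **knowledge selection** — αᵢₜ = softmaxₜ(hᵢ W₁ rₜ + b₁), kᵢ = Σₜ αᵢₜ rₜ
2. **knowledge–context alignment** — βᵢⱼ = softmaxⱼ(kᵢ W₂ hⱼ + b₂),
   h'ᵢ = Σⱼ βᵢⱼ hⱼ

The prediction head fuses vᵢ = W_h hᵢ + W_h′ h'ᵢ + b, concatenates
uᵢ = [h'ᵢ ; vᵢ], and scores start/end positions with separate feed-forward
networks `FFN(u) = RELU(u W₃ + b₃) W₄ + b₄`, softmax-normalised over the
sequence. The loss is −(log p_start[y_s] + log p_end[y_e])/2 averaged over
instances; null answers train the (0, 0) span on `[CLS]`. At inference the
span (i, j) maximising p_start[i]·p_end[j] is decoded, the `[CLS]` score
acting as the null threshold. Decoded spans that match a gold surface form
of the queried tail entity yield positive pair decisions, which are merged
per document ("any positive instance wins"), topped up by the fallback
heuristic (title chemicals × abstract diseases for documents with no
candidates), and scored as precision/recall/F1 over concept-ID pairs.

Preprocessing follows the standard candidate rules: intra-sentential pairs
use the containing sentence; pairs within sentence distance 1–3 become
inter-sentential instances (never both); other same-type mentions are
masked; candidates whose concept is a hierarchy ancestor of a more specific
concept in the same document are filtered out.

## Worked example

```python
from krc.experiments import run_end_to_end

out = run_end_to_end(seed=7, use_kb=True, n_docs=30, epochs=50)
r = out["report"]
print("instances", out["n_instances"], "gold", out["n_gold"],
      "epochs", out["epochs_to_target"])
for lvl in ("document", "intra", "inter"):
    m = getattr(r, lvl)
    print(lvl, f"P={m.precision:.3f} R={m.recall:.3f} F1={m.f1:.3f}")
```

prints

```
instances 81 gold 38 epochs 7
document P=1.000 R=0.947 F1=0.973
intra P=1.000 R=1.000 F1=1.000
inter P=1.000 R=0.905 F1=0.950
```

i.e. on a 30-document synthetic corpus (81 candidate instances, 38 gold
pairs) the knowledge-enabled reader recovers the training-set relations to
document-level F1 0.973 within 7 epochs; the two residual false negatives
are inter-sentential pairs. The same pipeline is available from the shell:

```
krc simulate --out-dir sim --n-docs 30 --seed 7
krc build-instances --corpus sim/corpus.pubtator --hierarchy sim/hierarchy.tsv --out sim/instances.json
krc kb-embed --triples sim/triples.tsv --out sim/emb.tsv --dim 16 --epochs 200 --seed 7
krc run-eval --corpus sim/corpus.pubtator --triples sim/triples.tsv --use-kb --epochs 30 --seed 7
```

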