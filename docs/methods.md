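# Methods

## Task reduction

Document-level relation extraction over (chemical, disease) — or, for
chemical-reaction corpora, (chemical, chemical) — concept pairs is reduced
to extractive question answering with unanswerable questions. Every
candidate pair yields one instance: a context window, a query naming the
head entity and the relation, and either a gold answer span over a mention
of the tail entity or the null answer. Decisions are made per instance and
merged back to concept-ID pairs per document, which is also the unit of
evaluation (set precision/recall/F1 of predicted vs annotated ID pairs).

## Candidate construction

* **Intra-sentential**: the pair co-occurs in at least one sentence; the
  context is the earliest such sentence. An intra pair is never also
  emitted as inter-sentential.
* **Inter-sentential**: otherwise, if the minimal sentence distance between
  a head and a tail mention is ≤ 3 (configurable), the context is the
  contiguous sentence window spanning the closest mention pair. Ties on
  distance break toward the leftmost head, then leftmost tail mention, for
  determinism. The window (rather than the whole abstract) keeps sequences
  short; for chemical-reaction corpora the full title+abstract is used
  instead, matching that task's convention.
* **Masking**: mentions of the tail entity type with a different concept ID
  are replaced by the placeholder token `UNK` so the reader cannot answer
  with a competing entity; an offset map retains the alignment of unmasked
  segments to document offsets. Masking is symmetric for same-type tasks
  (head and tail concepts are both kept) and can be disabled.
* **Hypernym filtering**: a candidate is dropped when its head or tail
  concept is a transitive ancestor — in the supplied concept hierarchy — of
  a more specific same-type concept mentioned in the same document. This
  mirrors most-specific-pair annotation guidelines; filtered gold pairs
  become unrecoverable false negatives, which is visible in the evaluation.
* **Queries**: natural style fills a per-task template ("what disease does
  X induce"); pseudo style concatenates head text, relation description and
  tail type. The pseudo wording is a fixed design choice (space-joined, no
  template words) since only its construction rule, not its surface form,
  is prescribed.
* **Gold answers**: the earliest unmasked tail mention in the context; the
  choice among multiple mentions is underdetermined, and "earliest" is the
  deterministic convention adopted here.
* Mentions with the unresolved concept marker `-1` are kept in text but
  excluded from pairing; composite pipe-joined concept annotations are
  expanded into one logical mention per ID.

## Sentence segmentation

Rule-based: the title is always one sentence; the abstract splits at
`.!?` followed by whitespace, guarded by an abbreviation list
(`i.e.`, `e.g.`, …), and any boundary that would split a mention is
dropped. Determinism matters more here than linguistic accuracy; the
splitter is configurable and the generator's sentence boundaries are
recovered exactly in tests.

## Knowledge representation

Triples from the knowledge base are unioned with `null`-labelled triples
for corpus candidate pairs the KB does not cover (for the
chemical-induced-disease task the label set is `inferred-association`,
`marker/mechanism`, `therapeutic`, `null`). TransE embeds entities and
relations in d₂ dimensions by minimising the margin ranking loss
max(0, margin + ‖h+r−t‖₂ − ‖h′+r−t′‖₂) with one uniformly corrupted
negative (head or tail, Bernoulli 0.5) per positive per epoch, entity
vectors renormalised to unit norm each epoch. Defaults: margin 1.0,
learning rate 0.01, normal initialisation; dimension and epochs are
caller-chosen (production-scale defaults 256/1000; desk-scale runs use
16/200–500 with learning rate 0.05, which converges on the small stores the
tests build). The loss curve reported by `track_loss=True` evaluates the
margin objective on a corruption sample fixed up front, so it tracks a
constant objective across epochs; because training resamples negatives
every epoch the curve fluctuates around its plateau, and the monotonicity
check operates on 10-bin means with a tolerance of 10% of the initial loss.

At lookup time a pair contributes the embedding vectors of its non-null KB
labels in lexicographic order (1–3 vectors); a pair with no KB evidence
contributes the single `null` vector, so the relation set is never empty.
The `null` vector never mixes with observed labels: it encodes the absence
of KB evidence, which contradicts any observed label.

## Model head

Bilinear logits with scalar biases implement both attention steps. The
printed formulation declares vector-valued biases (b₁ ∈ R^d₂, b₂ ∈ R^d₁)
added to scalar logits; a scalar bias is the dimensionally consistent
reading and is what this package implements (a constant shift cancels in
the softmax, so this choice only affects parameter count, not behaviour).
The FFN inner width defaults to d₁. In the no-knowledge ablation the head
consumes uᵢ = [hᵢ ; W_h hᵢ + b] — the same fusion shape with h′ replaced by
h — keeping the parameter count comparable and the head code shared; the
knowledge path is bypassed entirely, so outputs are invariant to whatever
relation vectors are supplied. The knowledge-selection step has an
averaging mode (kᵢ = mean of relation vectors) used for the
attention-vs-average comparison.

Sequences exceeding the encoder's maximum length are windowed SQuAD-style
with a configurable stride; training uses the window containing the gold
answer (window 0 for null instances), prediction takes the best-scoring
window, a non-null span from any window beating a null. Knowledge vectors
are computed once per pair and broadcast across windows.

## Training and decoding

All tensors run on a small in-package reverse-mode autodiff core
(`krc._autodiff`), so the encoder and head train end to end by exact
gradients; the core is verified against central-difference numerical
gradients. The optimizer is Adam with two parameter groups (encoder vs
head). Production-scale defaults mirror finetuned-LM practice (batch 12,
3e-5/1e-4 without KB, 2e-5/3e-5 with KB); desk-scale runs with the randomly
initialised tiny encoder use 1e-3/1e-3, appropriate for training from
scratch. Training is single-threaded and bit-reproducible given the seed.

Decoding maximises p_start[i]·p_end[j] over context positions with
i ≤ j < i + max_answer_length (default 20 tokens); the prediction is null
when p_start[0]·p_end[0] + threshold ≥ the best span score (threshold
default 0). Ties break toward the earlier start, then the shorter span. A
decoded span counts as a positive pair decision only if its normalised text
(lowercased, whitespace collapsed) equals a gold surface form of the
queried tail entity and the span maps back to an unmasked region; exact
match is the conservative reading of name matching, so near-miss strings
("headaches" vs "headache") resolve negative.

## Merging, fallback, evaluation

A pair is positive if any of its instances (intra or inter) is positive.
Documents that produced zero candidate instances fall back to the
cross-product heuristic: all title chemicals × all abstract diseases are
predicted positive. The fallback never removes pairs, so document-level
recall is non-decreasing under it. Intra/inter-level metrics restrict both
predictions and gold to pairs whose candidate level matches — a fixed,
symmetric convention, since level-restricted scoring has no single standard
definition. Precision is defined as 0 when there are no positive
predictions.

## Synthetic data

The generator emulates title+abstract corpora with controlled structure:
one chemical per document (title + an administration sentence), 3 diseases
placed either in a chemical-bearing sentence or 1–3 sentences downstream,
with filler sentences setting the distances. Positive pairs are expressed
by unambiguous trigger phrasing ("induced …" intra; "… emerged shortly
afterwards" inter) and negatives by negated or neutral phrasing, giving a
tiny encoder a learnable signal at desk scale. Diseases placed beyond the
distance cut are always negative — a relation the pipeline cannot see is
not annotated — except in designated fallback documents (zero reachable
candidates), whose positives exercise the heuristic. The generator records
exact offsets, sentence boundaries and the full expected candidate
inventory, which the preprocessing pipeline must reproduce; this
cross-module oracle is the strongest test in the suite. Default study
conditions: 30 documents, p(positive) = 0.5, p(same-sentence) = 0.5, KB
coverage 1.0 with noise 0.0 for the clean-knowledge comparison.

What the generator does *not* emulate: real PubMed language statistics,
ambiguous or implicit relation expression, NER errors (mentions are gold,
as in the target corpora), subword tokenisation effects (the toy tokenizer
is whitespace+punctuation based), or KB scale. Passing tests therefore
demonstrate the correctness of the pipeline's mechanics and the model's
capacity to learn an unambiguous signal — not performance on real
biomedical text.

The planted knowledge base for embedding checks is a small integer lattice:
entities are lattice points, each relation is a unit step along one axis,
so an exact translation embedding exists by construction (a cyclic-shift
design was rejected: translations cannot represent cycles). Sanity
thresholds: mean true-triple energy below mean corrupted energy, and
exhaustive tail-ranking hits@1 above the 1/20 chance level.

## Problem sizes

Desk-scale runs use 30 documents (~80 instances, sequences ≤ ~50 tokens),
a 2×32 transformer encoder, d₂ = 16 embeddings, and ≤ 50 training epochs
with early stop at training F1 ≥ 0.95; one end-to-end run takes a few
seconds on one CPU. These sizes were chosen so the whole suite and the
reproduction script complete quickly while every stage still operates on
non-trivial inputs.

## Known limitations

* Exact-match answer resolution cannot credit morphological variants of a
  gold surface form.
* The sentence splitter is deliberately simple; on real abstracts its
  boundaries will differ from tooling-based splitters, shifting intra/inter
  assignments.
* TransE cannot represent cyclic or symmetric relational structure; the
  embedding quality claims are limited to translation-consistent stores.
* Training at production scale (pretrained biomedical LM, millions of
  triples) is out of scope here: the encoder interface accepts such a model,
  but none ships with the package.
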