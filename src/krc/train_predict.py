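"""Training loop, span decoding with null handling, and pair resolution.

Instances are tokenized into (possibly windowed) packed sequences; training
minimises the mean span loss with an Adam optimizer using separate learning
rates for the encoder and the downstream head, mirroring the two-group
schedule standard for finetuned language-model readers.  Decoding picks the
(i, j) span maximising p_start[i] * p_end[j] over context positions, with the
[CLS] score acting as the null answer following the unanswerable-question
convention.  A decoded span counts as a detected relation only if its text
matches a gold-annotated surface form of the queried tail entity.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np

from ._autodiff import Tensor
from .encoder import PackedSequence, ToyTokenizer, pack_sequence
from .instance_builder import CandidateInstance
from .corpus_io import Document
from .krc_model import (ATTENTION, KrcParams, SpanDistributions,
                        batch_span_loss, forward)


@dataclass
class TrainConfig:
    batch_size: int = 12
    encoder_lr: float = 3e-5
    head_lr: float = 1e-4
    epochs: int = 10
    seed: int = 0
    use_kb: bool = False
    knowledge_mode: str = ATTENTION
    max_length: int | None = None
    stride: int = 16

    def __post_init__(self):
        if self.encoder_lr <= 0 or self.head_lr <= 0:
            raise ValueError("learning rates must be positive")

    @classmethod
    def cdr_defaults(cls, use_kb: bool = False, **kw) -> "TrainConfig":
        """Batch 12; encoder/head rates 3e-5/1e-4 without KB, 2e-5/3e-5
        with KB."""
        if use_kb:
            return cls(batch_size=12, encoder_lr=2e-5, head_lr=3e-5,
                       use_kb=True, **kw)
        return cls(batch_size=12, encoder_lr=3e-5, head_lr=1e-4, **kw)

    @classmethod
    def chr_defaults(cls, **kw) -> "TrainConfig":
        return cls(batch_size=32, encoder_lr=3e-5, head_lr=1e-4, **kw)


@dataclass
class TokenizedInstance:
    candidate: CandidateInstance
    windows: list[PackedSequence]
    train_window: int           # window index used for the training example
    y_start: int                # gold token indices within the train window
    y_end: int                  # (0, 0) encodes the null answer)
    relations: list[np.ndarray] = field(default_factory=list)


def tokenize_instance(candidate: CandidateInstance, tokenizer: ToyTokenizer,
                      max_length: int | None = None, stride: int = 16,
                      relations: list[np.ndarray] | None = None,
                      ) -> TokenizedInstance:
    """Pack an instance and align the gold answer to token indices.

    For positive instances the training window is the first window fully
    containing the answer; its gold indices are the first/last tokens
    overlapping the answer character span.  Null instances train on window 0
    with the (0, 0) sentinel.
    """
    windows = pack_sequence(tokenizer, candidate.query, candidate.context,
                            max_length=max_length, stride=stride)
    if candidate.is_null:
        return TokenizedInstance(candidate, windows, 0, 0, 0,
                                 relations or [])
    a_s, a_e = candidate.answer_start, candidate.answer_end
    for wi, w in enumerate(windows):
        hits = [ti for ti, (s, e) in enumerate(w.context_spans)
                if s < a_e and a_s < e]
        if not hits:
            continue
        first, last = hits[0], hits[-1]
        s0, e0 = w.context_spans[first][0], w.context_spans[last][1]
        if s0 <= a_s and a_e <= e0:
            off = w.context_token_start
            return TokenizedInstance(candidate, windows, wi,
                                     off + first, off + last,
                                     relations or [])
    raise RuntimeError(
        f"{candidate.doc_id}: gold answer not contained in any window")


# ---------------------------------------------------------------------------
# Optimizer

class Adam:
    """Adam with decoupled parameter groups (encoder vs head)."""

    def __init__(self, groups: list[tuple[list[Tensor], float]],
                 betas=(0.9, 0.999), eps: float = 1e-8):
        self.groups = groups
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.state = {id(p): (np.zeros_like(p.data), np.zeros_like(p.data))
                      for params, _ in groups for p in params}

    def step(self) -> None:
        self.t += 1
        for params, lr in self.groups:
            for p in params:
                if p.grad is None:
                    continue
                m, v = self.state[id(p)]
                m = self.b1 * m + (1 - self.b1) * p.grad
                v = self.b2 * v + (1 - self.b2) * p.grad ** 2
                self.state[id(p)] = (m, v)
                mhat = m / (1 - self.b1 ** self.t)
                vhat = v / (1 - self.b2 ** self.t)
                p.data -= lr * mhat / (np.sqrt(vhat) + self.eps)

    def zero_grad(self) -> None:
        for params, _ in self.groups:
            for p in params:
                p.grad = None


# ---------------------------------------------------------------------------
# Training

def train(instances: list[TokenizedInstance], encoder, params: KrcParams,
          config: TrainConfig, epoch_callback=None,
          ) -> list[float]:
    """Mini-batch training of encoder + head; returns the per-epoch mean
    training loss curve.  ``epoch_callback(epoch, loss)`` may return True to
    stop early (used for epochs-to-criterion measurements)."""
    if not instances:
        raise ValueError("no training instances")
    rng = np.random.default_rng(config.seed)
    opt = Adam([(encoder.parameters(), config.encoder_lr),
                (params.parameters(), config.head_lr)])
    curve: list[float] = []
    order = np.arange(len(instances))
    for epoch in range(config.epochs):
        rng.shuffle(order)
        total, count = 0.0, 0
        for lo in range(0, len(order), config.batch_size):
            batch = [instances[i] for i in order[lo:lo + config.batch_size]]
            opt.zero_grad()
            pairs = []
            for inst in batch:
                w = inst.windows[inst.train_window]
                hidden = encoder(w.token_ids, w.segment_ids)
                dists = forward(hidden, inst.relations, params,
                                use_kb=config.use_kb,
                                knowledge_mode=config.knowledge_mode)
                pairs.append((dists, inst.y_start, inst.y_end))
            loss = batch_span_loss(pairs)
            loss.backward()
            opt.step()
            total += float(loss.data) * len(batch)
            count += len(batch)
        curve.append(total / count)
        if epoch_callback is not None and epoch_callback(epoch, curve[-1]):
            break
    return curve


# ---------------------------------------------------------------------------
# Decoding

@dataclass
class SpanPrediction:
    start: int                  # token indices; (0, 0) = null
    end: int
    score: float                # p_start[start] * p_end[end]
    null_score: float
    text: str = ""
    is_null: bool = False
    char_span: tuple[int, int] | None = None  # context char offsets


def decode_span(dists: SpanDistributions, max_answer_length: int = 20,
                null_threshold: float = 0.0,
                context_range: tuple[int, int] | None = None,
                ) -> SpanPrediction:
    """Best-span decoding with the [CLS]-as-null convention.

    The best non-null span maximises p_start[i] * p_end[j] over context
    positions i <= j < i + max_answer_length; ties break toward the earlier
    start, then the shorter span.  The prediction is null when
    p_start[0] * p_end[0] + null_threshold >= best span score.
    """
    ps = np.asarray(dists.p_start.data, dtype=float).ravel()
    pe = np.asarray(dists.p_end.data, dtype=float).ravel()
    k = len(ps)
    lo, hi = context_range if context_range is not None else (1, k)
    null_score = float(ps[0] * pe[0])
    best = None  # (score, start, end); first hit wins ties (earlier, shorter)
    for i in range(lo, hi):
        for j in range(i, min(i + max_answer_length, hi)):
            s = float(ps[i] * pe[j])
            if best is None or s > best[0]:
                best = (s, i, j)
    if best is None or null_score + null_threshold >= best[0]:
        return SpanPrediction(0, 0, null_score, null_score, is_null=True)
    return SpanPrediction(best[1], best[2], best[0], null_score)


def predict_instance(inst: TokenizedInstance, encoder, params: KrcParams,
                     config: TrainConfig, max_answer_length: int = 20,
                     null_threshold: float = 0.0) -> SpanPrediction:
    """Decode every window and keep the best-scoring prediction (a non-null
    span from any window beats a null; otherwise the higher score wins)."""
    best: SpanPrediction | None = None
    for w in inst.windows:
        hidden = encoder(w.token_ids, w.segment_ids)
        dists = forward(hidden, inst.relations, params,
                        use_kb=config.use_kb,
                        knowledge_mode=config.knowledge_mode)
        pred = decode_span(dists, max_answer_length=max_answer_length,
                           null_threshold=null_threshold,
                           context_range=(w.context_token_start,
                                          w.context_token_end))
        if not pred.is_null:
            off = w.context_token_start
            c_start = w.context_spans[pred.start - off][0]
            c_end = w.context_spans[pred.end - off][1]
            pred.text = inst.candidate.context[c_start:c_end]
            pred.char_span = (c_start, c_end)
        better = (best is None
                  or (best.is_null and not pred.is_null)
                  or (best.is_null == pred.is_null
                      and pred.score > best.score))
        if better:
            best = pred
    return best


# ---------------------------------------------------------------------------
# Pair resolution

_WS = re.compile(r"\s+")


def _normalize(text: str) -> str:
    return _WS.sub(" ", text.strip().lower())


@dataclass(frozen=True)
class PairPrediction:
    doc_id: str
    head_id: str
    tail_id: str
    positive: bool
    provenance: str            # "intra", "inter" or "fallback"


def resolve_prediction(span: SpanPrediction, candidate: CandidateInstance,
                       doc: Document) -> PairPrediction:
    """Positive iff the decoded span text equals (case-insensitively, with
    whitespace collapsed) a gold surface form of the candidate tail entity
    and maps back to an unmasked document region."""
    positive = False
    if not span.is_null and span.text:
        in_masked = (span.char_span is not None
                     and candidate.to_document_span(*span.char_span) is None)
        gold_texts = {_normalize(m.text) for m in doc.mentions
                      if m.concept_id == candidate.tail_id}
        if not in_masked and _normalize(span.text) in gold_texts:
            positive = True
    return PairPrediction(candidate.doc_id, candidate.head_id,
                          candidate.tail_id, positive, candidate.level)


__all__ = [
    "TrainConfig", "TokenizedInstance", "tokenize_instance", "Adam", "train",
    "SpanPrediction", "decode_span", "predict_instance", "PairPrediction",
    "resolve_prediction",
]
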