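"""The knowledge-enhanced reading-comprehension model.

Given the encoder hidden states h_1..h_k of a packed [CLS] query [SEP]
context [SEP] sequence and a small set of candidate knowledge-base relation
vectors r_1..r_T for the entity pair, the model:

1. selects, per token, a weighted relation vector
   k_i = sum_t alpha_it r_t with alpha_it = softmax_t(h_i W1 r_t + b1)
   (bilinear knowledge-selection attention; ``mean`` mode replaces the
   attention by the plain average of the relation vectors);
2. aligns each k_i back onto the context,
   h'_i = sum_j beta_ij h_j with beta_ij = softmax_j(k_i W2 h_j + b2)
   (knowledge-context attention);
3. fuses v_i = W_h h_i + W_h' h'_i + b, u_i = [h'_i ; v_i], and scores
   start/end positions with separate FFN heads
   FFN(u) = RELU(u W3 + b3) W4 + b4, softmax-normalised along the sequence.

A null answer ("no relation expressed") is encoded as the span (0, 0), the
[CLS] position.  The training loss is the mean over instances of
-(log p_start[y_s] + log p_end[y_e]) / 2.

All operations run on the autodiff :class:`~krc._autodiff.Tensor`, so the
whole stack (including a trainable encoder) is differentiable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._autodiff import Tensor, concat
from .encoder import PackedSequence, ToyTokenizer, pack_sequence

ATTENTION = "attention"
MEAN = "mean"


def _as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(np.asarray(x, dtype=float))


@dataclass
class KrcParams:
    """Trainable parameters of the attention, fusion and prediction head."""

    W1: Tensor      # d1 x d2, knowledge-selection bilinear map
    b1: Tensor      # scalar logit bias
    W2: Tensor      # d2 x d1, knowledge-context bilinear map
    b2: Tensor      # scalar logit bias
    W_h: Tensor     # d1 x d1 fusion of h
    W_hp: Tensor    # d1 x d1 fusion of h'
    b: Tensor       # d1 fusion bias
    W3_s: Tensor    # 2*d1 x d_ff, start head
    b3_s: Tensor
    W4_s: Tensor    # d_ff x 1
    b4_s: Tensor
    W3_e: Tensor    # end head
    b3_e: Tensor
    W4_e: Tensor
    b4_e: Tensor

    @classmethod
    def init(cls, d1: int, d2: int, d_ff: int | None = None,
             seed: int = 0) -> "KrcParams":
        d_ff = d_ff or d1
        rng = np.random.default_rng(seed)
        def par(*shape):
            scale = 1.0 / np.sqrt(shape[0]) if shape else 1.0
            return Tensor(rng.normal(size=shape) * scale, requires_grad=True)
        def zero(*shape):
            return Tensor(np.zeros(shape), requires_grad=True)
        return cls(
            W1=par(d1, d2), b1=zero(), W2=par(d2, d1), b2=zero(),
            W_h=par(d1, d1), W_hp=par(d1, d1), b=zero(d1),
            W3_s=par(2 * d1, d_ff), b3_s=zero(d_ff),
            W4_s=par(d_ff, 1), b4_s=zero(),
            W3_e=par(2 * d1, d_ff), b3_e=zero(d_ff),
            W4_e=par(d_ff, 1), b4_e=zero(),
        )

    def parameters(self) -> list[Tensor]:
        return [self.W1, self.b1, self.W2, self.b2, self.W_h, self.W_hp,
                self.b, self.W3_s, self.b3_s, self.W4_s, self.b4_s,
                self.W3_e, self.b3_e, self.W4_e, self.b4_e]


@dataclass
class SpanDistributions:
    """Start/end probability vectors over the k sequence positions."""

    p_start: Tensor
    p_end: Tensor

    @property
    def k(self) -> int:
        return self.p_start.shape[-1]


def encode(query_tokens: str, context_tokens: str, encoder,
           tokenizer: ToyTokenizer | None = None,
           max_length: int | None = None, stride: int = 16,
           ) -> list[tuple[PackedSequence, Tensor]]:
    """Pack query+context and run the injected encoder on each window.

    Returns (window, hidden) pairs where hidden is a (k, d1) matrix.  The
    encoder is any callable ``encoder(token_ids, segment_ids) -> Tensor``.
    """
    windows = pack_sequence(tokenizer, query_tokens, context_tokens,
                            max_length=max_length, stride=stride)
    return [(w, encoder(w.token_ids, w.segment_ids)) for w in windows]


def knowledge_select_attention(hidden, relations, params: KrcParams,
                               mode: str = ATTENTION) -> Tensor:
    """Per-token weighted relation vector k_i (k x d2).

    ``attention`` mode weighs the candidate relation vectors by the bilinear
    logits h_i W1 r_t + b1, softmax-normalised over the relations;
    ``mean`` mode ignores the hidden states and averages the relations.
    """
    hidden = _as_tensor(hidden)
    rel_list = [np.asarray(r, dtype=float) for r in relations]
    if not rel_list:
        raise ValueError("at least one relation vector is required")
    rel = Tensor(np.stack(rel_list))               # T x d2
    if mode == MEAN:
        k = hidden.shape[0]
        mean_r = rel.mean(axis=0, keepdims=True)   # 1 x d2
        ones = Tensor(np.ones((k, 1)))
        return ones @ mean_r
    if mode != ATTENTION:
        raise ValueError(f"unknown knowledge mode {mode!r}")
    logits = hidden @ params.W1 @ rel.transpose() + params.b1   # k x T
    alpha = logits.softmax(axis=-1)
    return alpha @ rel


def knowledge_context_attention(k_mat, hidden, params: KrcParams) -> Tensor:
    """Knowledge-aligned context representation h'_i (k x d1)."""
    k_mat = _as_tensor(k_mat)
    hidden = _as_tensor(hidden)
    if k_mat.shape[0] != hidden.shape[0]:
        raise ValueError("row counts of k and h must match")
    logits = k_mat @ params.W2 @ hidden.transpose() + params.b2  # k x k
    beta = logits.softmax(axis=-1)
    return beta @ hidden


def _ffn(u: Tensor, W3: Tensor, b3: Tensor, W4: Tensor, b4: Tensor) -> Tensor:
    return (u @ W3 + b3).relu() @ W4 + b4


def fuse_and_predict(hidden, h_prime, params: KrcParams,
                     use_kb: bool = True) -> SpanDistributions:
    """Fusion v_i, concatenation u_i and start/end softmax distributions.

    With ``use_kb`` off the knowledge path is bypassed entirely: the head
    consumes u_i = [h_i ; W_h h_i + b], keeping the parameter shape of the
    knowledge-enabled head.
    """
    hidden = _as_tensor(hidden)
    if use_kb:
        h_prime = _as_tensor(h_prime)
        v = hidden @ params.W_h + h_prime @ params.W_hp + params.b
        u = concat([h_prime, v], axis=1)
    else:
        v = hidden @ params.W_h + params.b
        u = concat([hidden, v], axis=1)
    s_logits = _ffn(u, params.W3_s, params.b3_s, params.W4_s, params.b4_s)
    e_logits = _ffn(u, params.W3_e, params.b3_e, params.W4_e, params.b4_e)
    if not (np.isfinite(s_logits.data).all()
            and np.isfinite(e_logits.data).all()):
        raise FloatingPointError("non-finite span logits")
    k = hidden.shape[0]
    return SpanDistributions(
        p_start=s_logits.reshape(k).softmax(axis=-1),
        p_end=e_logits.reshape(k).softmax(axis=-1),
    )


def forward(hidden, relations, params: KrcParams, use_kb: bool = True,
            knowledge_mode: str = ATTENTION) -> SpanDistributions:
    """Full head: two-step knowledge attention + fusion + span prediction."""
    if use_kb:
        k_mat = knowledge_select_attention(hidden, relations, params,
                                           mode=knowledge_mode)
        h_prime = knowledge_context_attention(k_mat, hidden, params)
    else:
        h_prime = None
    return fuse_and_predict(hidden, h_prime, params, use_kb=use_kb)


def span_loss(dists: SpanDistributions, y_start: int, y_end: int) -> Tensor:
    """-(log p_start[y_s] + log p_end[y_e]) / 2; null answers use (0, 0)."""
    k = dists.k
    if not (0 <= y_start < k and 0 <= y_end < k):
        raise IndexError(f"gold span ({y_start},{y_end}) outside sequence "
                         f"of length {k}")
    ls = dists.p_start[y_start].log()
    le = dists.p_end[y_end].log()
    return (ls + le) * (-0.5)


def batch_span_loss(pairs) -> Tensor:
    """Mean span loss over (dists, y_start, y_end) triples."""
    losses = [span_loss(d, ys, ye).reshape(1) for d, ys, ye in pairs]
    return concat(losses, axis=0).mean()


__all__ = [
    "KrcParams", "SpanDistributions", "encode", "knowledge_select_attention",
    "knowledge_context_attention", "fuse_and_predict", "forward",
    "span_loss", "batch_span_loss", "ATTENTION", "MEAN",
]
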