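"""Pluggable sequence encoders and the toy whitespace tokenizer.

The reading-comprehension model only requires an encoder honouring a narrow
contract: given token ids (plus segment ids), return one d1-dimensional
hidden vector per token.  In production that contract is met by a pretrained
language model; for desk-scale experiments and tests this module provides a
small randomly initialised transformer (multi-head self-attention + FFN with
residual connections and layer normalisation) built on the package's
autodiff core, so it can be trained end to end.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np

from ._autodiff import Tensor, concat, gather_rows, layer_norm

CLS, SEP, PAD, UNK = "[CLS]", "[SEP]", "[PAD]", "[UNK]"
SPECIALS = (PAD, UNK, CLS, SEP)

_TOKEN_RE = re.compile(r"\w+|[^\w\s]")


@dataclass
class ToyTokenizer:
    """Whitespace + punctuation tokenizer over a fixed vocabulary.

    Tokens carry their character spans so answer character offsets can be
    aligned to token indices without subword bookkeeping.
    """

    vocab: dict[str, int] = field(default_factory=dict)

    def __post_init__(self):
        for sp in SPECIALS:
            self.vocab.setdefault(sp, len(self.vocab))

    @classmethod
    def from_texts(cls, texts) -> "ToyTokenizer":
        tok = cls()
        for text in texts:
            for match in _TOKEN_RE.finditer(text.lower()):
                tok.vocab.setdefault(match.group(), len(tok.vocab))
        return tok

    def __len__(self) -> int:
        return len(self.vocab)

    def tokenize(self, text: str) -> list[tuple[str, int, int]]:
        """Lowercased (token, char_start, char_end) triples."""
        return [(m.group(), m.start(), m.end())
                for m in _TOKEN_RE.finditer(text.lower())]

    def token_id(self, token: str) -> int:
        return self.vocab.get(token, self.vocab[UNK])


@dataclass
class PackedSequence:
    """A [CLS] query [SEP] context [SEP] window ready for encoding."""

    token_ids: np.ndarray        # (k,)
    segment_ids: np.ndarray      # (k,) 0 for query part, 1 for context part
    context_token_start: int     # index of first context token
    context_token_end: int       # one past last context token
    # char span in the context string for each context token
    context_spans: list[tuple[int, int]]
    window_char_start: int = 0   # context char offset where this window begins

    @property
    def k(self) -> int:
        return len(self.token_ids)


def pack_sequence(tokenizer: ToyTokenizer, query: str, context: str,
                  max_length: int | None = None, stride: int = 16,
                  ) -> list[PackedSequence]:
    """Pack query+context into one or more overlapping encoder windows.

    Sequences longer than ``max_length`` are split over the context tokens
    with the given stride (consecutive windows overlap by
    ``window_size - stride`` context tokens), the standard span-model
    treatment of long inputs.
    """
    if not context:
        raise ValueError("empty context")
    q_tokens = [t for t, _, _ in tokenizer.tokenize(query)]
    c_tokens = tokenizer.tokenize(context)
    header = [tokenizer.token_id(CLS)] + \
        [tokenizer.token_id(t) for t in q_tokens] + [tokenizer.token_id(SEP)]
    n_header = len(header)
    budget = None if max_length is None else max_length - n_header - 1
    if budget is not None and budget < 1:
        raise ValueError("max_length too small for the query")

    windows: list[PackedSequence] = []
    start = 0
    while True:
        chunk = c_tokens[start:start + budget] if budget else c_tokens[start:]
        ids = header + [tokenizer.token_id(t) for t, _, _ in chunk] + \
            [tokenizer.token_id(SEP)]
        seg = np.array([0] * n_header + [1] * (len(chunk) + 1))
        windows.append(PackedSequence(
            token_ids=np.array(ids),
            segment_ids=seg,
            context_token_start=n_header,
            context_token_end=n_header + len(chunk),
            context_spans=[(s, e) for _, s, e in chunk],
            window_char_start=chunk[0][1] if chunk else 0,
        ))
        if budget is None or start + budget >= len(c_tokens):
            break
        start += stride
    return windows


@dataclass
class TinyEncoderConfig:
    vocab_size: int
    d1: int = 32
    n_layers: int = 2
    n_heads: int = 2
    d_ff: int = 64
    max_positions: int = 512
    seed: int = 0


class TinyTransformerEncoder:
    """A small trainable transformer honouring the encode contract."""

    def __init__(self, config: TinyEncoderConfig):
        self.config = config
        rng = np.random.default_rng(config.seed)
        d = config.d1
        def par(*shape, scale=None):
            scale = scale if scale is not None else 1.0 / np.sqrt(shape[0])
            return Tensor(rng.normal(size=shape) * scale, requires_grad=True)
        self.tok_emb = par(config.vocab_size, d, scale=0.1)
        self.pos_emb = par(config.max_positions, d, scale=0.1)
        self.seg_emb = par(2, d, scale=0.1)
        self.layers = []
        for _ in range(config.n_layers):
            layer = {
                "Wq": par(d, d), "Wk": par(d, d), "Wv": par(d, d),
                "Wo": par(d, d),
                "ln1_g": Tensor(np.ones(d), requires_grad=True),
                "ln1_b": Tensor(np.zeros(d), requires_grad=True),
                "W_ff1": par(d, config.d_ff), "b_ff1":
                    Tensor(np.zeros(config.d_ff), requires_grad=True),
                "W_ff2": par(config.d_ff, d), "b_ff2":
                    Tensor(np.zeros(d), requires_grad=True),
                "ln2_g": Tensor(np.ones(d), requires_grad=True),
                "ln2_b": Tensor(np.zeros(d), requires_grad=True),
            }
            self.layers.append(layer)

    @property
    def d1(self) -> int:
        return self.config.d1

    def parameters(self) -> list[Tensor]:
        out = [self.tok_emb, self.pos_emb, self.seg_emb]
        for layer in self.layers:
            out.extend(layer.values())
        return out

    def __call__(self, token_ids: np.ndarray,
                 segment_ids: np.ndarray | None = None) -> Tensor:
        """Encode one packed sequence; returns a (k, d1) hidden matrix."""
        k = len(token_ids)
        if k == 0:
            raise ValueError("empty input sequence")
        d = self.config.d1
        dh = d // self.config.n_heads
        x = gather_rows(self.tok_emb, np.asarray(token_ids)) \
            + gather_rows(self.pos_emb, np.arange(k))
        if segment_ids is not None:
            x = x + gather_rows(self.seg_emb, np.asarray(segment_ids))
        for layer in self.layers:
            q = x @ layer["Wq"]
            kk = x @ layer["Wk"]
            v = x @ layer["Wv"]
            heads = []
            for h in range(self.config.n_heads):
                sl = slice(h * dh, (h + 1) * dh)
                scores = (q[:, sl] @ kk[:, sl].transpose()) * (dh ** -0.5)
                heads.append(scores.softmax(axis=-1) @ v[:, sl])
            attn = concat(heads, axis=1) @ layer["Wo"]
            x = layer_norm(x + attn, layer["ln1_g"], layer["ln1_b"])
            ff = ((x @ layer["W_ff1"] + layer["b_ff1"]).relu()
                  @ layer["W_ff2"] + layer["b_ff2"])
            x = layer_norm(x + ff, layer["ln2_g"], layer["ln2_b"])
        return x


__all__ = [
    "ToyTokenizer", "PackedSequence", "pack_sequence",
    "TinyEncoderConfig", "TinyTransformerEncoder",
    "CLS", "SEP", "PAD", "UNK",
]
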