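import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from krc._autodiff import Tensor
from krc.krc_model import (MEAN, KrcParams, SpanDistributions,
                           batch_span_loss, encode, forward, fuse_and_predict,
                           knowledge_context_attention,
                           knowledge_select_attention, span_loss)
from krc.encoder import (TinyEncoderConfig, TinyTransformerEncoder,
                         ToyTokenizer, pack_sequence)


# ---------------------------------------------------------------------------
# per-position loop oracles

def oracle_select(h, rels, W1, b1):
    k, d2 = h.shape[0], rels[0].shape[0]
    K = np.zeros((k, d2))
    for i in range(k):
        logits = np.array([h[i] @ W1 @ r + b1 for r in rels])
        a = np.exp(logits - logits.max())
        a /= a.sum()
        K[i] = sum(a[t] * rels[t] for t in range(len(rels)))
    return K


def oracle_context(K, h, W2, b2):
    k, d1 = h.shape
    Hp = np.zeros((k, d1))
    for i in range(k):
        logits = np.array([K[i] @ W2 @ h[j] + b2 for j in range(k)])
        b = np.exp(logits - logits.max())
        b /= b.sum()
        Hp[i] = sum(b[j] * h[j] for j in range(k))
    return Hp


def oracle_head(h, Hp, p):
    def ffn(u, W3, b3, W4, b4):
        return (np.maximum(u @ W3 + b3, 0) @ W4)[0] + b4
    v = np.array([h[i] @ p.W_h.data + Hp[i] @ p.W_hp.data + p.b.data
                  for i in range(len(h))])
    u = np.concatenate([Hp, v], axis=1)
    sl = np.array([ffn(u[i], p.W3_s.data, p.b3_s.data, p.W4_s.data,
                       float(p.b4_s.data)) for i in range(len(h))])
    el = np.array([ffn(u[i], p.W3_e.data, p.b3_e.data, p.W4_e.data,
                       float(p.b4_e.data)) for i in range(len(h))])
    ps = np.exp(sl - sl.max())
    pe = np.exp(el - el.max())
    return ps / ps.sum(), pe / pe.sum()


@pytest.fixture
def rng():
    return np.random.default_rng(7)


class TestKnowledgeSelectAttention:
    def test_matches_loop_oracle(self, rng):
        for _ in range(20):
            k, d1, d2, T = (int(rng.integers(2, 8)), int(rng.integers(2, 16)),
                            int(rng.integers(2, 8)), int(rng.integers(1, 4)))
            params = KrcParams.init(d1, d2, seed=int(rng.integers(100)))
            h = rng.normal(size=(k, d1))
            rels = [rng.normal(size=d2) for _ in range(T)]
            got = knowledge_select_attention(h, rels, params).data
            want = oracle_select(h, rels, params.W1.data,
                                 float(params.b1.data))
            assert np.abs(got - want).max() < 1e-5

    def test_single_relation_returned_exactly(self, rng):
        params = KrcParams.init(8, 4, seed=0)
        h = rng.normal(size=(5, 8))
        r = rng.normal(size=4)
        for mode in ("attention", "mean"):
            got = knowledge_select_attention(h, [r], params, mode=mode).data
            assert np.array_equal(got, np.tile(r, (5, 1)))

    def test_three_identical_relations_uniform_weights(self, rng):
        params = KrcParams.init(8, 4, seed=0)
        h = rng.normal(size=(5, 8))
        r = rng.normal(size=4)
        got = knowledge_select_attention(h, [r, r, r], params).data
        assert np.allclose(got, np.tile(r, (5, 1)))

    def test_mean_mode_averages(self, rng):
        params = KrcParams.init(8, 4, seed=0)
        h = rng.normal(size=(5, 8))
        rels = [rng.normal(size=4) for _ in range(3)]
        got = knowledge_select_attention(h, rels, params, mode=MEAN).data
        assert np.allclose(got, np.tile(np.mean(rels, axis=0), (5, 1)))

    def test_zero_relations_rejected(self, rng):
        params = KrcParams.init(8, 4, seed=0)
        with pytest.raises(ValueError):
            knowledge_select_attention(rng.normal(size=(5, 8)), [], params)


class TestKnowledgeContextAttention:
    def test_matches_loop_oracle(self, rng):
        for _ in range(20):
            k, d1, d2 = (int(rng.integers(1, 8)), int(rng.integers(2, 16)),
                         int(rng.integers(2, 8)))
            params = KrcParams.init(d1, d2, seed=int(rng.integers(100)))
            h = rng.normal(size=(k, d1))
            K = rng.normal(size=(k, d2))
            got = knowledge_context_attention(K, h, params).data
            want = oracle_context(K, h, params.W2.data, float(params.b2.data))
            assert np.abs(got - want).max() < 1e-5

    def test_length_one_sequence_identity(self, rng):
        params = KrcParams.init(4, 3, seed=0)
        h = rng.normal(size=(1, 4))
        got = knowledge_context_attention(rng.normal(size=(1, 3)), h,
                                          params).data
        assert np.allclose(got, h)

    def test_identical_hidden_states_convexity(self, rng):
        params = KrcParams.init(4, 3, seed=0)
        h = np.tile(rng.normal(size=4), (6, 1))
        got = knowledge_context_attention(rng.normal(size=(6, 3)), h,
                                          params).data
        assert np.allclose(got, h)

    def test_shape_mismatch_rejected(self, rng):
        params = KrcParams.init(4, 3, seed=0)
        with pytest.raises(ValueError):
            knowledge_context_attention(rng.normal(size=(3, 3)),
                                        rng.normal(size=(4, 4)), params)


class TestFuseAndPredict:
    def test_matches_loop_oracle(self, rng):
        for _ in range(20):
            k, d1, d2 = (int(rng.integers(2, 8)), int(rng.integers(2, 16)),
                         int(rng.integers(2, 8)))
            params = KrcParams.init(d1, d2, seed=int(rng.integers(100)))
            h = rng.normal(size=(k, d1))
            Hp = rng.normal(size=(k, d1))
            dists = fuse_and_predict(h, Hp, params)
            ps, pe = oracle_head(h, Hp, params)
            assert np.abs(dists.p_start.data - ps).max() < 1e-5
            assert np.abs(dists.p_end.data - pe).max() < 1e-5

    def test_constant_input_uniform_distributions(self, rng):
        params = KrcParams.init(6, 3, seed=1)
        h = np.tile(rng.normal(size=6), (4, 1))
        dists = fuse_and_predict(h, h.copy(), params)
        assert np.allclose(dists.p_start.data, 0.25)
        assert np.allclose(dists.p_end.data, 0.25)

    def test_distributions_normalized(self, rng):
        params = KrcParams.init(6, 3, seed=2)
        dists = fuse_and_predict(rng.normal(size=(4, 6)),
                                 rng.normal(size=(4, 6)), params)
        assert abs(dists.p_start.data.sum() - 1) < 1e-6
        assert abs(dists.p_end.data.sum() - 1) < 1e-6
        assert (dists.p_start.data >= 0).all()

    def test_no_kb_ignores_relations(self, rng):
        params = KrcParams.init(6, 3, seed=3)
        h = rng.normal(size=(5, 6))
        r1 = [rng.normal(size=3)]
        r2 = [rng.normal(size=3), rng.normal(size=3)]
        d1 = forward(h, r1, params, use_kb=False)
        d2 = forward(h, r2, params, use_kb=False)
        assert np.array_equal(d1.p_start.data, d2.p_start.data)
        assert np.array_equal(d1.p_end.data, d2.p_end.data)


class TestSpanLoss:
    def test_one_hot_correct_is_zero(self):
        ps = np.zeros(6)
        ps[2] = 1.0
        pe = np.zeros(6)
        pe[4] = 1.0
        d = SpanDistributions(Tensor(ps), Tensor(pe))
        assert float(span_loss(d, 2, 4).data) == 0.0

    def test_uniform_is_log_k(self):
        d = SpanDistributions(Tensor(np.full(10, 0.1)),
                              Tensor(np.full(10, 0.1)))
        assert abs(float(span_loss(d, 0, 0).data)
                   - math.log(10)) < 1e-12

    def test_batch_loss_is_mean(self, rng):
        params = KrcParams.init(4, 2, seed=4)
        ds = [fuse_and_predict(rng.normal(size=(5, 4)),
                               rng.normal(size=(5, 4)), params)
              for _ in range(2)]
        a = float(span_loss(ds[0], 1, 2).data)
        b = float(span_loss(ds[1], 0, 0).data)
        batch = float(batch_span_loss([(ds[0], 1, 2), (ds[1], 0, 0)]).data)
        assert abs(batch - (a + b) / 2) < 1e-12

    def test_out_of_range_gold_rejected(self):
        d = SpanDistributions(Tensor(np.full(4, .25)), Tensor(np.full(4, .25)))
        with pytest.raises(IndexError):
            span_loss(d, 4, 1)


class TestEncoderContract:
    @pytest.fixture
    def setup(self):
        tok = ToyTokenizer.from_texts(["aspirin causes headache nausea"])
        enc = TinyTransformerEncoder(
            TinyEncoderConfig(vocab_size=len(tok), d1=32, seed=5))
        return tok, enc

    def test_output_shape(self, setup):
        tok, enc = setup
        out = encode("what disease", "aspirin causes headache", enc,
                     tokenizer=tok)
        (w, hidden), = out
        assert hidden.shape == (w.k, 32)
        assert w.k >= 3  # [CLS] .. [SEP] .. [SEP]

    def test_deterministic_given_seed(self, setup):
        tok, _ = setup
        cfg = TinyEncoderConfig(vocab_size=len(tok), d1=32, seed=9)
        e1, e2 = TinyTransformerEncoder(cfg), TinyTransformerEncoder(cfg)
        ids = np.array([2, 4, 5, 3, 6, 3])
        seg = np.array([0, 0, 0, 0, 1, 1])
        assert np.array_equal(e1(ids, seg).data, e2(ids, seg).data)

    def test_windowing_overlap(self, setup):
        tok, _ = setup
        context = " ".join(["aspirin causes headache"] * 10)  # 30 tokens
        windows = pack_sequence(tok, "what disease", context,
                                max_length=16, stride=4)
        assert len(windows) >= 2
        # consecutive windows overlap by window size minus stride
        s0 = windows[0].context_spans
        s1 = windows[1].context_spans
        assert s1[0] == s0[4]  # stride 4 tokens forward

    def test_empty_context_rejected(self, setup):
        tok, enc = setup
        with pytest.raises(ValueError):
            encode("q", "", enc, tokenizer=tok)

    def test_gradient_step_decreases_loss(self, setup):
        tok, enc = setup
        params = KrcParams.init(32, 4, seed=6)
        ids = np.array([2, 4, 5, 3, 6, 7, 3])
        seg = np.array([0, 0, 0, 0, 1, 1, 1])
        rel = [np.zeros(4)]

        def loss_value():
            hidden = enc(ids, seg)
            dists = forward(hidden, rel, params, use_kb=True)
            return span_loss(dists, 4, 5)

        before = loss_value()
        before.backward()
        lr = 1e-2
        for p in enc.parameters() + params.parameters():
            if p.grad is not None:
                p.data -= lr * p.grad
        after = loss_value()
        assert float(after.data) < float(before.data)


@settings(deadline=None, max_examples=30, derandomize=True)
@given(st.integers(0, 2 ** 31 - 1))
def test_distributions_valid_for_random_inputs(seed):
    """p_start/p_end are probability vectors for any finite input."""
    rng = np.random.default_rng(seed)
    k = int(rng.integers(1, 9))
    d1, d2 = int(rng.integers(2, 12)), int(rng.integers(2, 6))
    params = KrcParams.init(d1, d2, seed=seed % 997)
    h = rng.normal(size=(k, d1)) * 10
    rels = [rng.normal(size=d2) for _ in range(int(rng.integers(1, 4)))]
    dists = forward(h, rels, params, use_kb=True)
    for p in (dists.p_start.data, dists.p_end.data):
        assert abs(p.sum() - 1) < 1e-6
        assert (p >= 0).all() and (p <= 1).all()
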