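"""Model forward-pass correctness: attention oracles, LSTM recurrence, invariants."""

import numpy as np
import pytest

from tsann.encoding import EncodedSequence
from tsann.model import (
    Batch,
    ModelConfig,
    TSANNModel,
    VariantSpec,
    attach_time_embedding,
    code_level_attention,
    cross_entropy,
    lstm_forward,
    pad_batch,
    visit_level_attention,
)

RNG = np.random.default_rng(7)


def _attention_oracle(C, W, b, u):
    """Straight-line recomputation of additive attention: tanh, dot, softmax, sum."""
    scores = [np.tanh(W @ c if W.ndim == 1 else c @ W + b) @ u for c in C]
    e = np.exp(scores - np.max(scores))
    a = e / e.sum()
    return sum(ai * ci for ai, ci in zip(a, C)), a


class TestCodeLevelAttention:
    def test_single_code_gets_full_weight(self):
        c = RNG.normal(size=(1, 4))
        v, a = code_level_attention(c, RNG.normal(size=(4, 4)), RNG.normal(size=4), RNG.normal(size=4))
        assert np.allclose(a, [1.0])
        assert np.allclose(v, c[0])

    def test_identical_codes_share_weight(self):
        c = np.tile(RNG.normal(size=4), (2, 1))
        _, a = code_level_attention(c, RNG.normal(size=(4, 4)), RNG.normal(size=4), RNG.normal(size=4))
        assert np.allclose(a, [0.5, 0.5])

    def test_matches_independent_oracle(self):
        C = RNG.normal(size=(3, 5))
        W, b, u = RNG.normal(size=(5, 5)), RNG.normal(size=5), RNG.normal(size=5)
        v, a = code_level_attention(C, W, b, u)
        v0, a0 = _attention_oracle(C, W, b, u)
        assert np.allclose(v, v0, atol=1e-6)
        assert np.allclose(a, a0, atol=1e-6)

    def test_empty_visit_rejected(self):
        with pytest.raises(ValueError):
            code_level_attention(np.empty((0, 4)), np.eye(4), np.zeros(4), np.zeros(4))


class TestTimeEmbedding:
    def test_gap_zero_appends_row_zero(self):
        T = RNG.normal(size=(365, 3))
        out = attach_time_embedding(np.ones(4), 0, T)
        assert np.allclose(out[4:], T[0])

    def test_ablation_appends_zeros(self):
        T = RNG.normal(size=(365, 3))
        out = attach_time_embedding(np.ones(4), 100, T, use_time=False)
        assert np.allclose(out[4:], 0.0)

    def test_step_variant_uses_rank(self):
        T = RNG.normal(size=(365, 3))
        out = attach_time_embedding(np.ones(4), 200, T, rank=2)
        assert np.allclose(out[4:], T[2])

    @pytest.mark.parametrize("gap", [-1, 365, 1000])
    def test_out_of_range_gap_rejected(self, gap):
        with pytest.raises(ValueError):
            attach_time_embedding(np.ones(4), gap, RNG.normal(size=(365, 3)))

    def test_output_length_is_dc_plus_m(self):
        T = RNG.normal(size=(365, 3))
        assert attach_time_embedding(RNG.normal(size=6), 10, T).shape == (9,)


class TestLstmForward:
    def test_zero_weights_fixed_point(self):
        xs = np.zeros((4, 3))
        hs = lstm_forward(xs, np.zeros((3, 8)), np.zeros((2, 8)), np.zeros(8), "tanh")
        assert np.allclose(hs, 0.0)

    def test_single_step_matches_hand_computation(self):
        H = 2
        x = RNG.normal(size=3)
        Wx, Wh, b = RNG.normal(size=(3, 4 * H)), RNG.normal(size=(H, 4 * H)), RNG.normal(size=4 * H)
        hs = lstm_forward(x[None], Wx, Wh, b, "tanh")
        z = x @ Wx + b  # zero initial state
        sig = lambda a: 1 / (1 + np.exp(-a))
        c = sig(z[:H]) * 0 + sig(z[H:2 * H]) * np.tanh(z[3 * H:])
        h = sig(z[2 * H:3 * H]) * np.tanh(c)
        assert np.allclose(hs[0], h, atol=1e-10)

    @pytest.mark.parametrize("act", ["tanh", "relu", "leaky_relu"])
    def test_matches_step_by_step_oracle(self, act):
        H, D, T = 3, 4, 3
        Wx, Wh, b = RNG.normal(size=(D, 4 * H)), RNG.normal(size=(H, 4 * H)), RNG.normal(size=4 * H)
        xs = RNG.normal(size=(T, D))
        hs = lstm_forward(xs, Wx, Wh, b, act)
        actf = {"tanh": np.tanh, "relu": lambda a: np.maximum(a, 0),
                "leaky_relu": lambda a: np.where(a > 0, a, 0.01 * a)}[act]
        sig = lambda a: 1 / (1 + np.exp(-a))
        h = np.zeros(H)
        c = np.zeros(H)
        for t in range(T):
            z = xs[t] @ Wx + h @ Wh + b
            f, i, o, g = sig(z[:H]), sig(z[H:2 * H]), sig(z[2 * H:3 * H]), actf(z[3 * H:])
            c = f * c + i * g
            h = o * actf(c)
            assert np.allclose(hs[t], h, atol=1e-6)


class TestVisitLevelAttention:
    def test_single_visit_identity(self):
        h = RNG.normal(size=(1, 4))
        r, b = visit_level_attention(h, RNG.normal(size=(4, 4)), RNG.normal(size=4), RNG.normal(size=4))
        assert np.allclose(b, [1.0]) and np.allclose(r, h[0])

    def test_identical_states_uniform_weights(self):
        h = np.tile(RNG.normal(size=4), (3, 1))
        _, b = visit_level_attention(h, RNG.normal(size=(4, 4)), RNG.normal(size=4), RNG.normal(size=4))
        assert np.allclose(b, 1 / 3)

    def test_matches_independent_oracle(self):
        Hs = RNG.normal(size=(4, 5))
        W, bp, u = RNG.normal(size=(5, 5)), RNG.normal(size=5), RNG.normal(size=5)
        r, b = visit_level_attention(Hs, W, bp, u)
        r0, b0 = _attention_oracle(Hs, W, bp, u)
        assert np.allclose(r, r0, atol=1e-6)
        assert np.allclose(b, b0, atol=1e-6)


def _toy_sequences():
    return [
        EncodedSequence("a", 1, [([2, 3], 10), ([4], 3), ([2, 5], 0)]),
        EncodedSequence("b", 0, [([3], 7), ([5, 6, 2], 0)]),
    ]


ALL_VARIANTS = ["MLP", "LSTM", "ALSTM", "TSANN_I", "TSANN_I_STEP", "TSANN_II"]


class TestPredict:
    @pytest.mark.parametrize("name", ALL_VARIANTS)
    def test_class_probabilities_sum_to_one(self, name):
        m = TSANNModel(VariantSpec(name), ModelConfig(6, 4, 5), 8, seed=1)
        for s in _toy_sequences():
            out = m.predict(s)
            assert abs(out.class_probs.sum() - 1.0) < 1e-9
            assert 0.0 < out.probability < 1.0

    def test_single_visit_tsann_ii_equals_tsann_i(self):
        # with one visit the visit-attention layer is the identity
        cfg = ModelConfig(6, 4, 5)
        m2 = TSANNModel(VariantSpec("TSANN_II"), cfg, 8, seed=3)
        m1 = TSANNModel(VariantSpec("TSANN_I"), cfg, 8, seed=3)
        m1.params = {k: m2.params[k] for k in m1.params}  # shared weights
        s = EncodedSequence("a", 1, [([2, 3, 4], 0)])
        assert abs(m2.predict(s).probability - m1.predict(s).probability) < 1e-12

    def test_code_permutation_invariance(self):
        m = TSANNModel(VariantSpec("TSANN_II"), ModelConfig(6, 4, 5), 8, seed=5)
        s1 = EncodedSequence("a", 1, [([2, 3, 4], 10), ([5, 6], 0)])
        s2 = EncodedSequence("a", 1, [([4, 2, 3], 10), ([6, 5], 0)])
        assert abs(m.predict(s1).probability - m.predict(s2).probability) < 1e-12

    @pytest.mark.parametrize("name", ALL_VARIANTS)
    def test_padding_invariance(self, name):
        # batching a short sequence with a long one pads it; P must not change
        m = TSANNModel(VariantSpec(name), ModelConfig(6, 4, 5), 12, seed=5)
        short = EncodedSequence("a", 1, [([2, 3], 10), ([4], 0)])
        long = EncodedSequence("b", 0, [([2, 3, 4, 5, 6, 7], 30), ([8, 9], 12),
                                        ([10, 11], 7), ([3], 2), ([4], 0)])
        alone = m.predict_proba([short])[0]
        padded = m.predict_proba([short, long])[0]
        assert abs(alone - padded) < 1e-12

    def test_attention_weights_normalized(self):
        m = TSANNModel(VariantSpec("TSANN_II"), ModelConfig(6, 4, 5), 8, seed=2)
        out = m.predict(_toy_sequences()[0])
        for a in out.alpha:
            assert abs(a.sum() - 1.0) < 1e-9
        assert abs(out.beta.sum() - 1.0) < 1e-9

    def test_lr_variant_rejected(self):
        with pytest.raises(ValueError):
            TSANNModel(VariantSpec("LR"), ModelConfig(4, 2, 3), 8)

    def test_unknown_variant_rejected(self):
        with pytest.raises(ValueError):
            VariantSpec("GRU")


@pytest.mark.parametrize("name", ALL_VARIANTS)
def test_gradients_match_finite_differences(name):
    """Analytic gradients agree with central differences for every parameter block."""
    cfg = ModelConfig(4, 3, 4, batch_norm=True)
    m = TSANNModel(VariantSpec(name), cfg, 8, seed=3)
    batch = pad_batch(_toy_sequences())

    def loss_value():
        logits, _ = m.forward(batch, training=False)
        return cross_entropy(logits, batch.labels, (1.0, 2.0))

    for p in m.params.values():
        p.grad = None
    loss_value().backward()
    eps = 1e-6
    for key, p in m.params.items():
        grad = p.grad if p.grad is not None else np.zeros_like(p.data)
        flat = p.data.reshape(-1)
        for i in range(0, flat.size, max(1, flat.size // 5)):  # sample entries per block
            old = flat[i]
            flat[i] = old + eps
            lp = loss_value().data
            flat[i] = old - eps
            lm = loss_value().data
            flat[i] = old
            assert abs((lp - lm) / (2 * eps) - grad.reshape(-1)[i]) < 1e-4, key
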