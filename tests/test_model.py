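"""Conv blocks, attention arithmetic, cross-attention fusion and gradients."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from xmodal_affect.model import (
    AttentionSpec,
    ConvBlockSpec,
    CrossAttentionClassifier,
    ModelConfig,
    branch_forward,
    classify,
    conv_block,
    cross_attention_fuse,
    identity_attention_params,
    init_attention_params,
    multi_head,
    scaled_dot_attention,
)


def tiny_model(seed=1, n_eeg=5, n_peri=4, n_classes=2):
    blocks = tuple(ConvBlockSpec(n_filters=3, kernel_size=3, pool_size=1,
                                 dropout_rate=0.0) for _ in range(3))
    att = AttentionSpec(n_heads=2, model_dim=4, key_dim=4, value_dim=4)
    config = ModelConfig(eeg_branch=blocks, peri_branch=blocks, attention=att,
                         n_classes=n_classes, fc_hidden=3, seed=seed)
    return CrossAttentionClassifier(config, n_eeg, n_peri)


class TestConvBlock:
    def test_pooling_halves_length(self, rng):
        spec = ConvBlockSpec(n_filters=4, kernel_size=3, pool_size=2, dropout_rate=0.0)
        out = conv_block(rng.standard_normal((16, 5)), spec)
        assert out.shape == (8, 4)

    def test_zero_input_zero_output(self):
        spec = ConvBlockSpec(n_filters=2, kernel_size=3, pool_size=1, dropout_rate=0.0)
        params = {"W": np.ones((3, 3, 2)), "b": np.zeros(2)}  # no BN -> identity norm
        out = conv_block(np.zeros((8, 3)), spec, mode="eval", params=params)
        np.testing.assert_array_equal(out, 0.0)

    def test_pointwise_kernel_matches_direct_computation(self, rng):
        w, b = 1.7, -0.3
        spec = ConvBlockSpec(n_filters=1, kernel_size=1, pool_size=1, dropout_rate=0.0)
        x = rng.standard_normal((10, 1))
        out = conv_block(x, spec, params={"W": np.array([[[w]]]), "b": np.array([b])})
        np.testing.assert_allclose(out, np.maximum(w * x + b, 0.0), rtol=1e-12)

    def test_input_shorter_than_kernel_errors(self):
        spec = ConvBlockSpec(kernel_size=5)
        with pytest.raises(ValueError, match="kernel"):
            conv_block(np.zeros((3, 2)), spec)


class TestBranchForward:
    def test_three_poolings(self, rng):
        blocks = [ConvBlockSpec(n_filters=4, pool_size=2, dropout_rate=0.0)] * 3
        out = branch_forward(rng.standard_normal((16, 3)), blocks)
        assert out.shape == (2, 4)

    def test_eval_deterministic(self, rng):
        blocks = [ConvBlockSpec(n_filters=4, pool_size=2, dropout_rate=0.3)] * 3
        x = rng.standard_normal((16, 3))
        np.testing.assert_array_equal(branch_forward(x, blocks, seed=7),
                                      branch_forward(x, blocks, seed=7))

    def test_too_short_sequence_names_block(self, rng):
        blocks = [ConvBlockSpec(n_filters=2, pool_size=2, dropout_rate=0.0)] * 3
        with pytest.raises(ValueError, match="block 2"):
            branch_forward(rng.standard_normal((7, 3)), blocks)


class TestScaledDotAttention:
    def test_single_key_returns_value_row(self, rng):
        V = rng.standard_normal((1, 3))
        out = scaled_dot_attention(rng.standard_normal((4, 2)), rng.standard_normal((1, 2)), V)
        np.testing.assert_allclose(out, np.repeat(V, 4, axis=0))

    def test_equal_values_collapse(self, rng):
        v = rng.standard_normal(3)
        V = np.tile(v, (5, 1))
        out = scaled_dot_attention(rng.standard_normal((2, 4)), rng.standard_normal((5, 4)), V)
        np.testing.assert_allclose(out, np.tile(v, (2, 1)))

    def test_hand_computed_example(self):
        out, weights = scaled_dot_attention(np.array([[1.0, 0.0]]), np.eye(2), np.eye(2),
                                            return_weights=True)
        e = np.exp(1 / np.sqrt(2))
        expected = np.array([e / (e + 1), 1 / (e + 1)])
        np.testing.assert_allclose(weights[0], expected, atol=1e-10)
        np.testing.assert_allclose(out[0], expected, atol=1e-10)

    def test_dimension_mismatch(self):
        with pytest.raises(ValueError):
            scaled_dot_attention(np.zeros((2, 3)), np.zeros((2, 4)), np.zeros((2, 2)))

    def test_rows_are_distributions(self, rng):
        _, w = scaled_dot_attention(rng.standard_normal((5, 4)), rng.standard_normal((6, 4)),
                                    rng.standard_normal((6, 2)), return_weights=True)
        assert np.all(w >= 0)
        np.testing.assert_allclose(w.sum(axis=1), 1.0)


class TestMultiHead:
    def test_single_head_identity_reduces_to_sdpa(self, rng):
        spec = AttentionSpec(n_heads=1, model_dim=3, key_dim=3, value_dim=3)
        params = identity_attention_params(spec, 3)
        Q, K, V = (rng.standard_normal((4, 3)) for _ in range(3))
        np.testing.assert_allclose(multi_head(Q, K, V, spec, params),
                                   scaled_dot_attention(Q, K, V), rtol=1e-12)

    def test_output_width_is_model_dim(self, rng):
        spec = AttentionSpec(n_heads=4, model_dim=32, key_dim=32, value_dim=32)
        params = init_attention_params(spec, 7, 9, rng)
        out = multi_head(rng.standard_normal((5, 7)), rng.standard_normal((6, 9)),
                         rng.standard_normal((6, 9)), spec, params)
        assert out.shape == (5, 32)

    def test_joint_kv_permutation_invariance(self, rng):
        spec = AttentionSpec(n_heads=2, model_dim=6, key_dim=4, value_dim=4)
        params = init_attention_params(spec, 5, 5, rng)
        Q = rng.standard_normal((3, 5))
        K = rng.standard_normal((6, 5))
        V = rng.standard_normal((6, 5))
        perm = rng.permutation(6)
        np.testing.assert_allclose(multi_head(Q, K, V, spec, params),
                                   multi_head(Q, K[perm], V[perm], spec, params),
                                   rtol=1e-10)

    def test_indivisible_head_dims_rejected(self):
        with pytest.raises(ValueError, match="divisible"):
            AttentionSpec(n_heads=3, model_dim=8, key_dim=8, value_dim=8)

    def test_agrees_with_brute_force(self, rng):
        """Independent dense per-head evaluation on random small instances."""
        for _ in range(25):
            h = rng.integers(1, 4)
            dk, dv = h * rng.integers(1, 3), h * rng.integers(1, 3)
            spec = AttentionSpec(n_heads=int(h), model_dim=int(rng.integers(2, 8)),
                                 key_dim=int(dk), value_dim=int(dv))
            m, n, d = (int(rng.integers(1, 5)) for _ in range(3))
            d += 1
            Q, K, V = rng.standard_normal((m, d)), rng.standard_normal((n, d)), rng.standard_normal((n, d))
            params = init_attention_params(spec, d, d, rng)
            heads = []
            for i in range(spec.n_heads):
                Qh, Kh, Vh = Q @ params["Wq"][i], K @ params["Wk"][i], V @ params["Wv"][i]
                S = Qh @ Kh.T / np.sqrt(Qh.shape[1])
                E = np.exp(S - S.max(axis=1, keepdims=True))
                A = E / E.sum(axis=1, keepdims=True)
                heads.append(A @ Vh)
            expected = np.concatenate(heads, axis=1) @ params["Wo"]
            np.testing.assert_allclose(multi_head(Q, K, V, spec, params), expected,
                                       rtol=1e-6, atol=1e-12)

    def test_convex_hull_bounds(self, rng):
        """Each head's output rows lie within the projected-V coordinate bounds."""
        spec = AttentionSpec(n_heads=2, model_dim=4, key_dim=4, value_dim=4)
        params = init_attention_params(spec, 3, 3, rng)
        K = rng.standard_normal((5, 3))
        V = rng.standard_normal((5, 3))
        for i in range(2):
            Vh = V @ params["Wv"][i]
            out = scaled_dot_attention(rng.standard_normal((4, 2)),
                                       (K @ params["Wk"][i]), Vh)
            assert np.all(out <= Vh.max(axis=0) + 1e-12)
            assert np.all(out >= Vh.min(axis=0) - 1e-12)


class TestCrossAttentionFuse:
    def test_symmetric_inputs_give_identical_halves(self, rng):
        spec = AttentionSpec(n_heads=2, model_dim=6, key_dim=4, value_dim=4)
        seq = rng.standard_normal((4, 5))
        params = init_attention_params(spec, 5, 5, rng)
        fused = cross_attention_fuse(seq, seq, spec, params_eeg=params, params_peri=params)
        np.testing.assert_allclose(fused.attention_eeg, fused.attention_peri)

    def test_output_width(self, rng):
        spec = AttentionSpec(n_heads=2, model_dim=8, key_dim=4, value_dim=4)
        fused = cross_attention_fuse(rng.standard_normal((3, 5)),
                                     rng.standard_normal((3, 4)), spec)
        assert fused.values.shape == (3, 16)

    def test_empty_sequence_rejected(self, rng):
        spec = AttentionSpec(n_heads=1, model_dim=4, key_dim=4, value_dim=4)
        with pytest.raises(ValueError, match="non-empty"):
            cross_attention_fuse(np.empty((0, 4)), rng.standard_normal((3, 4)), spec)

    def test_matches_brute_force_on_toy_sequences(self, rng):
        """Two-window toy case against an explicit evaluation of the equations."""
        spec = AttentionSpec(n_heads=1, model_dim=2, key_dim=2, value_dim=2)
        eeg = np.array([[1.0, 0.0], [0.0, 1.0]])
        peri = np.array([[0.5, 0.5], [1.0, -1.0]])
        eye = np.eye(2)
        params = {"Wq": eye[None], "Wk": eye[None], "Wv": eye[None], "Wo": eye.copy()}
        fused = cross_attention_fuse(eeg, peri, spec, params_eeg=params, params_peri=params)

        def sdpa(Q, K, V):
            S = Q @ K.T / np.sqrt(2)
            E = np.exp(S - S.max(axis=1, keepdims=True))
            return (E / E.sum(axis=1, keepdims=True)) @ V

        np.testing.assert_allclose(fused.attention_eeg, sdpa(peri, eeg, eeg), rtol=1e-12)
        np.testing.assert_allclose(fused.attention_peri, sdpa(eeg, peri, peri), rtol=1e-12)


class TestClassify:
    def test_probabilities_sum_to_one(self, rng):
        probs = classify(rng.standard_normal((4, 6)), n_classes=3)
        assert probs.sum() == pytest.approx(1.0, abs=1e-6)

    def test_zero_weights_uniform(self, rng):
        params = {"W1": np.zeros((6, 4)), "b1": np.zeros(4),
                  "W2": np.zeros((4, 3)), "b2": np.zeros(3)}
        probs = classify(rng.standard_normal((4, 6)), 3, params=params)
        np.testing.assert_allclose(probs, 1 / 3)

    def test_argmax_shift_invariant(self, rng):
        x = rng.standard_normal((4, 6))
        params = {"W1": rng.standard_normal((6, 4)), "b1": rng.standard_normal(4),
                  "W2": rng.standard_normal((4, 3)), "b2": rng.standard_normal(3)}
        base = classify(x, 3, params=params)
        shifted_params = dict(params, b2=params["b2"] + 5.0)
        shifted = classify(x, 3, params=shifted_params)
        assert np.argmax(base) == np.argmax(shifted)


class TestFullModel:
    def test_eval_forward_deterministic(self, rng):
        m = tiny_model()
        Xe, Xp = rng.standard_normal((3, 4, 5)), rng.standard_normal((3, 4, 4))
        np.testing.assert_array_equal(m.predict_proba(Xe, Xp), m.predict_proba(Xe, Xp))

    def test_model_config_requires_three_blocks(self):
        blocks2 = tuple(ConvBlockSpec() for _ in range(2))
        blocks3 = tuple(ConvBlockSpec() for _ in range(3))
        with pytest.raises(ValueError, match="3 conv blocks"):
            ModelConfig(eeg_branch=blocks2, peri_branch=blocks3,
                        attention=AttentionSpec(), n_classes=2)

    def test_gradients_match_central_differences(self, rng):
        """Analytic backprop through the full loss vs numerical differentiation."""
        m = tiny_model(seed=1)
        Xe = rng.standard_normal((3, 4, 5))
        Xp = rng.standard_normal((3, 4, 4))
        y = np.array([0, 1, 0])
        lam = 1e-3
        probs, cache = m.forward(Xe, Xp, mode="train", update_stats=False)
        grads = m.backward(cache, y, lam)
        h = 1e-6
        for name, P in m.params.items():
            flat = P.reshape(-1)
            for k in range(0, flat.size, max(1, flat.size // 4)):
                orig = flat[k]
                flat[k] = orig + h
                p1, _ = m.forward(Xe, Xp, mode="train", update_stats=False)
                l1 = m.loss(p1, y, lam)
                flat[k] = orig - h
                p2, _ = m.forward(Xe, Xp, mode="train", update_stats=False)
                l2 = m.loss(p2, y, lam)
                flat[k] = orig
                num = (l1 - l2) / (2 * h)
                ana = grads[name].reshape(-1)[k]
                assert abs(num - ana) <= 1e-4 * max(1.0, abs(num) + abs(ana)), \
                    f"{name}[{k}]: numeric {num} vs analytic {ana}"
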