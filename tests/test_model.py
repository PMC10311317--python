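"""Layer-by-layer behavior of the architecture and its composition."""

import numpy as np
import pytest

from motifnet import autodiff as ad
from motifnet.model import ModelConfig, SequenceModel, mse_loss
from motifnet.motifs import to_kernel_bank
from motifnet.simulate import random_library
from tests.conftest import one_hot


def build(lib, L, c=2, seed=0, **cfg):
    bank = to_kernel_bank(lib)
    config = ModelConfig(m=len(lib), L=L, c=c, **cfg)
    return SequenceModel.build(config, bank, seed=seed)


class TestTransformInput:
    def test_zero_embedding_is_identity(self, degenerate_library):
        model = build(degenerate_library, L=8)
        x = ad.constant(one_hot("ACGTACGT")[None])
        out = model.transform_input(x)
        assert np.array_equal(out.data, x.data)

    def test_embedding_broadcasts_over_rows(self, degenerate_library):
        model = build(degenerate_library, L=8)
        model.params["embedding"].data[...] = 1.0
        x = ad.constant(one_hot("ACGTACGT")[None])
        out = model.transform_input(x)
        assert np.allclose(out.data, x.data + 1.0)

    def test_zeroed_attention_projection_passes_residual(self, degenerate_library):
        model = build(degenerate_library, L=8, use_attention=True)
        model.params["embedding"].data[...] = 0.3  # nonzero pre-attention shift
        x = ad.constant(one_hot("ACGTACGT")[None])
        out = model.transform_input(x)
        # attn_out starts at zero, so the block reduces to the raw input
        assert np.allclose(out.data, x.data)


class TestMatchAndCalibrate:
    def test_zero_scale_and_offset_give_half(self, degenerate_library):
        model = build(degenerate_library, L=10)
        model.params["scale"].data[...] = 0.0
        model.params["offset"].data[...] = 0.0
        probs = model.match_and_calibrate(ad.constant(one_hot("ACGTACGTAC")[None]))
        assert np.allclose(probs.data, 0.5)

    def test_consensus_match_hits_max_score(self, degenerate_library):
        model = build(degenerate_library, L=9, strands="forward")
        bank = to_kernel_bank(degenerate_library)
        a = model.params["scale"].data
        b = model.params["offset"].data
        seq = "ACTAAAAAA"  # motif 'ACT' at offset 0
        probs = model.match_and_calibrate(ad.constant(one_hot(seq)[None]))
        smax = bank.max_scores()[0]
        expected = 1.0 / (1.0 + np.exp(-(a[0] * smax + b[0])))
        assert probs.data[0, 0, 0] == pytest.approx(expected, rel=1e-12)

    def test_palindromic_kernel_equal_on_both_strands(self, rng):
        from motifnet.motifs import PWM, MotifLibrary

        half = rng.dirichlet(np.ones(4), size=3)
        pal = np.vstack([half, half[::-1, ::-1]])  # reverse-complement palindrome
        lib = MotifLibrary([PWM("pal", pal)])
        model = build(lib, L=20, seed=1)
        x = np.zeros((1, 4, 20))
        cols = rng.integers(0, 4, size=20)
        x[0, cols, np.arange(20)] = 1.0
        # both-strand max equals forward scan for a palindrome
        both = model.match_and_calibrate(ad.constant(x)).data
        model.config = ModelConfig(m=1, L=20, c=2, strands="forward")
        fwd = model.match_and_calibrate(ad.constant(x)).data
        assert np.allclose(both, fwd, atol=1e-12)

    def test_reverse_complement_site_scores_as_forward(self, degenerate_library):
        model = build(degenerate_library, L=9)
        fwd = model.match_and_calibrate(ad.constant(one_hot("ACTAAAAAA")[None])).data
        rc = model.match_and_calibrate(ad.constant(one_hot("AGTAAAAAA")[None])).data
        # 'AGT' is the reverse complement of 'ACT': same best score at offset 0
        assert rc[0, 0, 0] == pytest.approx(fwd[0, 0, 0], rel=1e-12)


class TestTrainablePool:
    def test_zero_alpha_is_average_pooling(self, degenerate_library):
        model = build(degenerate_library, L=10)
        probs = ad.constant(np.array([[[0.1], [0.9]]]))  # (n=1, L'=2, m=1)
        model.params["pool"].data[...] = 0.0
        pooled, weights = model.trainable_pool(probs)
        assert np.allclose(weights.data, 0.5)
        assert pooled.data[0, 0] == pytest.approx(0.5)

    def test_unit_alpha_softmax_values(self, degenerate_library):
        model = build(degenerate_library, L=10)
        probs = ad.constant(np.array([[[0.0], [1.0]]]))
        model.params["pool"].data[...] = 1.0
        pooled, weights = model.trainable_pool(probs)
        e = np.e
        assert weights.data[0, :, 0] == pytest.approx([1 / (1 + e), e / (1 + e)])
        assert pooled.data[0, 0] == pytest.approx(e / (1 + e), abs=1e-6)

    def test_large_alpha_approaches_max(self, degenerate_library):
        model = build(degenerate_library, L=10)
        probs = ad.constant(np.array([[[0.1], [0.9]]]))
        model.params["pool"].data[...] = 1000.0
        pooled, _ = model.trainable_pool(probs)
        assert pooled.data[0, 0] == pytest.approx(0.9, abs=1e-6)

    def test_weight_rows_sum_to_one_and_pool_is_convex(self, rng, degenerate_library):
        model = build(degenerate_library, L=10)
        probs = ad.constant(rng.uniform(size=(3, 8, 3)))
        model.params["pool"].data[...] = rng.normal(size=3)
        pooled, weights = model.trainable_pool(probs)
        assert np.allclose(weights.data.sum(axis=1), 1.0, atol=1e-6)
        assert np.all(pooled.data <= probs.data.max(axis=1) + 1e-12)
        assert np.all(pooled.data >= probs.data.min(axis=1) - 1e-12)

    def test_pooled_nondecreasing_in_alpha(self, rng, degenerate_library):
        model = build(degenerate_library, L=10)
        row = rng.uniform(size=(1, 12, 1))
        last = -np.inf
        for alpha in np.linspace(0.0, 20.0, 15):
            model.params["pool"].data[...] = alpha
            pooled, _ = model.trainable_pool(ad.constant(np.tile(row, (1, 1, 3))))
            val = pooled.data[0, 0]
            assert val >= last - 1e-12
            last = val


class TestInteractionGate:
    def test_zero_matrix_halves_input(self, degenerate_library):
        model = build(degenerate_library, L=10, use_interaction=True)
        pooled = ad.constant(np.array([[0.2, 0.4, 0.8]]))
        out = model.interaction_gate(pooled)
        assert np.allclose(out.data, 0.5 * pooled.data)

    def test_zero_input_absorbed(self, degenerate_library):
        model = build(degenerate_library, L=10, use_interaction=True)
        model.params["interaction"].data[...] = np.random.default_rng(0).normal(
            size=(3, 3)
        )
        out = model.interaction_gate(ad.constant(np.zeros((1, 3))))
        assert np.allclose(out.data, 0.0)

    def test_hand_computed_gate(self, soft_library):
        model = build(soft_library, L=10, use_interaction=True)
        model.params["interaction"].data[...] = np.array([[0.0, 10.0], [0.0, 0.0]])
        pooled = ad.constant(np.array([[0.5, 1.0]]))
        out = model.interaction_gate(pooled)
        sig10 = 1.0 / (1.0 + np.exp(-10.0))
        assert out.data[0] == pytest.approx([0.5 * sig10, 0.5], rel=1e-9)

    def test_disabled_gate_is_identity(self, degenerate_library):
        model = build(degenerate_library, L=10, use_interaction=False)
        pooled = ad.constant(np.array([[0.2, 0.4, 0.8]]))
        assert model.interaction_gate(pooled) is pooled


class TestPredictHead:
    def test_zero_coefficients_return_intercept(self, soft_library):
        model = build(soft_library, L=10, c=2)
        model.params["intercept"].data[...] = [1.0, 2.0]
        out = model.predict_head(ad.constant(np.zeros((3, 2))))
        assert np.allclose(out.data, [[1.0, 2.0]] * 3)

    def test_hand_computed_linear_readout(self, soft_library):
        model = build(soft_library, L=10, c=1)
        model.params["coef"].data[...] = [[1.0, -2.0]]
        model.params["intercept"].data[...] = [0.1]
        out = model.predict_head(ad.constant(np.array([[0.5, 0.25]])))
        assert out.data[0, 0] == pytest.approx(0.1)


class TestForward:
    def test_all_zero_params_predict_intercept(self, degenerate_library, rng):
        model = build(degenerate_library, L=12, c=2)
        for name in ("scale", "offset", "coef"):
            model.params[name].data[...] = 0.0
        model.params["intercept"].data[...] = [3.0, -1.0]
        X = np.stack([one_hot("ACGTACGTACGT") for _ in range(4)])
        assert np.allclose(model.predict(X), [[3.0, -1.0]] * 4)

    def test_trace_satisfies_layer_invariants(self, soft_library):
        model = build(soft_library, L=15, use_interaction=True, seed=3)
        trace = model.trace(one_hot("ACGTACGTACGTACG"))
        assert trace.match_probs.shape[1] == 15 - soft_library.max_width + 1
        assert np.all((trace.match_probs > 0) & (trace.match_probs < 1))
        assert np.allclose(trace.pool_weights.sum(axis=1), 1.0, atol=1e-6)
        assert trace.prediction.shape == (2,)

    def test_batch_permutation_equivariance(self, soft_library, rng):
        model = build(soft_library, L=12, seed=4)
        for t in model.params.tensors.values():
            t.data += rng.normal(scale=0.2, size=t.data.shape)
        X = np.zeros((5, 4, 12))
        X[np.arange(5)[:, None], rng.integers(0, 4, (5, 12)), np.arange(12)] = 1.0
        perm = rng.permutation(5)
        assert np.allclose(model.predict(X)[perm], model.predict(X[perm]), atol=1e-12)

    def test_alpha_zero_equals_explicit_average_pooling(self, soft_library, rng):
        model = build(soft_library, L=14, seed=5)
        for name in ("scale", "offset", "coef", "intercept"):
            model.params[name].data += rng.normal(
                scale=0.3, size=model.params[name].data.shape
            )
        model.params["pool"].data[...] = 0.0
        X = np.zeros((3, 4, 14))
        X[np.arange(3)[:, None], rng.integers(0, 4, (3, 14)), np.arange(14)] = 1.0
        got = model.predict(X)
        # oracle: replace learned pooling by an explicit mean over positions
        probs = model.match_and_calibrate(
            model.transform_input(ad.constant(X))
        ).data
        pooled = probs.mean(axis=1)
        B = model.params["coef"].data
        expected = pooled @ B.T + model.params["intercept"].data
        assert np.allclose(got, expected, atol=1e-6)


class TestGradients:
    def test_backprop_matches_central_differences(self, rng):
        """Analytic gradients of the full model (every parameter group)
        agree with a finite-difference oracle on a tiny instance."""
        lib = random_library(3, width=5, seed=1)
        bank = to_kernel_bank(lib)
        config = ModelConfig(m=3, L=20, c=2, use_attention=True,
                             use_interaction=True, kernels_frozen=False)
        model = SequenceModel.build(config, bank, seed=2)
        for t in model.params.tensors.values():
            t.data += rng.normal(scale=0.3, size=t.data.shape)
        X = np.zeros((4, 4, 20))
        X[np.arange(4)[:, None], rng.integers(0, 4, (4, 20)), np.arange(20)] = 1.0
        Y = rng.normal(size=(4, 2))

        loss = mse_loss(model.forward(X), Y)
        loss.backward()
        eps = 1e-6
        for name, tensor in model.params.items():
            if not tensor.requires_grad:
                continue
            flat = tensor.data.ravel()
            numeric = np.zeros_like(flat)
            for k in range(flat.size):
                orig = flat[k]
                flat[k] = orig + eps
                lp = float(mse_loss(model.forward(X), Y).data)
                flat[k] = orig - eps
                lm = float(mse_loss(model.forward(X), Y).data)
                flat[k] = orig
                numeric[k] = (lp - lm) / (2 * eps)
            numeric = numeric.reshape(tensor.data.shape)
            rel = np.abs(tensor.grad - numeric) / np.maximum(np.abs(numeric), 1e-6)
            assert rel.max() < 1e-4, f"gradient mismatch for {name}: {rel.max():.2e}"


class TestPersistence:
    def test_save_load_roundtrip(self, tmp_path, soft_library, rng):
        model = build(soft_library, L=12, use_interaction=True, seed=6)
        for t in model.params.tensors.values():
            t.data += rng.normal(scale=0.1, size=t.data.shape)
        X = np.zeros((2, 4, 12))
        X[np.arange(2)[:, None], rng.integers(0, 4, (2, 12)), np.arange(12)] = 1.0
        before = model.predict(X)
        path = tmp_path / "model.npz"
        model.save(path)
        loaded = SequenceModel.load(path)
        assert loaded.config == model.config
        assert np.allclose(loaded.predict(X), before, atol=1e-12)
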