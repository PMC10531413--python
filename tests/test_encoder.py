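"""Patch decomposition, token embedding, attention blocks and the
classification head, checked against straight-line numpy oracles."""

import numpy as np
import pytest

from fuzzyvit.autodiff import Tensor
from fuzzyvit.encoder import (
    EncoderConfig,
    FRPETransformer,
    patchify,
    unpatchify,
)
from fuzzyvit.encoder import _batch_patchify
from fuzzyvit.frpe import smoothed_bias_matrix
from fuzzyvit.harness import _cross_entropy

TINY = EncoderConfig(input_size=16, patch_size=8, embed_dim=8, depth=1, n_heads=2)


class TestPatchify:
    def test_unit_patches_enumerate_pixels(self):
        grid = patchify(np.array([[1.0, 2.0], [3.0, 4.0]]), 1)
        np.testing.assert_array_equal(grid.patches, [[1], [2], [3], [4]])

    def test_single_whole_image_patch(self):
        grid = patchify(np.array([[1.0, 2.0], [3.0, 4.0]]), 2)
        np.testing.assert_array_equal(grid.patches, [[1, 2, 3, 4]])

    @pytest.mark.parametrize("size,k", [(4, 2), (8, 4), (12, 3), (6, 6)])
    def test_round_trip_is_exact(self, size, k):
        image = np.arange(size * size, dtype=float).reshape(size, size) / (size * size)
        grid = patchify(image, k)
        np.testing.assert_array_equal(unpatchify(grid.patches, k, size, size), image)

    def test_non_divisible_dimensions_rejected(self):
        with pytest.raises(ValueError):
            patchify(np.zeros((5, 4)), 2)

    def test_non_finite_rejected(self):
        with pytest.raises(ValueError):
            patchify(np.full((4, 4), np.nan), 2)

    def test_batch_path_agrees_with_single(self):
        rng = np.random.default_rng(0)
        images = rng.random((3, 8, 8))
        batched = _batch_patchify(images, 4)
        for i in range(3):
            np.testing.assert_array_equal(batched[i], patchify(images[i], 4).patches)


class TestEmbed:
    def test_identity_projection_recovers_patches(self):
        cfg = EncoderConfig(input_size=16, patch_size=4, embed_dim=16, depth=1, n_heads=2)
        model = FRPETransformer(cfg, seed=0)
        model.params["embed.Wx"].data = np.eye(16)
        model.params["embed.cls"].data[:] = 0.0
        patches = np.random.default_rng(1).random((2, cfg.n_patches, 16))
        tokens = model.embed(Tensor(patches)).data
        np.testing.assert_allclose(tokens[:, 0, :], 0.0)
        np.testing.assert_allclose(tokens[:, 1:, :], patches)

    def test_zero_projection_isolates_position_term(self):
        cfg = EncoderConfig(
            input_size=16, patch_size=8, embed_dim=8, depth=1, n_heads=2, use_absolute_pos=True
        )
        model = FRPETransformer(cfg, seed=0)
        model.params["embed.Wx"].data[:] = 0.0
        patches = np.random.default_rng(2).random((1, cfg.n_patches, 64))
        tokens = model.embed(Tensor(patches)).data
        expected = model.params["embed.E"].data @ model.params["embed.We"].data
        np.testing.assert_allclose(tokens[0, 1:, :], expected, atol=1e-12)

    def test_matches_independent_matmul_oracle(self):
        cfg = EncoderConfig(
            input_size=16, patch_size=8, embed_dim=8, depth=1, n_heads=2, use_absolute_pos=True
        )
        model = FRPETransformer(cfg, seed=3)
        patches = np.random.default_rng(4).random((2, cfg.n_patches, 64))
        tokens = model.embed(Tensor(patches)).data
        oracle = np.einsum("bmk,kd->bmd", patches, model.params["embed.Wx"].data)
        oracle += model.params["embed.E"].data @ model.params["embed.We"].data
        np.testing.assert_allclose(tokens[:, 1:, :], oracle, atol=1e-12)


class TestEncoderBlock:
    def test_zero_value_and_mlp_paths_give_identity(self):
        model = FRPETransformer(TINY, seed=0)
        for name in ("attn.Wv", "attn.bv", "attn.bo", "mlp.W2", "mlp.b2"):
            model.params[f"block0.{name}"].data[:] = 0.0
        x = Tensor(np.random.default_rng(5).normal(size=(1, 3, 8)))
        out = model._block(x, 0, None)
        np.testing.assert_allclose(out.data, x.data, atol=1e-12)

    def test_matches_straight_line_oracle(self):
        """Re-derive one block output by materializing LN, Q, K, V, the bias
        gather, softmax and the MLP with plain numpy."""
        model = FRPETransformer(TINY, seed=7)
        x = np.random.default_rng(8).normal(size=(1, 5, 8))
        got = model._block(Tensor(x), 0, model.attention_bias()).data

        p = {k: v.data for k, v in model.params.items()}

        def ln(a, g, b):
            mu = a.mean(-1, keepdims=True)
            var = ((a - mu) ** 2).mean(-1, keepdims=True)
            return (a - mu) / np.sqrt(var + 1e-6) * g + b

        h = ln(x, p["block0.ln1.g"], p["block0.ln1.b"])
        nh, dh = 2, 4
        q = (h @ p["block0.attn.Wq"] + p["block0.attn.bq"]).reshape(1, 5, nh, dh)
        k = (h @ p["block0.attn.Wk"] + p["block0.attn.bk"]).reshape(1, 5, nh, dh)
        v = (h @ p["block0.attn.Wv"] + p["block0.attn.bv"]).reshape(1, 5, nh, dh)
        out = np.empty((1, 5, nh, dh))
        for head in range(nh):
            logits = q[0, :, head] @ k[0, :, head].T / np.sqrt(dh)
            smoothed = smoothed_bias_matrix(model.bias_table, model.index, head).values
            bias = np.full((5, 5), p["frpe.cls_bias"][head])
            bias[1:, 1:] = p["frpe.gain"][head] * smoothed
            logits = logits + bias
            e = np.exp(logits - logits.max(-1, keepdims=True))
            attn = e / e.sum(-1, keepdims=True)
            out[0, :, head] = attn @ v[0, :, head]
        x2 = x + (out.reshape(1, 5, 8) @ p["block0.attn.Wo"] + p["block0.attn.bo"])
        h2 = ln(x2, p["block0.ln2.g"], p["block0.ln2.b"])
        from scipy.special import erf

        pre = h2 @ p["block0.mlp.W1"] + p["block0.mlp.b1"]
        act = pre * 0.5 * (1 + erf(pre / np.sqrt(2)))
        expected = x2 + act @ p["block0.mlp.W2"] + p["block0.mlp.b2"]
        np.testing.assert_allclose(got, expected, atol=1e-10)

    def test_nan_propagation_raises_with_block_index(self):
        model = FRPETransformer(TINY, seed=0)
        model.params["block0.mlp.b2"].data[:] = np.nan
        with pytest.raises(FloatingPointError, match="block 0"):
            model.forward(np.random.default_rng(0).random((1, 16, 16)))


class TestPositionalInformation:
    @staticmethod
    def permuted_image(image, patch_size, perm):
        grid = patchify(image, patch_size)
        n = image.shape[0]
        return unpatchify(grid.patches[perm], patch_size, n, n)

    def test_permutation_equivariance_without_position_encoding(self):
        cfg = EncoderConfig(
            input_size=16, patch_size=8, embed_dim=8, depth=2, n_heads=2,
            use_frpe=False, use_absolute_pos=False,
        )
        model = FRPETransformer(cfg, seed=2)
        rng = np.random.default_rng(3)
        image = rng.random((16, 16))
        perm = rng.permutation(cfg.n_patches)
        a = model.forward(image[None]).data
        b = model.forward(self.permuted_image(image, 8, perm)[None]).data
        np.testing.assert_allclose(a, b, atol=1e-9)

    def test_fuzzy_bias_makes_position_live(self):
        cfg = EncoderConfig(input_size=16, patch_size=4, embed_dim=8, depth=2, n_heads=2)
        model = FRPETransformer(cfg, seed=2)
        # spread the raw table so the smoothed bias is far from uniform, and
        # open the head so class logits reflect the features
        model.params["frpe.raw"].data *= 100.0
        model.params["head.W"].data = np.random.default_rng(0).normal(size=(8, 2))
        rng = np.random.default_rng(3)
        image = rng.random((16, 16))
        perm = rng.permutation(cfg.n_patches)
        a = model.forward(image[None]).data
        b = model.forward(self.permuted_image(image, 4, perm)[None]).data
        assert np.abs(a - b).max() > 1e-6


class TestClassify:
    def test_fresh_model_is_maximally_uncertain(self):
        model = FRPETransformer(TINY, seed=0)
        pred = model.classify(np.random.default_rng(0).random((16, 16)))
        assert pred.probs == (0.5, 0.5)

    def test_probabilities_sum_to_one(self):
        model = FRPETransformer(TINY, seed=1)
        model.params["head.W"].data = np.random.default_rng(2).normal(size=(8, 2))
        probs = model.predict_proba(np.random.default_rng(3).random((4, 16, 16)))
        np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-9)
        assert np.all(probs >= 0)

    def test_forward_is_deterministic(self):
        model = FRPETransformer(TINY, seed=4)
        image = np.random.default_rng(5).random((2, 16, 16))
        np.testing.assert_array_equal(model.forward(image).data, model.forward(image).data)

    def test_wrong_input_size_rejected(self):
        model = FRPETransformer(TINY, seed=0)
        with pytest.raises(ValueError):
            model.forward(np.zeros((1, 32, 32)))


class TestGradients:
    def test_fuzzy_coefficient_gradient_matches_finite_differences(self):
        """Autodiff gradient of the loss w.r.t. the fuzzy coefficients w
        agrees with central differences on a small model."""
        model = FRPETransformer(TINY, seed=6)
        rng = np.random.default_rng(7)
        images = rng.random((2, 16, 16))
        y = np.array([0, 1])
        model.params["head.W"].data = rng.normal(size=(8, 2))

        loss = _cross_entropy(model.forward(images), y)
        for t in model.params.values():
            t.grad = None
        loss.backward()
        coeff = model.params["frpe.coeff_raw"]
        analytic = coeff.grad.copy()

        eps = 1e-6
        for idx in [(0, 0), (1, 1), (2, 0)]:
            orig = coeff.data[idx]
            coeff.data[idx] = orig + eps
            up = _cross_entropy(model.forward(images), y).data
            coeff.data[idx] = orig - eps
            down = _cross_entropy(model.forward(images), y).data
            coeff.data[idx] = orig
            fd = (up - down) / (2 * eps)
            denom = max(abs(fd), abs(analytic[idx]), 1e-8)
            assert abs(fd - analytic[idx]) / denom < 1e-4


class TestCheckpoint:
    def test_save_load_round_trip(self, tmp_path):
        model = FRPETransformer(TINY, seed=9)
        model.params["head.W"].data = np.random.default_rng(1).normal(size=(8, 2))
        image = np.random.default_rng(2).random((1, 16, 16))
        before = model.forward(image).data
        path = tmp_path / "model.npz"
        model.save(str(path))
        loaded = FRPETransformer.load(str(path))
        assert loaded.config == model.config
        np.testing.assert_array_equal(loaded.forward(image).data, before)
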