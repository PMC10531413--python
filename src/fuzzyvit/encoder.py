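"""Flat vision-transformer encoder with fuzzy relative-position bias.

The classifier follows the single-scale token layout: a grayscale image is
cut into non-overlapping K x K patches, each patch is linearly projected to
a d-dimensional token, a learnable class token is prepended, and the
sequence runs through pre-norm transformer blocks whose attention logits
receive the fuzzy-smoothed relative-position bias from
:mod:`fuzzyvit.frpe`. The class token's final representation feeds a linear
head over {benign, malignant}.

Positional information enters in two (independently switchable) ways:

* the fuzzy relative-position bias, scaled by a learnable per-head gain
  (initialized at 1; the no-effect case gain = 0 stays reachable);
* an optional absolute position embedding ``We @ E_m`` added to each patch
  token (off by default — the relative pathway is the model's mechanism).

The class token has no spatial offset, so its bias row and column carry a
separate learnable scalar per head instead of a smoothed value.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field

import numpy as np

from .autodiff import Tensor, cat, gelu, layer_norm, softmax
from .frpe import (
    FuzzyBiasTable,
    NeighborhoodSpec,
    RelativePositionIndex,
    compute_relative_position_index,
    smoothed_bias_tensor,
)

__all__ = [
    "EncoderConfig",
    "PatchGrid",
    "ClassPrediction",
    "FRPETransformer",
    "patchify",
    "unpatchify",
]


@dataclass(frozen=True)
class EncoderConfig:
    """Architecture hyperparameters (desk-scale defaults)."""

    input_size: int = 64
    patch_size: int = 8
    embed_dim: int = 64
    depth: int = 4
    n_heads: int = 4
    mlp_ratio: float = 2.0
    neighborhood: str = "row"
    use_absolute_pos: bool = False
    use_frpe: bool = True
    drop_rate: float = 0.0

    def __post_init__(self) -> None:
        if self.embed_dim % self.n_heads != 0:
            raise ValueError("embed_dim must be divisible by n_heads")
        if self.input_size % self.patch_size != 0:
            raise ValueError("input_size must be a multiple of patch_size")
        if min(self.patch_size, self.embed_dim, self.depth, self.n_heads) < 1:
            raise ValueError("all size parameters must be >= 1")
        if not 0.0 <= self.drop_rate < 1.0:
            raise ValueError("drop_rate must be in [0, 1)")

    @property
    def grid_side(self) -> int:
        return self.input_size // self.patch_size

    @property
    def n_patches(self) -> int:
        return self.grid_side**2


@dataclass(frozen=True)
class PatchGrid:
    """Row-major decomposition of an image into flattened K x K patches."""

    image: np.ndarray
    patch_size: int
    patches: np.ndarray  # (M, K*K)


@dataclass(frozen=True)
class ClassPrediction:
    probs: tuple[float, float]  # (p_benign, p_malignant)
    label: str

    @property
    def p_malignant(self) -> float:
        return self.probs[1]


def patchify(image: np.ndarray, patch_size: int) -> PatchGrid:
    """Cut an H x W image into non-overlapping patches, row-major, lossless."""
    image = np.asarray(image, dtype=np.float64)
    if image.ndim != 2:
        raise ValueError("expected a 2-D grayscale image")
    if not np.all(np.isfinite(image)):
        raise ValueError("image contains non-finite values")
    h, w = image.shape
    k = patch_size
    if h % k or w % k:
        raise ValueError(f"image shape {image.shape} not divisible by patch size {k}")
    patches = (
        image.reshape(h // k, k, w // k, k).transpose(0, 2, 1, 3).reshape(-1, k * k)
    )
    return PatchGrid(image=image, patch_size=k, patches=patches)


def unpatchify(patches: np.ndarray, patch_size: int, height: int, width: int) -> np.ndarray:
    """Inverse of :func:`patchify`."""
    k = patch_size
    gh, gw = height // k, width // k
    return (
        np.asarray(patches)
        .reshape(gh, gw, k, k)
        .transpose(0, 2, 1, 3)
        .reshape(height, width)
    )


def _dct_projection(k: int, d: int, rng: np.random.Generator) -> np.ndarray:
    """Patch-projection init: orthonormal 2-D DCT filters, low frequency first.

    Tokens then start as patch frequency coefficients, giving the encoder
    ready-made edge and texture detectors instead of random projections.
    Extra output dimensions (d > k^2) fall back to fan-in-scaled noise.
    """
    n = np.arange(k)
    c = np.cos(np.pi * (2 * n[None, :] + 1) * n[:, None] / (2 * k))
    c[0] *= np.sqrt(1.0 / k)
    c[1:] *= np.sqrt(2.0 / k)
    filters = np.einsum("ui,vj->uvij", c, c).reshape(k * k, k * k)  # (filter, pixel)
    freq = (n[:, None] + n[None, :]).ravel()
    filters = filters[np.argsort(freq, kind="stable")]
    if d <= k * k:
        return filters[:d].T.copy()
    extra = rng.normal(0.0, 1.0 / k, (k * k, d - k * k))
    return np.concatenate([filters.T, extra], axis=1)


def _batch_patchify(images: np.ndarray, patch_size: int) -> np.ndarray:
    b, h, w = images.shape
    k = patch_size
    return (
        images.reshape(b, h // k, k, w // k, k)
        .transpose(0, 1, 3, 2, 4)
        .reshape(b, (h // k) * (w // k), k * k)
    )


class FRPETransformer:
    """Benign/malignant classifier over fixed-size grayscale images.

    Parameters live in ``self.params`` (name -> Tensor) so the optimizer and
    the checkpoint format can treat them uniformly. The fuzzy bias table is
    part of that dict (``frpe.raw`` / ``frpe.coeff_raw``).
    """

    def __init__(self, config: EncoderConfig, seed: int = 0):
        self.config = config
        self.index: RelativePositionIndex = compute_relative_position_index(
            config.grid_side, config.grid_side
        )
        rng = np.random.default_rng(seed)
        self.params: dict[str, Tensor] = {}
        self._init_params(rng)
        self.training = False
        self._drop_rng = np.random.default_rng(seed + 1)
        self.bias_table = FuzzyBiasTable(
            raw=self.params["frpe.raw"],
            coeff_raw=self.params["frpe.coeff_raw"],
            neighborhood=NeighborhoodSpec(config.neighborhood),
        )

    # -- parameter setup -----------------------------------------------------
    def _init_params(self, rng: np.random.Generator) -> None:
        cfg = self.config
        d, k2, m = cfg.embed_dim, cfg.patch_size**2, cfg.n_patches
        hidden = int(round(d * cfg.mlp_ratio))

        def tn(*shape, std=0.02):
            return Tensor(
                np.clip(rng.normal(0.0, std, shape), -2 * std, 2 * std),
                requires_grad=True,
            )

        def proj(fan_in, fan_out):
            # fan-in scaling keeps activation variance O(1) through the stack
            return Tensor(
                rng.normal(0.0, 1.0 / np.sqrt(fan_in), (fan_in, fan_out)),
                requires_grad=True,
            )

        p = self.params
        p["embed.Wx"] = Tensor(_dct_projection(cfg.patch_size, d, rng), requires_grad=True)
        p["embed.cls"] = tn(d)
        if cfg.use_absolute_pos:
            p["embed.E"] = tn(m, d)
            p["embed.We"] = proj(d, d)
        n_buckets = (2 * cfg.grid_side - 1) ** 2
        table = FuzzyBiasTable.create(n_buckets, cfg.n_heads, rng=rng)
        p["frpe.raw"] = table.raw
        p["frpe.coeff_raw"] = table.coeff_raw
        p["frpe.gain"] = Tensor(np.ones(cfg.n_heads), requires_grad=cfg.use_frpe)
        p["frpe.cls_bias"] = Tensor(np.zeros(cfg.n_heads), requires_grad=cfg.use_frpe)
        if not cfg.use_frpe:
            p["frpe.gain"].data[:] = 0.0
        for layer in range(cfg.depth):
            pre = f"block{layer}."
            for name in ("ln1", "ln2"):
                p[pre + name + ".g"] = Tensor(np.ones(d), requires_grad=True)
                p[pre + name + ".b"] = Tensor(np.zeros(d), requires_grad=True)
            for name in ("Wq", "Wk", "Wv", "Wo"):
                p[pre + "attn." + name] = proj(d, d)
            for name in ("bq", "bk", "bv", "bo"):
                p[pre + "attn." + name] = Tensor(np.zeros(d), requires_grad=True)
            p[pre + "mlp.W1"] = proj(d, hidden)
            p[pre + "mlp.b1"] = Tensor(np.zeros(hidden), requires_grad=True)
            p[pre + "mlp.W2"] = proj(hidden, d)
            p[pre + "mlp.b2"] = Tensor(np.zeros(d), requires_grad=True)
        p["head.ln.g"] = Tensor(np.ones(d), requires_grad=True)
        p["head.ln.b"] = Tensor(np.zeros(d), requires_grad=True)
        # zero head: a fresh model predicts (0.5, 0.5)
        p["head.W"] = Tensor(np.zeros((d, 2)), requires_grad=True)
        p["head.b"] = Tensor(np.zeros(2), requires_grad=True)

    def parameters(self) -> dict[str, Tensor]:
        return {k: v for k, v in self.params.items() if v.requires_grad}

    # -- forward pieces ------------------------------------------------------
    def embed(self, patches: Tensor) -> Tensor:
        """Project patch pixels to tokens and prepend the class token.

        ``patches``: (B, M, K^2) -> tokens (B, M+1, d).
        """
        cfg = self.config
        tokens = patches @ self.params["embed.Wx"]
        if cfg.use_absolute_pos:
            tokens = tokens + self.params["embed.E"] @ self.params["embed.We"]
        b = patches.shape[0]
        cls = self.params["embed.cls"].reshape(1, 1, cfg.embed_dim) + Tensor(
            np.zeros((b, 1, cfg.embed_dim))
        )
        return cat([cls, tokens], axis=1)

    def attention_bias(self) -> Tensor | None:
        """Full (heads, M+1, M+1) additive logit bias, or None when disabled."""
        cfg = self.config
        if not cfg.use_frpe:
            return None
        smoothed = smoothed_bias_tensor(self.bias_table, self.index)  # (H, M, M)
        h, m = cfg.n_heads, cfg.n_patches
        gained = self.params["frpe.gain"].reshape(h, 1, 1) * smoothed
        cls_b = self.params["frpe.cls_bias"]
        top = cls_b.reshape(h, 1, 1) + Tensor(np.zeros((h, 1, m + 1)))
        left = cls_b.reshape(h, 1, 1) + Tensor(np.zeros((h, m, 1)))
        return cat([top, cat([left, gained], axis=2)], axis=1)

    def _dropout(self, x: Tensor) -> Tensor:
        rate = self.config.drop_rate
        if not self.training or rate == 0.0:
            return x
        mask = (self._drop_rng.random(x.shape) >= rate) / (1.0 - rate)
        return x * Tensor(mask)

    def _block(self, x: Tensor, layer: int, bias: Tensor | None) -> Tensor:
        cfg = self.config
        p = self.params
        pre = f"block{layer}."
        b, t, d = x.shape
        nh, dh = cfg.n_heads, d // cfg.n_heads

        h = layer_norm(x, p[pre + "ln1.g"], p[pre + "ln1.b"])

        def heads(y: Tensor) -> Tensor:
            return y.reshape(b, t, nh, dh).transpose(0, 2, 1, 3)

        q = heads(h @ p[pre + "attn.Wq"] + p[pre + "attn.bq"])
        k = heads(h @ p[pre + "attn.Wk"] + p[pre + "attn.bk"])
        v = heads(h @ p[pre + "attn.Wv"] + p[pre + "attn.bv"])
        logits = (q @ k.transpose(0, 1, 3, 2)) * (1.0 / np.sqrt(dh))
        if bias is not None:
            logits = logits + bias.reshape(1, nh, t, t)
        attn = softmax(logits, axis=-1)
        ctx = (attn @ v).transpose(0, 2, 1, 3).reshape(b, t, d)
        x = x + self._dropout(ctx @ p[pre + "attn.Wo"] + p[pre + "attn.bo"])

        h = layer_norm(x, p[pre + "ln2.g"], p[pre + "ln2.b"])
        h = gelu(h @ p[pre + "mlp.W1"] + p[pre + "mlp.b1"]) @ p[pre + "mlp.W2"] + p[
            pre + "mlp.b2"
        ]
        out = x + self._dropout(h)
        if not np.all(np.isfinite(out.data)):
            raise FloatingPointError(f"non-finite activations in encoder block {layer}")
        return out

    def forward(self, images: np.ndarray) -> Tensor:
        """Logits (B, 2) for a batch of (B, H, W) images in [0, 1]."""
        images = np.asarray(images, dtype=np.float64)
        if images.ndim == 2:
            images = images[None]
        expected = (self.config.input_size, self.config.input_size)
        if images.shape[1:] != expected:
            raise ValueError(f"expected images of shape {expected}, got {images.shape[1:]}")
        x = self.embed(Tensor(_batch_patchify(images, self.config.patch_size)))
        bias = self.attention_bias()
        for layer in range(self.config.depth):
            x = self._block(x, layer, bias)
        x = layer_norm(x, self.params["head.ln.g"], self.params["head.ln.b"])
        cls = x[:, 0, :]
        return cls @ self.params["head.W"] + self.params["head.b"]

    def predict_proba(self, images: np.ndarray) -> np.ndarray:
        """Class probabilities (B, 2), columns (benign, malignant)."""
        logits = self.forward(images)
        return softmax(logits, axis=-1).data

    def classify(self, image: np.ndarray) -> ClassPrediction:
        probs = self.predict_proba(np.asarray(image)[None])[0]
        label = "malignant" if probs[1] >= 0.5 else "benign"
        return ClassPrediction(probs=(float(probs[0]), float(probs[1])), label=label)

    # -- checkpointing -------------------------------------------------------
    def save(self, path: str) -> None:
        """Single-archive checkpoint: config JSON plus all named arrays."""
        arrays = {name: t.data for name, t in self.params.items()}
        arrays["__config__"] = np.frombuffer(
            json.dumps(asdict(self.config)).encode(), dtype=np.uint8
        )
        np.savez(path, **arrays)

    @classmethod
    def load(cls, path: str) -> "FRPETransformer":
        with np.load(path) as archive:
            cfg = EncoderConfig(**json.loads(bytes(archive["__config__"]).decode()))
            model = cls(cfg, seed=0)
            for name in model.params:
                model.params[name].data = archive[name].astype(np.float64)
        return model
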