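"""Fuzzy relative-position encoding (FRPE).

Windowed attention over image patches can carry a learnable scalar bias per
(head, 2-D offset bucket): the relative-position bias of windowed
transformers. FRPE replaces the raw learned bias values with fuzzy
memberships

    S(E_m) = exp(-w_m E_m) / sum_{i in Ng} exp(-w_i E_i)

where ``E_m`` is the raw position value for offset bucket ``m``, ``w_m`` a
non-negative per-bucket coefficient, and ``Ng`` the neighborhood over which
memberships are normalized. The memberships are continuous, lie in (0, 1]
and sum to one per neighborhood, smoothing the discrete bias table into a
distribution over positions.

This module owns the offset bucketing, the smoothing function and the
learnable bias table; :mod:`fuzzyvit.encoder` injects the smoothed bias into
the attention logits.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .autodiff import Tensor, softmax, softplus

__all__ = [
    "RelativePositionIndex",
    "NeighborhoodSpec",
    "FuzzyBiasTable",
    "SmoothedBias",
    "compute_relative_position_index",
    "fuzzy_smooth",
    "smoothed_bias_matrix",
    "smoothed_bias_tensor",
]

# inverse softplus of 1.0: initializes the reparameterized coefficients at 1
_COEFF_INIT = math.log(math.e - 1.0)


@dataclass(frozen=True)
class RelativePositionIndex:
    """Dense bucketing of 2-D patch offsets within a window.

    ``index[a, b]`` is the bucket of the coordinate difference between
    patches ``a`` and ``b`` (row-major order), so it depends only on the
    offset — translation invariance within the window.
    """

    window_h: int
    window_w: int
    index: np.ndarray

    @property
    def n_buckets(self) -> int:
        return (2 * self.window_h - 1) * (2 * self.window_w - 1)

    @property
    def n_tokens(self) -> int:
        return self.window_h * self.window_w


@dataclass(frozen=True)
class NeighborhoodSpec:
    """Normalization neighborhood Ng for the fuzzy memberships.

    ``mode="row"``: for query patch *i*, Ng is the set of key positions it
    attends to, so each query row of the bias block normalizes to one.
    ``mode="full"``: Ng is the whole bucket table; memberships are computed
    per bucket and then gathered.
    """

    mode: str = "row"

    def __post_init__(self) -> None:
        if self.mode not in ("row", "full"):
            raise ValueError(f"unknown neighborhood mode {self.mode!r}")


@dataclass
class FuzzyBiasTable:
    """Learnable raw position values E and fuzzy coefficients w per head.

    ``coeff_raw`` stores the pre-softplus parameters; the effective
    coefficients ``softplus(coeff_raw)`` are strictly positive, keeping
    exp(-w E) a decaying membership.
    """

    raw: Tensor
    coeff_raw: Tensor
    neighborhood: NeighborhoodSpec = field(default_factory=NeighborhoodSpec)

    def __post_init__(self) -> None:
        if self.raw.shape != self.coeff_raw.shape:
            raise ValueError("raw and coeff tables must have identical shape")

    @property
    def n_buckets(self) -> int:
        return self.raw.shape[0]

    @property
    def n_heads(self) -> int:
        return self.raw.shape[1]

    @property
    def coeff(self) -> np.ndarray:
        """Effective non-negative coefficients w (numpy view)."""
        return np.logaddexp(0.0, self.coeff_raw.data)

    @classmethod
    def create(
        cls,
        n_buckets: int,
        n_heads: int,
        neighborhood: NeighborhoodSpec | None = None,
        rng: np.random.Generator | None = None,
        init_std: float = 0.02,
    ) -> "FuzzyBiasTable":
        """Fresh table: raw values truncated-normal(std), coefficients at 1."""
        rng = rng or np.random.default_rng()
        raw = np.clip(rng.normal(0.0, init_std, (n_buckets, n_heads)), -2 * init_std, 2 * init_std)
        coeff_raw = np.full((n_buckets, n_heads), _COEFF_INIT)
        return cls(
            raw=Tensor(raw, requires_grad=True),
            coeff_raw=Tensor(coeff_raw, requires_grad=True),
            neighborhood=neighborhood or NeighborhoodSpec(),
        )


@dataclass(frozen=True)
class SmoothedBias:
    """Fuzzy-membership bias block for one head; entries in (0, 1]."""

    values: np.ndarray
    neighborhood: NeighborhoodSpec


def compute_relative_position_index(window_h: int, window_w: int) -> RelativePositionIndex:
    """Bucket every pair of patch positions in an h x w window by 2-D offset.

    Offset (dr, dc) maps to bucket ``(dr + h - 1) * (2w - 1) + (dc + w - 1)``,
    the dense row-major enumeration of the (2h-1) x (2w-1) offset grid.
    """
    if window_h < 1 or window_w < 1:
        raise ValueError("window dimensions must be positive")
    coords = np.stack(
        np.meshgrid(np.arange(window_h), np.arange(window_w), indexing="ij"), axis=-1
    ).reshape(-1, 2)
    delta = coords[:, None, :] - coords[None, :, :]  # (T, T, 2)
    index = (delta[..., 0] + window_h - 1) * (2 * window_w - 1) + (delta[..., 1] + window_w - 1)
    index.setflags(write=False)
    return RelativePositionIndex(window_h=window_h, window_w=window_w, index=index)


def fuzzy_smooth(values: np.ndarray, coeff: np.ndarray) -> np.ndarray:
    """Fuzzy membership over one neighborhood: softmax of -coeff * values.

    Returns ``exp(-coeff[m] values[m]) / sum_i exp(-coeff[i] values[i])``,
    computed with max-subtraction. Outputs are in (0, 1] and sum to 1.
    """
    values = np.asarray(values, dtype=np.float64)
    coeff = np.asarray(coeff, dtype=np.float64)
    if values.shape != coeff.shape or values.ndim != 1 or values.size < 1:
        raise ValueError("values and coeff must be 1-D, non-empty and of equal length")
    if not (np.all(np.isfinite(values)) and np.all(np.isfinite(coeff))):
        raise ValueError("non-finite input to fuzzy_smooth")
    if np.any(coeff < 0):
        raise ValueError("coefficients must be non-negative")
    z = -coeff * values
    z -= z.max()
    e = np.exp(z)
    return e / e.sum()


def smoothed_bias_matrix(
    table: FuzzyBiasTable, index: RelativePositionIndex, head: int
) -> SmoothedBias:
    """Gather one head's raw/coeff values by offset bucket and smooth them.

    With ``mode="row"`` each query row of the (tokens x tokens) block is one
    normalization group; with ``mode="full"`` memberships are computed over
    the whole bucket table and then gathered (so a row need not sum to one).
    """
    if index.index.max() >= table.n_buckets:
        raise ValueError(
            f"index references bucket {index.index.max()} but table has {table.n_buckets}"
        )
    e = table.raw.data[:, head]
    w = np.logaddexp(0.0, table.coeff_raw.data[:, head])
    mode = table.neighborhood.mode
    if mode == "row":
        block_e = e[index.index]
        block_w = w[index.index]
        out = np.stack([fuzzy_smooth(v, c) for v, c in zip(block_e, block_w)])
    else:
        memberships = fuzzy_smooth(e, w)
        out = memberships[index.index]
    return SmoothedBias(values=out, neighborhood=table.neighborhood)


def smoothed_bias_tensor(table: FuzzyBiasTable, index: RelativePositionIndex) -> Tensor:
    """Differentiable smoothed bias for all heads: shape (n_heads, T, T)."""
    flat = index.index.ravel()
    T = index.n_tokens
    e = table.raw.take(flat, axis=0).reshape(T, T, table.n_heads).transpose(2, 0, 1)
    w = (
        softplus(table.coeff_raw)
        .take(flat, axis=0)
        .reshape(T, T, table.n_heads)
        .transpose(2, 0, 1)
    )
    if table.neighborhood.mode == "row":
        return softmax(-(w * e), axis=-1)
    memberships = softmax(-(softplus(table.coeff_raw) * table.raw), axis=0)  # (buckets, heads)
    return memberships.take(flat, axis=0).reshape(T, T, table.n_heads).transpose(2, 0, 1)
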