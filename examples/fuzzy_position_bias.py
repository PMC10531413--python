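"""Inspect the fuzzy relative-position bias for a small patch window.

Builds the offset bucketing for a 4x4 window of patches, creates a fresh
bias table, and prints the smoothed membership row of the center patch.
The memberships are positive, sum to one across the keys the patch attends
to, and start nearly uniform (the raw table is initialized near zero).
"""

import numpy as np

from fuzzyvit import FuzzyBiasTable, compute_relative_position_index, smoothed_bias_matrix

index = compute_relative_position_index(4, 4)
print(f"window 4x4 -> {index.n_tokens} tokens, {index.n_buckets} offset buckets")
print(f"distinct buckets realized: {len(np.unique(index.index))}")

table = FuzzyBiasTable.create(index.n_buckets, n_heads=1, rng=np.random.default_rng(0))
bias = smoothed_bias_matrix(table, index, head=0)
center = index.n_tokens // 2
row = bias.values[center]
print(f"membership row of patch {center}: min {row.min():.4f}, max {row.max():.4f}, "
      f"sum {row.sum():.9f}")

# sharpening the raw values concentrates membership on favored offsets
table.raw.data[:, 0] = np.linspace(-2, 2, index.n_buckets)
sharp = smoothed_bias_matrix(table, index, head=0).values[center]
print(f"after spreading raw values: min {sharp.min():.4f}, max {sharp.max():.4f} "
      f"(still sums to {sharp.sum():.9f})")
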