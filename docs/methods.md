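# Methods

## Problem and model

`fuzzyvit` classifies grayscale breast-ultrasound-like images as benign or
malignant with a single-scale vision transformer whose attention carries a
*fuzzy relative-position bias*. An image of side `N` is cut into `M =
(N/K)^2` non-overlapping `K x K` patches; each flattened patch `X_m` is
linearly projected to a `d`-dimensional token `H_m = W_x X_m (+ W_e E_m)`,
where the absolute position term `W_e E_m` is optional and off by default.
A learnable class token is prepended and the sequence passes through
`depth` pre-norm transformer blocks; the class token's final representation
feeds a linear head over the two classes.

Positional structure enters through the relative-position pathway. Every
ordered pair of patches maps to one of `(2h-1)(2w-1)` offset buckets (the
dense bucketing of 2-D coordinate differences used by windowed
transformers). A table holds, per attention head, a raw value `E_m` and a
non-negative coefficient `w_m` for every bucket. Instead of adding the raw
values to the attention logits, the table is smoothed into fuzzy
memberships

    S(E_m) = exp(-w_m E_m) / sum_{i in Ng} exp(-w_i E_i)

over a neighborhood `Ng`. The memberships are continuous, lie in (0, 1]
and sum to one per neighborhood, so each query patch sees a *distribution*
over relative positions rather than a set of unconstrained offsets. The
smoothed block is scaled by a learnable per-head gain (initialized at 1)
and added to the pre-softmax attention logits. With the default
`Ng = row`, the neighborhood of query patch *i* is the set of key positions
it attends to, so each query row normalizes to one; a `full`-table mode
(memberships normalized over all buckets, then gathered) is available in
the config.

Choices where the design was genuinely open:

* **Where the smoothing acts.** The smoothing is applied to the scalar
  per-bucket bias values gathered into the attention-logit block, not to
  the absolute embedding vectors; the absolute pathway is kept as an
  independent optional term. A per-embedding-dimension reading of the
  smoothing is representable but is not the default.
* **Coefficient positivity.** `w_m` is learnable (one per bucket per head,
  initialized to 1) and kept non-negative through a softplus
  reparameterization, so `exp(-w_m E_m)` stays a decaying membership.
* **Class token.** It has no spatial offset, so its bias row and column
  carry one learnable scalar per head (initialized 0) instead of smoothed
  values.
* **Pre-norm blocks, GELU MLP.** Pre-norm is the stabler choice at small
  scale.

## Autodifferentiation

The stack — including the smoothing function — is trained end to end by a
compact reverse-mode autodiff engine over numpy arrays written for this
package (`fuzzyvit.autodiff`). It implements exactly the primitives the
model needs (broadcast-aware arithmetic, batched matmul, gather with
scatter-add backward, stable softmax/softplus, erf-based GELU, layer norm).
Gradient correctness is pinned by central-difference checks in the test
suite (relative error below 1e-4 on every parameter class, including the
fuzzy coefficients).

## Synthetic phantoms

The generator renders one hypoechoic lesion per image on a speckled
background. The boundary is polar, `r(theta) = R (1 + p(theta))` around a
jittered center:

* **benign**: `p` is a sum of low-frequency harmonics (k = 2..4, sigma
  0.05/sqrt(k)) — a smooth, continuous boundary;
* **malignant**: the same base plus 5–10 radial spicules (Gaussian bumps in
  angle, height 0.54–0.9 R, angular width 0.2–0.35 rad) and
  high-frequency roughness (k = 8..24, sigma 0.04) — sharp curves and
  small branches.

Every boundary is rescaled so its enclosed area equals `pi R^2` exactly;
with the shared radius distribution this pins the lesion area — and hence
the image mean — to be class-independent, forcing any classifier to read
boundary *shape*. Speckle is a multiplicative unit-mean Rayleigh field
with a short correlation length (Gaussian blur, sigma 0.6 px), blended
toward unity by a `speckle_contrast` parameter (default 0.5): fully
developed speckle has contrast 1, while clinical B-mode processing
(spatial compounding, frame averaging) substantially reduces speckle
contrast, which the blend emulates. Default conditions: 64 x 64 px,
background level 0.55, lesion contrast 0.5, lesion radius 0.18–0.30 of the
image side.

Two generator choices are driven by *recoverability* of the morphology
signal at desk scale. First, the spicule geometry is deliberately coarse
(several pixels wide at 64 px): thinner spicules survive the
segmentation-based compactness readout but are invisible to the
patch-token classifier under speckle. Second, the default speckle contrast
is 0.5: at contrast 1.0 the 160-image training runs stay at or near chance
even though a location-indexed linear probe on per-patch statistics still
separates the classes. Both choices keep the generator's two contracts
intact (compactness AUC ~1.0 between classes; mean-intensity separation at
chance by the area normalization, independent of speckle level).

What the phantoms do **not** emulate: point-spread-function anisotropy,
attenuation and posterior shadowing, microcalcifications, heterogeneous
parenchyma, operator-dependent gain. Passing tests on phantoms therefore
demonstrates that the pipeline can learn boundary morphology under
speckle — not clinical-grade performance on real ultrasound.

Determinism: one image is a pure function of (params, label, seed); dataset
image *i* uses seed `(master * 1_000_003 + i) mod 2^31`.

## Evaluation protocol

Rows of the confusion matrix are true labels, columns predictions, order
(benign, malignant). Accuracy is the diagonal fraction; precision, recall
and F1 are computed per class (each class positive in turn) and
macro-averaged (unweighted mean — this convention reproduces the published
"Total" rows exactly). Zero-denominator metrics are defined as 0 with a
warning. The ROC sweep takes malignant as positive, sweeps the unique
score values, and integrates trapezoidally; on finite samples this equals
pairwise concordance with ties at 1/2, which the tests assert against a
brute-force oracle. Decision threshold at evaluation time: malignancy
probability >= 0.5.

## Training and cross-validation

Five stratified folds at a 4:1 train:test ratio; per-fold accuracy,
per-class and macro precision/recall/F1 and AUC are aggregated as
mean ± sample standard deviation (ddof = 1) over folds. All randomness
(fold assignment, weight init, batch order, augmentation draws) derives
from one seed, so a run is bit-reproducible on a single platform (exact
bit-reproducibility across BLAS builds is not guaranteed).

Optimizer defaults. The default optimizer is Adam (lr 1e-3, beta
0.9/0.999) with decoupled weight decay 0.05 on weight matrices and the
fuzzy table, 5 warmup epochs then cosine decay, and label smoothing 0.1;
SGD with momentum 0.9, cosine decay and global gradient-norm clipping at
1.0 remains available (`optimizer="sgd"`). At this problem size plain SGD
stalls near chance — the loss surface of the tiny from-scratch transformer
is poorly conditioned — while Adam with decay and warmup trains reliably;
that empirical finding drove the default.

Patch-projection initialization: `W_x` starts as the orthonormal 2-D DCT
basis (low frequencies first), so tokens begin as patch frequency
coefficients; other projections use fan-in-scaled Gaussian init, and the
classifier head starts at zero (a fresh model predicts exactly (0.5,
0.5)). Training mirrors each batch horizontally with probability 1/2
(label-preserving for the phantoms) from the seeded stream; evaluation
averages the malignancy score over the image and its mirror. Batch size
32, 60 epochs by default. These defaults are the desk-scale study
conditions: 200 phantoms, 64 x 64 input, patch size 8 (64 tokens), width
64, depth 4, 4 heads, MLP ratio 2.

At this scale the held-out signal is real but modest: cross-validated
accuracy sits well above the 50% majority baseline on average, with the
weakest folds passing by a few test images, and fold-to-fold spread is
wide (individual folds can touch the baseline at other dataset seeds).
The pipeline's contract is to beat the majority baseline, not to reach the
performance of full-scale training on real data; numbers reported on real
clinical datasets require thousands of images and GPU-scale training and
are out of scope here.

## Numerical notes

* Softmax and the fuzzy smoothing use max-subtraction;
  memberships sum to one within 1e-9 in double precision.
* Non-finite activations abort the forward pass with the block index;
  NaN loss aborts training.
* Checkpoints are a single `.npz` archive holding the config (JSON) plus
  every named parameter array; loading restores bit-identical forwards.
* Degenerate inputs: single-patch windows produce the membership [[1.0]];
  empty confusion matrices and single-class ROC inputs raise errors rather
  than returning conventions.
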