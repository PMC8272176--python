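# Methods

## The model

The package implements a U-shaped encoder–decoder for single-class 2D
segmentation (fetal body in sagittal MRI slices), augmented with two
channel/spatial recalibration operators:

**Squeeze-and-excitation (SE) block.** For a feature map `U` with `C`
channels of size `H×W`, the squeeze is global average pooling,
`z_n = (1/HW) Σ_ij U_n(i,j)`. The excitation is a bottlenecked two-layer
gating network `s = σ(W2 · δ(W1 z + b1) + b2)` with `W1: C → C/g`,
`W2: C/g → C`, `δ` = ReLU, `σ` = sigmoid, and reduction (complexity value)
`g = 8`. The output rescales each channel plane by its gate, `X̃_n = s_n U_n`.
Biases are included in both fully connected layers (the default behaviour of
mainstream layer implementations) and can be disabled.

**Additive attention gate.** The skip features `x` and a same-resolution
gating signal `g_s` (the decoder features immediately after the transposed
convolution) each pass through a 1×1 convolution into `F_int` channels; the
sum is ReLU-ed, collapsed by another 1×1 convolution to one channel, and
squashed by a sigmoid into a per-pixel coefficient `α ∈ (0,1)`. The output
is `α ⊙ x`, broadcast over the skip channels. The gate therefore operates at
matched resolution — no resampling inside the gate — and the attention map
multiplies the *skip* features (multiplying the gating signal instead would
make the subsequent concatenation redundant). `F_int` defaults to half the
skip channel count.

**Assembly.** Five encoder levels with widths 64/128/256/512/1024 (the
U-Net convention; the source architecture does not state widths), each level
two stacked 5×5 'same'-padded conv+ReLU stages. Levels 2–5 are entered
through 2×2 max-pooling and exit through an SE block, so the skip
connection carries the recalibrated channels; level 1 (the superficial
layer) has neither SE nor attention on the encoder side. The decoder has
four stages: stride-2 transposed convolution (halving channels), attention
gate on the skip, concatenation, two conv+ReLU stages. A 1×1 convolution +
sigmoid emits the probability map at input resolution. With SE and
attention enabled this instantiates exactly `depth−1 = 4` SE blocks and 4
attention gates — one gate per deconvolution, which necessarily includes
the stage that reunites with the level-1 skip.

**Variants.** `casenet` (full), `casenet_3x3`, `casenet_no_atn`,
`casenet_no_se` (single-delta ablations), and the baselines `unet`
(3×3 kernels, nearest-neighbour upsampling, no SE, no attention — kept in
classic form so the transposed-convolution change remains a measurable
delta), `use_net` (= unet + SE), `atn_net` (= unet + attention). The
ablations nest: stripping all four deltas from `casenet` yields a
configuration structurally identical to `unet`.

## Numerical substrate

No deep-learning framework is used: `casenet.nn` is a small tape-based
reverse-mode autodiff engine over numpy arrays with exactly the operator set
the network needs. Convolutions run as one GEMM per layer via im2col;
max-pool ties break deterministically to the first maximum; parameters are
float32 with He-normal initialisation. All gradients are verified against
central finite differences in the test suite. Training on one CPU thread is
bit-reproducible for a fixed seed.

## Analytic cost accounting

`summarize` counts parameters and forward-pass multiply–accumulates (MACs)
from the configuration alone: `k²·C_in·C_out·H·W` per convolution (output
size `H×W`), `C_in·C_out` per fully connected layer, `4·C_in·C_out` per
input pixel for the stride-2 transposed convolution; pooling and
activations are free; the elementwise recalibration products (SE channel
scaling, attention masking) are charged one multiply per value. Under these
conventions the four SE blocks add ≈0.003% to the default configuration's
MACs — comfortably inside the ≤0.5% overhead expected of SE blocks — and
the figure is insensitive to whether the elementwise products are charged
at all.

## Training protocol

Defaults (`TrainConfig`): binary cross-entropy (probabilities clipped at
1e-7), Adam (β1=0.9, β2=0.999, ε=1e-7) at 1e-4, batch size 4, 100 epochs,
384×384 inputs, 5-fold patient-level cross-validation. The scheduler
monitors validation loss and performs a single reduction to 1e-5 after 5
epochs without an improvement of at least 1e-4 (the stagnation criterion is
not stated in the source recipe; patience 5 / min-delta 1e-4 / one
reduction is this package's choice, matching the single fallback rate
named). The best-validation-loss weights are checkpointed and restored.
Augmentation — horizontal stretch, vertical stretch, shear, zoom (all
sampled per slice), horizontal flip — is applied to training slices only;
ranges default to factors in [0.9, 1.1], shear ±8°, flip probability 0.5
(mild transforms; the source names the transform set but not its ranges).
The same sampled transform warps image (bilinear) and mask
(nearest-neighbour), so masks stay exactly binary and cannot desynchronise.
Prediction thresholds the sigmoid output at 0.5.

Cross-validation runs inside the training partition of the 60/20/20
patient-level split; the test partition is never touched during CV. The
split is patient-level (2368/832/832 slices at ~119 slices per patient is
consistent with 20/7/7 patients) to preclude leakage of adjacent slices.
Intensity normalization is per-volume min–max to [0, 1] (z-score available);
the normalization used on the original scanner data is not stated.

## The synthetic phantom

The original fetal MRI cohort is private, so the package ships a generator
of fetal-like 2D phantoms: per patient, a body ellipse (semi-axes `a`,
`0.62a`), an overlapping head disc (radius `0.48a`) and 2–4 limb capsules,
with `a` drawn as a fraction of image size from (0.15, 0.28) and mapped
linearly to a 20–37-week gestational-age proxy used for stratified splits.
Pose drifts smoothly across the 119 slices of a "sagittal sweep". Images
add dimmer maternal-tissue ellipses (intensity 0.2–0.45 vs foreground
0.6–0.8), a smooth quadratic multiplicative bias field (±20% by default),
and additive Gaussian noise (σ=0.05 post-normalization; Rician optional).
The mask is the exact foreground raster — no label noise — so a noiseless
phantom is exactly threshold-recoverable (a soundness check), and the
threshold segmenter's Dice degrades monotonically with noise (the benchmark
is non-degenerate).

What the phantom does *not* emulate: MR physics (no k-space or sequence
modelling), partial-volume boundaries, motion artifacts, anatomical
texture, or multi-fetus pregnancies. Passing the end-to-end tests therefore
demonstrates that the architecture, optimizer, and pipeline are correctly
wired and can fit a non-trivial segmentation task — not that clinical-grade
fetal segmentation accuracy would be reached on real data.

## Problem sizes

The repository's end-to-end quality bar runs the depth-3, base-width-8
model on 64×64 phantoms with 200 training and 50 validation slices for 20
epochs at batch size 4, and requires mean validation Dice ≥ 0.90 with a
decreasing loss curve; the run finishes in a few minutes on one CPU and
reaches ≈0.98. Full-size training (depth 5, width 64, 384×384) is supported
through the same API and CLI but is a GPU-scale undertaking and is not part
of any test.

## Degenerate inputs and tie-breaks

Empty-vs-empty mask pairs score DSC/recall/precision 1.0 (correct
prediction of absence; slices near volume edges are routinely fetus-free),
with slice exclusion available at aggregation. Zero-variance score groups in
the Welch t-test return t=0, p=1 when means coincide and ±∞, p=0 otherwise.
Constant images normalize to zeros. Max-pooling ties route gradient to the
first maximum. The architecture comparison test is Welch's
(unequal-variance) form — more conservative than the pooled-variance test,
which the source does not disambiguate.

## Known limitations

* Pure-numpy training is ~1–2 orders of magnitude slower than a GPU
  framework; full-size runs are impractical here by design.
* The "±" dispersion of cross-validation aggregates is reported across
  folds; per-slice and per-patient dispersions are available from the
  evaluation CSV.
* The phantom's gestational-age proxy is a monotone function of fetus
  scale, not a biological growth model.
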