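# Methods

## Problem and model

The package segments hypoechoic lesions in 2-D grayscale breast-ultrasound
images: given an image, predict the binary lesion mask. The core model,
RCU-Net, is a U-Net encoder–decoder with two modifications:

1. **Res Paths.** Each of the four shortcut connections carries a chain of
   residual units, `x_l = H_l(x_{l-1}) + x_{l-1}`, instead of routing raw
   encoder features to the decoder. The chains have 4, 3, 2 and 1 units at
   encoder levels 1–4, with 64, 128, 256 and 512 channels respectively
   (scaled proportionally when the backbone is narrowed). The extra
   nonlinear transform reduces the semantic gap between encoder and decoder
   features at the concatenation points.
2. **Dense input connection.** A dense block runs from the raw input
   directly to the last decoder stage: a stem convolution produces F = 64
   feature maps, then four layers each add k = 16 maps, every layer seeing
   the channel-wise concatenation of everything before it
   (layer *l* has F + k·(l−1) input channels), ending at F + 4k = 128
   channels. It contains no pooling, so it preserves full-resolution detail
   that the encoder–decoder path loses; its output is merged by element-wise
   addition into the (widened, 128-kernel) last decoder stage.

The backbone uses encoder widths 64/128/256/512/1024, four 2×2 max-pool
steps, 2×2-kernel stride-2 transposed-convolution up-sampling, two
3×3-conv + ReLU stages per level, and a 1×1 convolution + sigmoid head
producing a per-pixel lesion probability. Binarization threshold is 0.5
(configurable). Input extent 256×256 by default; any extent divisible by 16
works.

### Unit internals the published description leaves open

* Residual unit transform H: Conv3×3 → BatchNorm → ReLU → Conv3×3 →
  BatchNorm, ReLU after the add — the standard residual-unit layout. Where
  a unit changes channel width, the identity branch is a 1×1 convolution
  projection so the addition is well-defined.
* Dense layers: BatchNorm → ReLU → Conv3×3 producing k maps (DenseNet
  convention).
* The plain U-Net backbone blocks carry no batch normalization, matching
  the original U-Net; normalization appears only inside Res Path units and
  dense layers.
* Decoder concatenation order is [shortcut features, up-sampled features].

## Training

Per-image loss is the **pixel sum** of binary cross-entropy terms
−(y·log p + (1−y)·log(1−p)), averaged over the batch. Many frameworks
default to pixel means; the sum is kept deliberately, with a
`loss_reduction="mean"` switch. Probabilities are clamped to
(1e-7, 1−1e-7) before the logarithms; pixels clamped flat contribute zero
gradient. Optimization is Adam with α = 1e-4, β₁ = 0.9, β₂ = 0.999,
ε = 1e-8 (the ε is a numerical stabilizer absent from the published update
rule), batch size 4, 120 epochs by default. Weights are he_normal
(zero-mean Gaussian, variance 2/fan_in; biases zero). No learning-rate
schedule and no early stopping. Training is bit-reproducible under a fixed
seed: initialization and shuffling both derive from `TrainConfig.seed`.

The network engine is written directly in NumPy (im2col + BLAS matmul
convolutions with hand-derived backward passes), runs in float32 by
default, and is verified against central-difference gradients (run in
float64 via `rcunet.nn.layers.set_default_dtype`) in the test suite.

## Evaluation

Five metrics per ground-truth/prediction pair: TP = |GT∩SR|/|GT|,
FP = |SR∖GT|/|GT| (can exceed 1), Dice = 2|GT∩SR|/(|GT|+|SR|),
Jaccard = |GT∩SR|/|GT∪SR|, and the symmetric Hausdorff distance in pixels.
HD is computed on contour pixels (4-connectivity boundary) with Euclidean
distances by default; `hd_mode="area"` uses all foreground pixels, since
the point-set definition is ambiguous in the literature. A segmentation
counts as successful when JS > 0.75, strictly.

Empty-mask policy: a metric whose denominator set is empty is *undefined*
and reported as missing, never as 0 or a sentinel — aggregates average only
the defined values and track undefined counts separately, which prevents
silent distortion of fold means.

## Cross-validation protocol

Images are randomly partitioned into k = 10 test cases; every architecture
variant trains on identical fold memberships (same split seed). The
training side of each fold is doubled by augmentation *after* splitting, so
no augmented copy of a training image can leak into the test set. The
augmentation transform is a horizontal flip applied identically to image
and mask: deterministic, anatomically plausible, and exactly doubling.
538 images cannot give ten folds of 54 (540 ≠ 538); the partition is eight
folds of 54 and two of 53 test images, preserving disjointness and
coverage; the 54-test/484-train fold is the canonical case (484 doubles to
968 training images). Summary statistics are mean and sample standard
deviation across the k fold means (not pooled over images), plus medians
and inclusive-median quartiles for the JS > 0.75 success-count
distributions.

## Synthetic phantoms

The clinical dataset behind the published results is private, so the
package ships a phantom generator that emulates the stated characteristics
of breast ultrasound:

* **Lesion geometry**: a randomly rotated ellipse whose unit contour is
  perturbed by low-order radial Fourier modes (m = 2..4, amplitudes up to
  0.08) — irregular tumor-like outlines that exercise the Hausdorff metric.
* **Hypoechogenicity**: lesion mean intensity is `lesion_contrast` times
  the background level (default contrast 0.5, background 0.45); the
  transition is smoothed with a Gaussian of `boundary_blur_sigma` pixels
  (default 1.5) to emulate fuzzy margins. The ground-truth mask is the
  sharp pre-blur footprint.
* **Speckle**: multiplicative unit-mean Gamma noise (shape 5 by default,
  i.e. ≈45 % relative standard deviation) with slight lateral smearing as a
  crude point-spread function. No beam physics is modeled.
* **Posterior shadowing**: with probability 0.2, the band below the lesion
  is attenuated by up to 40 %.
* **Hard sub-population**: a configurable fraction (default 10 %) of
  phantoms is generated nearly isoechoic (contrast pushed toward 1) with
  3× boundary blur, mimicking the obscure-boundary failure cases reported
  for real data.
* **Size range**: the published lesions span 3–52 mm maximum diameter; no
  pixel spacing is stated, so the package assumes 0.25 mm/pixel at 256×256,
  giving a default radius range of 6–104 px (capped at 45 % of the canvas).
  The desk-scale 64×64 spec scales this to 4–26 px, dropping sub-4-px
  lesions as unresolvable on that grid.

What the phantoms do *not* reproduce: real tissue texture and anatomy
(glandular layers, Cooper's ligaments), probe-dependent resolution
anisotropy, BI-RADS-graded lesion morphology, or annotation noise from
human readers. Passing desk-scale tests therefore demonstrates that the
architectures, training loop and metrics are implemented correctly and can
learn hypoechoic-lesion segmentation from speckled images — not that the
published clinical accuracy transfers.

## Problem sizes used in tests and the acceptance run

Unit tests exercise 16×16–32×32 models with 2–64 channels. The end-to-end
convergence check and `scripts/acceptance.py` train the quarter-width
RCU-Net (filters 16–256) at 64×64 on 200 phantoms for 30 epochs and
evaluate on 50 held-out phantoms — the package's chosen desk-scale
configuration, small enough for a single CPU while deep enough to exercise
all four pooling levels, every Res Path and the dense connection.

## Known limitations

* Convolutions are stride-1 same-padding only, kernels odd (plus the 2×2
  stride-2 transposed convolution); this covers every published layer but
  is not a general conv library.
* BatchNorm running statistics use momentum 0.1 with batch statistics in
  training mode; very small batches at tiny widths can make eval-mode
  outputs noisy early in training.
* The CLAHE implementation quantizes to 256 bins; images are assumed
  already normalized to [0, 1].
* Full-size (256×256, 64-base-filter) training is supported but slow on
  CPU; the published 120-epoch protocol at that scale is meant for
  accelerator-backed reproduction, not the test suite.
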