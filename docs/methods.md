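# Methods

## Model

The network is a lightweight residual feature-learning CNN for
single-channel single-image super-resolution at scale r ∈ {2, 4}:

```
x ── conv3×3 (1→C) ──┬── ResBlock × B ── conv3×3 (C→C) ──(+)── head ──(+)── y
                     └────────────── feature skip ───────┘          │
x ───────────────────────── bicubic ×r (optional global skip) ──────┘
```

Each **ResBlock** (trunk width C) computes, in order: a 1×1 squeeze;
two parallel 3×3 branches — one with BatchNorm + ReLU, one with ReLU
only — whose concatenation (2C channels) is fused by a 1×1 conv back to
C; the same dual-branch stage a second time; a size-preserving max pool
(kernel 3, stride 1, padding 1); a 1×1 fusion; an enhanced spatial
attention gate; and a block-input residual skip.  With all weights at
zero every branch vanishes and the gate multiplies zeros, so the block
is exactly the identity — a property the tests assert and a useful
sanity anchor for the residual design.

**Enhanced spatial attention (ESA).**  The gate squeezes C channels to
f = C/`esa_reduction` with a 1×1 conv, reduces spatially (3×3 stride-2
conv, then 7×7 stride-3 max pooling), passes a group of two 3×3 convs
with ReLU, upsamples bilinearly back to the input size, adds a 1×1 skip
of the squeezed tensor, projects to a **single** attention channel, and
applies a sigmoid.  The block features are multiplied by this per-pixel
map in (0, 1), broadcast over channels.  A single-channel map (rather
than per-channel) was chosen because spatial selection is the gate's
purpose; the squeeze factor defaults to 4.

**Upsampling head.**  2×: conv3×3 C→4m → pixel shuffle → conv3×3 m→1.
4×: two cascaded ×2 stages (C→4m, shuffle, m→4m₂, shuffle, m₂→1), so
the trunk — and the first head conv — are shared between the scales.

**Global interpolation skip.**  By default the bicubic upscale of the
input is added to the head output (`ModelConfig.global_skip`), making
the network an interpolation-residual learner in the VDSR tradition.
This is a deliberate design choice of this package: with CPU-scale
training budgets (hundreds of steps) a direct-prediction network spends
its entire budget re-learning interpolation, whereas the residual form
starts at bicubic quality and invests every step in the correctable
residual.  The skip has no parameters, so the calibrated budgets are
unaffected; setting the flag off gives the plain direct-prediction
architecture.

## Parameter budgets and width calibration

The architecture's published footprint is 452K trainable scalars at 2×
and 468K at 4×.  Depth is fixed at B = 6; `calibrate_width` searches
trunk width C (multiples of the ESA reduction, ascending) and head
width m (ascending) for the first configuration whose exact count
rounds to the 2× budget, then — holding that trunk and m fixed —
searches the 4× second-stage width m₂ against the 4× budget.  The
search uses closed-form layer arithmetic and cross-checks the winner
against the built model's actual scalar count.  The result, C = 40,
m = 15, m₂ = 28 (with ESA reduction 4 and a 2-conv ESA group), gives
452,442 and 467,791 parameters — both rounding to the printed budgets —
and is baked in as the `ModelConfig` default.

## Training

MSE loss on normalised [0, 1] intensities, optimised with Adam
(β₁ = 0.9, β₂ = 0.999).  Defaults: 600 steps, batch 8, LR-space
patches 32×32, learning rate 2·10⁻³ halved at the midpoint; chosen by
pilot runs as the smallest recipe that reliably clears the bicubic
baseline on clean 2× phantom data.  Validation mean PSNR is computed
every `checkpoint_every` steps and the best-validation weights are the
returned model.  Training aborts with a diagnostic on a non-finite
loss.  All randomness (weight init, patch sampling, data synthesis)
flows from explicit seeds; two runs with the same seed produce
identical losses bitwise.

Weight initialisation is Kaiming-uniform over fan-in with zero biases;
the final conv is additionally scaled by 0.1 so the initial prediction
stays close to the interpolation skip.

The default experiment size in the tests — 20 phantoms, the width-16 /
2-block "desk" configuration (`desk_model_config`, ~30K parameters),
600 steps — is the package's chosen desk-scale study condition; the
full 452K configuration trains with exactly the same loop and is simply
slower per step.

## Synthetic data

The generator emulates two acquisition settings:

* **ct_mri_like** (512×512 default): random rotated ellipses with
  distinct intensities over a rim + tissue-disc base, a smooth
  multiplicative bias field (σ = size/8 Gaussian, ±15%), and slight
  edge smoothing (σ = 0.7) — piecewise-smooth tomography-like anatomy.
* **ultrasound_like** (256×256 default): low-frequency anatomy
  modulated by a Rayleigh-envelope speckle field (|a+bi| of a σ = 1
  Gaussian-filtered complex normal field, mean-normalised, mixed in at
  `speckle_strength` = 0.5) with a few bright inclusions.

Degradation is Gaussian blur (optional) → antialiased bicubic
downsampling (Pillow) → additive Gaussian noise (optional) → clip.
Datasets split 80/10/10 by index (last tenth test, previous tenth
validation), deterministically.

What the phantoms do **not** model: acquisition physics (projection /
k-space sampling, attenuation, shadowing), pathology diversity, scanner
noise spectra, and inter-patient variability.  Passing tests therefore
demonstrate that the implementation learns and measures correctly on
piecewise-smooth, speckled single-channel data — not that the trained
weights transfer to clinical images.

## Metrics

PSNR = 10·log10(MAX²/MSE) with an explicit `max_i` (255 for 8-bit, 1
for normalised floats) and a +inf sentinel for identical images.  SSIM
uses k₁ = 0.01, k₂ = 0.03 and an 11×11 Gaussian window (σ = 1.5) by
default, population moments under the window, and **valid-mode**
borders: only fully-inside window positions contribute to the mean.
The implementation is cross-checked in the tests against brute-force
windowed statistics and against scikit-image's implementation in the
matching configuration.

## Numerical choices

* float32 throughout the network; metric arithmetic in float64.
* BatchNorm: ε = 10⁻⁵, running-statistic momentum 0.1; batch moments
  in training mode, running statistics at inference.
* Max pooling pads with −inf so padded cells never win; the ESA pooling
  (7×7, stride 3, padding 3) guarantees ≥ 1 output cell for any input
  size ≥ 1, so odd and tiny images are handled exactly.
* Bilinear resizing uses half-pixel-center alignment and is applied as
  an explicit linear operator, giving an exact-transpose backward pass.
* Model outputs are clipped to the value range before metrics.
* Checkpoints store weights, BatchNorm running statistics and the
  config; reload is bitwise exact.

## Known limitations

* CPU-only NumPy execution: roughly 0.2 s per training step at the
  desk scale, seconds per 512×512 image at the full width — fine for
  study and testing, far from clinical throughput.
* The class-balancing step described for annotated clinical corpora
  has no analogue for unlabelled synthetic pairs and is out of scope.
* Runtime [ms] columns in benchmark reports are informational only.
* `in_channels` > 1 is plumbed through but untested; the intended
  domain is single-channel imagery.
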