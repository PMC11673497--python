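# medsr

Lightweight single-image super-resolution (SISR) for single-channel
medical images — CT, MRI and ultrasound — built around a residual
feature-learning CNN with enhanced spatial attention (ESA).

Medical scanners often deliver images whose resolution limits what a
radiologist can see; SISR reconstructs a high-resolution (HR) image from
a single low-resolution (LR) acquisition. `medsr` provides:

* the network: a shallow 3×3 conv, a trunk of modified residual blocks
  (dual BatchNorm / plain 3×3 branches fused through concatenations and
  1×1 convs, size-preserving max pooling, an ESA sigmoid gate, and a
  block-input skip), a global feature skip, and a pixel-shuffle
  upsampling head for 2× and 4×;
* width calibration of the open hyperparameters against the published
  lightweight budgets — 452K trainable parameters at 2×, 468K at 4×
  (same trunk, different head);
* reference PSNR (`10·log10(MAX²/MSE)`) and windowed SSIM metrics;
* a seeded synthetic phantom generator (CT/MRI-like 512×512,
  ultrasound-like 256×256 with speckle) plus the HR→LR degradation
  pipeline (Gaussian blur → bicubic downsample → Gaussian noise), so
  everything runs without external data;
* a preprocessing/augmentation pipeline (quarter-turn
  rotations, flips, brightness/contrast jitter, noise/blur), an MSE
  training loop with Adam, checkpointing, and a benchmark harness
  reporting Params [K] / Runtime [ms] / PSNR / SSIM against a bicubic
  baseline.

Everything — convolutions, BatchNorm, pooling, pixel shuffle, bilinear
resizing, backpropagation and Adam — is implemented in NumPy
(`medsr.nn`), so the package has no deep-learning-framework dependency
and runs on any CPU.

## Worked example

Train the desk-scale model (width 16, two blocks, ~30K parameters) on
twelve synthetic CT/MRI-like phantoms and compare against bicubic
interpolation on the held-out split:

```python
from medsr import (
    DegradationSpec, PhantomSpec, TrainOptions, BicubicBaseline,
    build_model, desk_model_config, evaluate, make_dataset, train,
)

dataset = make_dataset(
    12,
    PhantomSpec(modality="ct_mri_like", size=256, seed=0),
    DegradationSpec(scale=2, seed=10_000),
)
baseline = evaluate(BicubicBaseline(2), dataset, name="bicubic")
model = build_model(desk_model_config(scale=2, seed=0))
model, history = train(model, dataset, TrainOptions(steps=300, seed=0))
ours = evaluate(model, dataset, name="ours")
for row in (baseline, ours):
    print(f"{row['model']:>8}: params {row['params_k']:3d}K  "
          f"PSNR {row['psnr_db']:.2f} dB  SSIM {row['ssim']:.4f}")
```

Output (about a minute on one CPU):

```
 bicubic: params   0K  PSNR 34.21 dB  SSIM 0.9858
    ours: params  30K  PSNR 35.61 dB  SSIM 0.9792
```

The trained network recovers about 1.4 dB of PSNR over plain bicubic
upscaling: it has learned to sharpen the phantom edges that
interpolation blurs.  (PSNR measures mean-squared fidelity on the
0–1 intensity scale; SSIM the windowed structural agreement.)

The same workflow is available from the shell:

```bash
medsr generate --modality ct_mri_like --n 20 --scale 2 --seed 1 --out data/
medsr train --data data/manifest.tsv --steps 300 --seed 1 --out model.npz
medsr eval --data data/manifest.tsv --model model.npz
medsr upscale input.png --model model.npz --out output.png
medsr benchmark --n 6 --size 128 --steps 200   # full table vs bicubic
```

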