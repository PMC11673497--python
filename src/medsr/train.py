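"""MSE training loop, validation checkpointing, and PSNR/SSIM evaluation.

The loss is the mean squared error between predicted and ground-truth
HR intensities, computed on normalised [0, 1] values.  Each step samples
a batch of aligned random LR/HR patch pairs from the training split,
runs forward/backward, and takes one Adam step.  The "best" checkpoint
is the one with the highest validation mean PSNR; training is
deterministic given the seed on one device.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field

import numpy as np

from . import nn
from .data import SRDataset, bicubic_upscale
from .errors import ConfigError, ContractError
from .metrics import SsimParams, psnr, ssim
from .model import Model, count_parameters


@dataclass
class TrainOptions:
    """Optimisation hyperparameters (artifact choices, exposed for study)."""

    steps: int = 600
    batch_size: int = 8
    patch_size: int = 32  # LR-space patch edge
    learning_rate: float = 2e-3
    lr_schedule: str = "step"  # 'constant' or 'step'
    lr_gamma: float = 0.5
    lr_step_every: int = 0  # 0 -> half of the total steps
    beta1: float = 0.9
    beta2: float = 0.999
    seed: int = 0
    checkpoint_every: int = 100  # validation / best-tracking cadence
    device: str = "cpu"

    def __post_init__(self) -> None:
        if self.steps < 0 or self.batch_size < 1 or self.patch_size < 8:
            raise ConfigError("invalid steps/batch_size/patch_size")
        if self.learning_rate <= 0:
            raise ConfigError("learning_rate must be > 0")
        if self.lr_schedule not in ("constant", "step"):
            raise ConfigError("lr_schedule must be 'constant' or 'step'")
        if self.device != "cpu":
            raise ConfigError("only cpu execution is implemented")


@dataclass
class TrainHistory:
    losses: list[float] = field(default_factory=list)
    lr_values: list[float] = field(default_factory=list)
    val_steps: list[int] = field(default_factory=list)
    val_psnr: list[float] = field(default_factory=list)
    val_ssim: list[float] = field(default_factory=list)
    wall_seconds: float = 0.0

    def to_csv(self) -> str:
        lines = ["step,loss,lr"]
        for i, (loss, lr) in enumerate(zip(self.losses, self.lr_values)):
            lines.append(f"{i + 1},{loss:.8g},{lr:.8g}")
        return "\n".join(lines) + "\n"


def _sample_batch(
    pairs: list[tuple[np.ndarray, np.ndarray]],
    patch: int,
    batch: int,
    scale: int,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    lrs, hrs = [], []
    for _ in range(batch):
        lr, hr = pairs[int(rng.integers(len(pairs)))]
        y = int(rng.integers(0, lr.shape[0] - patch + 1))
        x = int(rng.integers(0, lr.shape[1] - patch + 1))
        lrs.append(lr[y : y + patch, x : x + patch])
        hrs.append(
            hr[y * scale : (y + patch) * scale, x * scale : (x + patch) * scale]
        )
    return (
        np.stack(lrs)[:, None].astype(nn.DTYPE),
        np.stack(hrs)[:, None].astype(nn.DTYPE),
    )


def _mean_val_psnr(model: Model, dataset: SRDataset) -> float:
    vals = []
    for lr, hr in dataset.pairs("val"):
        sr = np.clip(model.predict(lr), 0.0, 1.0)
        vals.append(psnr(sr, hr, 1.0))
    return float(np.mean(vals)) if vals else float("nan")


def train(
    model: Model, dataset: SRDataset, opts: TrainOptions
) -> tuple[Model, TrainHistory]:
    """Minimise the MSE loss over sampled patch batches.

    Returns the best-validation model (the input model object, with its
    weights set to the best checkpoint) and the full history.
    """
    if len(dataset) == 0 or not dataset.train_idx:
        raise ContractError("dataset has no training pairs")
    scale = dataset.scale
    if model.config.scale != scale:
        raise ContractError(
            f"model scale {model.config.scale} != dataset scale {scale}"
        )
    pairs = dataset.pairs("train")
    if any(min(lr.shape) < opts.patch_size for lr, _ in pairs):
        raise ContractError("patch_size larger than an LR training image")

    history = TrainHistory()
    if opts.steps == 0:
        return model, history

    start = time.perf_counter()
    rng = np.random.default_rng(opts.seed)
    params = model.parameters()
    optimiser = nn.Adam(
        params, lr=opts.learning_rate, beta1=opts.beta1, beta2=opts.beta2
    )
    step_every = opts.lr_step_every or max(1, opts.steps // 2)
    best_psnr = -np.inf
    best_state = None

    for step in range(1, opts.steps + 1):
        if opts.lr_schedule == "step":
            optimiser.lr = opts.learning_rate * (
                opts.lr_gamma ** ((step - 1) // step_every)
            )
        x, y = _sample_batch(pairs, opts.patch_size, opts.batch_size, scale, rng)
        out = model.forward(x, training=True)
        diff = out - y
        loss = float(np.mean(diff.astype(np.float64) ** 2))
        if not np.isfinite(loss):
            raise RuntimeError(
                f"non-finite loss {loss} at step {step}; "
                "lower the learning rate or check the data"
            )
        optimiser.zero_grad()
        model.backward((2.0 / diff.size) * diff.astype(nn.DTYPE))
        optimiser.step()
        history.losses.append(loss)
        history.lr_values.append(optimiser.lr)

        if step % opts.checkpoint_every == 0 or step == opts.steps:
            val = _mean_val_psnr(model, dataset)
            history.val_steps.append(step)
            history.val_psnr.append(val)
            history.val_ssim.append(float("nan"))  # tracked on demand only
            if not np.isnan(val) and val > best_psnr:
                best_psnr = val
                best_state = (
                    [p.data.copy() for p in params],
                    [(name, buf.copy()) for name, buf in model.buffers()],
                )

    if best_state is not None:
        weights, buffers = best_state
        for p, w in zip(params, weights):
            p.data = w
        for (_, buf), (_, saved) in zip(model.buffers(), buffers):
            buf[...] = saved
    history.wall_seconds = time.perf_counter() - start
    return model, history


class BicubicBaseline:
    """Zero-parameter baseline exposing the same predict contract."""

    def __init__(self, scale: int):
        self.scale = scale

    def predict(self, image: np.ndarray) -> np.ndarray:
        return bicubic_upscale(image, self.scale)


def evaluate(
    model,
    dataset: SRDataset,
    max_i: float = 1.0,
    split: str = "test",
    name: str | None = None,
) -> dict:
    """Mean PSNR / mean SSIM of model outputs vs HR over a split.

    ``model`` is anything with a ``predict(lr) -> sr`` method (a trained
    network or the bicubic baseline).  Runtime per image is measured and
    reported but informational only.
    """
    pairs = dataset.pairs(split)
    if not pairs:
        raise ContractError(f"split {split!r} is empty")
    if isinstance(model, Model) and model.config.scale != dataset.scale:
        raise ContractError("model scale does not match dataset scale")
    ssim_params = SsimParams(dynamic_range=max_i)
    psnrs, ssims, times = [], [], []
    for lr, hr in pairs:
        t0 = time.perf_counter()
        sr = model.predict(lr)
        times.append(1000.0 * (time.perf_counter() - t0))
        sr = np.clip(sr, 0.0, max_i)
        psnrs.append(psnr(sr, hr, max_i))
        ssims.append(ssim(sr, hr, ssim_params))
    n_params = count_parameters(model) if isinstance(model, Model) else 0
    return {
        "model": name or type(model).__name__,
        "params": n_params,
        "params_k": round(n_params / 1000),
        "runtime_ms": float(np.mean(times)),
        "psnr_db": float(np.mean(psnrs)),
        "ssim": float(np.mean(ssims)),
        "n_images": len(pairs),
    }
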