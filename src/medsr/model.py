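"""The lightweight residual-attention super-resolution network.

The network maps a single-channel low-resolution image to an r-times
larger image (r in {2, 4}).  Macro-structure::

    3x3 conv (1 -> C)                      shallow feature extraction
    B modified residual blocks             trunk
    3x3 conv (C -> C)  + shallow skip
    upsampling head (conv -> pixel shuffle [-> conv -> pixel shuffle] -> conv)

Each residual block runs a 1x1 squeeze, two parallel 3x3 branches (one
with BatchNorm), a 1x1 fusion of their concatenation, a second such
dual-branch stage, a size-preserving max pool, a 1x1 fusion, an enhanced
spatial attention (ESA) gate, and finally adds the block input back
(residual skip), so a zero-weight block is the identity map.

ESA squeezes channels by ``esa_reduction``, reduces spatially (stride-2
conv + max pooling), passes a small conv group, upsamples bilinearly
back, adds a 1x1 skip of the squeezed input, projects to a single
channel and gates the block features with a per-pixel sigmoid map.

Default widths come from calibrating the trainable-parameter count to
the published budgets of 452K (2x) and 468K (4x); see
:func:`calibrate_width`.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict, replace

import numpy as np

from . import nn
from .errors import CalibrationError, ConfigError, ContractError

# Published parameter budgets (thousands) for the two scales.
BUDGET_2X_KPARAMS = 452
BUDGET_4X_KPARAMS = 468

# Calibrated defaults (depth fixed at 6; widths from calibrate_width).
DEFAULT_NUM_BLOCKS = 6
DEFAULT_FEATURE_WIDTH = 40
DEFAULT_HEAD_WIDTH = 15
DEFAULT_HEAD_WIDTH2 = 28


@dataclass
class ModelConfig:
    """All architecture hyperparameters.

    Parameters
    ----------
    scale : upscaling factor r, 2 or 4.
    in_channels : image channels (medical images here are single-channel).
    feature_width : trunk channel count C.
    num_blocks : number of residual blocks B.
    esa_reduction : channel-squeeze divisor inside the attention gate.
    esa_group_convs : number of 3x3 convs in the ESA conv group.
    use_bn_branch : whether the BatchNorm branches are active.
    pool_kernel : kernel of the size-preserving max pool (stride 1).
    head_width : channel count m entering the first pixel shuffle.
    head_width2 : channel count of the second 4x head stage (ignored at 2x).
    global_skip : add the bicubic upscale of the input to the head output
        (parameter-free interpolation-residual learning; makes short
        training budgets productive by letting the network model only the
        residual over plain interpolation).
    seed : RNG seed for weight initialisation.
    """

    scale: int = 2
    in_channels: int = 1
    feature_width: int = DEFAULT_FEATURE_WIDTH
    num_blocks: int = DEFAULT_NUM_BLOCKS
    esa_reduction: int = 4
    esa_group_convs: int = 2
    use_bn_branch: bool = True
    pool_kernel: int = 3
    head_width: int = DEFAULT_HEAD_WIDTH
    head_width2: int = DEFAULT_HEAD_WIDTH2
    global_skip: bool = True
    seed: int = 0

    def validate(self) -> None:
        if self.scale not in (2, 4):
            raise ConfigError(f"scale must be 2 or 4, got {self.scale}")
        if self.feature_width < 4:
            raise ConfigError("feature_width must be >= 4")
        if self.num_blocks < 1:
            raise ConfigError("num_blocks must be >= 1")
        if self.esa_reduction < 1 or self.feature_width % self.esa_reduction:
            raise ConfigError(
                f"esa_reduction {self.esa_reduction} must divide "
                f"feature_width {self.feature_width}"
            )
        if self.esa_group_convs < 1:
            raise ConfigError("esa_group_convs must be >= 1")
        if self.pool_kernel < 1 or self.pool_kernel % 2 == 0:
            raise ConfigError("pool_kernel must be odd and >= 1")
        if self.head_width < 1 or (self.scale == 4 and self.head_width2 < 1):
            raise ConfigError("head widths must be >= 1")


class ESA(nn.Module):
    """Enhanced spatial attention: a per-pixel sigmoid gate in (0, 1)."""

    def __init__(self, channels: int, reduction: int, group_convs: int, rng):
        f = channels // reduction
        self.channels = channels
        self.conv_squeeze = nn.Conv2d(channels, f, 1, rng)
        self.conv_skip = nn.Conv2d(f, f, 1, rng)
        self.conv_stride = nn.Conv2d(f, f, 3, rng, stride=2, padding=1)
        self.pool = nn.MaxPool2d(7, 3, padding=3)
        self.group = [nn.Conv2d(f, f, 3, rng) for _ in range(group_convs)]
        self.group_act = [nn.ReLU() for _ in range(group_convs)]
        self.resize = nn.BilinearResize()
        self.conv_out = nn.Conv2d(f, 1, 1, rng)
        self.sigmoid = nn.Sigmoid()
        self._cache = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        if x.shape[1] != self.channels:
            raise ContractError(
                f"ESA expects {self.channels} channels, got {x.shape[1]}"
            )
        t = self.conv_squeeze.forward(x)
        skip = self.conv_skip.forward(t)
        s = self.conv_stride.forward(t)
        s = self.pool.forward(s)
        for conv, act in zip(self.group, self.group_act):
            s = act.forward(conv.forward(s))
        s = self.resize.forward(s, x.shape[2:])
        u = s + skip
        a = self.conv_out.forward(u)
        gate = self.sigmoid.forward(a)
        self._cache = (x, gate)
        return x * gate

    def attention_map(self, x: np.ndarray) -> np.ndarray:
        """The gate alone, for inspection; entries lie in (0, 1)."""
        self.forward(x)
        _, gate = self._cache
        self._cache = None
        return gate

    def backward(self, grad: np.ndarray) -> np.ndarray:
        x, gate = self._cache
        self._cache = None
        dgate = (grad * x).sum(axis=1, keepdims=True)
        dx = grad * gate
        da = self.sigmoid.backward(dgate)
        du = self.conv_out.backward(da)
        ds = self.resize.backward(du)
        for conv, act in zip(reversed(self.group), reversed(self.group_act)):
            ds = conv.backward(act.backward(ds))
        ds = self.pool.backward(ds)
        dt = self.conv_stride.backward(ds) + self.conv_skip.backward(du)
        dx += self.conv_squeeze.backward(dt)
        return dx


class ResBlock(nn.Module):
    """The modified residual block (see module docstring)."""

    def __init__(self, config: ModelConfig, rng):
        c = config.feature_width
        self.channels = c
        self.use_bn = config.use_bn_branch
        self.conv1 = nn.Conv2d(c, c, 1, rng)
        self.conv2 = nn.Conv2d(c, c, 3, rng)
        self.bn2 = nn.BatchNorm2d(c)
        self.relu2 = nn.ReLU()
        self.conv3 = nn.Conv2d(c, c, 3, rng)
        self.relu3 = nn.ReLU()
        self.conv4 = nn.Conv2d(2 * c, c, 1, rng)
        self.conv5 = nn.Conv2d(c, c, 3, rng)
        self.bn5 = nn.BatchNorm2d(c)
        self.relu5 = nn.ReLU()
        self.conv6 = nn.Conv2d(c, c, 3, rng)
        self.relu6 = nn.ReLU()
        self.pool = nn.MaxPool2d(
            config.pool_kernel, 1, padding=config.pool_kernel // 2
        )
        self.conv8 = nn.Conv2d(2 * c, c, 1, rng)
        self.esa = ESA(c, config.esa_reduction, config.esa_group_convs, rng)

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        if x.shape[1] != self.channels:
            raise ContractError(
                f"ResBlock expects {self.channels} channels, got {x.shape[1]}"
            )
        l1 = self.conv1.forward(x)
        b2 = self.conv2.forward(l1)
        if self.use_bn:
            b2 = self.bn2.forward(b2, training)
        l2 = self.relu2.forward(b2)
        l3 = self.relu3.forward(self.conv3.forward(l1))
        l4 = self.conv4.forward(np.concatenate([l2, l3], axis=1))
        b5 = self.conv5.forward(l4)
        if self.use_bn:
            b5 = self.bn5.forward(b5, training)
        l5 = self.relu5.forward(b5)
        l6 = self.relu6.forward(self.conv6.forward(l4))
        l7 = np.concatenate([l6, l5], axis=1)
        l8 = self.conv8.forward(self.pool.forward(l7))
        l9 = self.esa.forward(l8)
        return x + l9

    def backward(self, grad: np.ndarray) -> np.ndarray:
        c = self.channels
        dl8 = self.esa.backward(grad)
        dl7 = self.pool.backward(self.conv8.backward(dl8))
        dl6, dl5 = dl7[:, :c], dl7[:, c:]
        dl4 = self.conv6.backward(self.relu6.backward(dl6))
        d5 = self.relu5.backward(dl5)
        if self.use_bn:
            d5 = self.bn5.backward(d5)
        dl4 = dl4 + self.conv5.backward(d5)
        dl23 = self.conv4.backward(dl4)
        dl2, dl3 = dl23[:, :c], dl23[:, c:]
        d2 = self.relu2.backward(dl2)
        if self.use_bn:
            d2 = self.bn2.backward(d2)
        dl1 = self.conv2.backward(d2)
        dl1 = dl1 + self.conv3.backward(self.relu3.backward(dl3))
        return self.conv1.backward(dl1) + grad


class Model(nn.Module):
    """The full network; built by :func:`build_model`."""

    def __init__(self, config: ModelConfig):
        config.validate()
        self.config = config
        rng = np.random.default_rng(config.seed)
        c, m = config.feature_width, config.head_width
        self.conv_in = nn.Conv2d(config.in_channels, c, 3, rng)
        self.blocks = [ResBlock(config, rng) for _ in range(config.num_blocks)]
        self.conv_mid = nn.Conv2d(c, c, 3, rng)
        self.conv_up1 = nn.Conv2d(c, 4 * m, 3, rng)
        self.shuffle1 = nn.PixelShuffle(2)
        if config.scale == 2:
            self.conv_out = nn.Conv2d(m, config.in_channels, 3, rng)
        else:  # two cascaded x2 stages share the trunk with the 2x model
            m2 = config.head_width2
            self.conv_up2 = nn.Conv2d(m, 4 * m2, 3, rng)
            self.shuffle2 = nn.PixelShuffle(2)
            self.conv_out = nn.Conv2d(m2, config.in_channels, 3, rng)
        # down-scale the final conv so the initial output stays close to
        # the interpolation skip (stabilises short training runs)
        self.conv_out.weight.data *= nn.DTYPE(0.1)
        self._cache = None

    # -- forward / backward over NCHW batches ---------------------------

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        if x.ndim != 4 or x.shape[1] != self.config.in_channels:
            raise ContractError(
                f"expected NCHW input with {self.config.in_channels} "
                f"channel(s), got shape {x.shape}"
            )
        shallow = self.conv_in.forward(x.astype(nn.DTYPE))
        t = shallow
        for block in self.blocks:
            t = block.forward(t, training)
        t = self.conv_mid.forward(t) + shallow
        h = self.shuffle1.forward(self.conv_up1.forward(t))
        if self.config.scale == 4:
            h = self.shuffle2.forward(self.conv_up2.forward(h))
        out = self.conv_out.forward(h)
        if self.config.global_skip:
            out = out + self._upscale_input(x)
        return out

    def _upscale_input(self, x: np.ndarray) -> np.ndarray:
        from .data import _pil_resize  # no import cycle: data has no model dep

        r = self.config.scale
        n, c, h, w = x.shape
        up = np.empty((n, c, h * r, w * r), dtype=nn.DTYPE)
        for i in range(n):
            for j in range(c):
                up[i, j] = _pil_resize(x[i, j], (h * r, w * r))
        return up

    def backward(self, grad: np.ndarray) -> np.ndarray:
        g = self.conv_out.backward(grad)
        if self.config.scale == 4:
            g = self.conv_up2.backward(self.shuffle2.backward(g))
        g = self.conv_up1.backward(self.shuffle1.backward(g))
        gs = self.conv_mid.backward(g)
        for block in reversed(self.blocks):
            gs = block.backward(gs)
        # the shallow skip feeds both the trunk and the residual add
        return self.conv_in.backward(gs + g)

    # -- image-level convenience ----------------------------------------

    def predict(self, image: np.ndarray) -> np.ndarray:
        """Upscale one H x W image (float in [0, 1]) to rH x rW."""
        if image.ndim != 2:
            raise ContractError(f"predict expects a 2-D image, got {image.shape}")
        x = image[None, None].astype(nn.DTYPE)
        return self.forward(x, training=False)[0, 0]


def build_model(config: ModelConfig) -> Model:
    """Build the network; weights are a deterministic function of
    ``config.seed``."""
    return Model(config)


def count_parameters(model: Model) -> int:
    """Exact number of trainable scalars (conv weights/biases, BN scale/shift).

    BatchNorm running statistics are buffers, not trained, and are not
    counted."""
    return sum(p.size for p in model.parameters())


def zero_weights(model: Model) -> Model:
    """Set every trainable scalar to zero (diagnostic: the trunk collapses
    to the shallow features because each block becomes the identity)."""
    for p in model.parameters():
        p.data.fill(0.0)
    return model


def desk_model_config(scale: int = 2, seed: int = 0) -> ModelConfig:
    """Reduced configuration for CPU-scale experiments (training studies,
    benchmarks): width 16, two blocks, head width 8.  The full calibrated
    architecture is the ``ModelConfig()`` default."""
    return ModelConfig(
        scale=scale, feature_width=16, num_blocks=2,
        head_width=8, head_width2=8, seed=seed,
    )


# -- width calibration against the published budgets --------------------


def _conv_params(k: int, cin: int, cout: int) -> int:
    return k * k * cin * cout + cout


def _arch_params(cfg: ModelConfig) -> int:
    """Closed-form parameter count mirroring the layer construction;
    calibration uses this to avoid building thousands of candidate models.
    ``calibrate_width`` cross-checks the winner against the built model."""
    c, f = cfg.feature_width, cfg.feature_width // cfg.esa_reduction
    esa = (
        _conv_params(1, c, f)
        + _conv_params(1, f, f)
        + _conv_params(3, f, f)
        + cfg.esa_group_convs * _conv_params(3, f, f)
        + _conv_params(1, f, 1)
    )
    bn = 2 * c if cfg.use_bn_branch else 0
    block = (
        _conv_params(1, c, c)
        + 2 * (_conv_params(3, c, c) + bn)
        + 2 * _conv_params(3, c, c)
        + 2 * _conv_params(1, 2 * c, c)
        + esa
    )
    total = (
        _conv_params(3, cfg.in_channels, c)
        + cfg.num_blocks * block
        + _conv_params(3, c, c)
        + _conv_params(3, c, 4 * cfg.head_width)
    )
    if cfg.scale == 2:
        total += _conv_params(3, cfg.head_width, cfg.in_channels)
    else:
        total += _conv_params(3, cfg.head_width, 4 * cfg.head_width2)
        total += _conv_params(3, cfg.head_width2, cfg.in_channels)
    return total


def calibrate_width(
    budget_kparams: int,
    scale: int,
    base: ModelConfig | None = None,
    num_blocks: int = DEFAULT_NUM_BLOCKS,
    esa_reduction: int = 4,
    max_width: int = 128,
) -> ModelConfig:
    """Find the first configuration whose parameter count rounds to
    ``budget_kparams`` thousands.

    Search order (documented contract): trunk width C ascending in steps
    of ``esa_reduction``, then head width m ascending (4 .. max(2C, 96)).
    For ``scale == 4`` the trunk and first head stage are taken from the
    calibrated 2x configuration (``base`` if given, else the result of
    calibrating scale 2 against the published 2x budget) and only the
    second-stage head width is searched, so the two scales share the
    trunk by construction.
    """
    if budget_kparams <= 0:
        raise CalibrationError("budget must be positive")
    if scale not in (2, 4):
        raise ConfigError(f"scale must be 2 or 4, got {scale}")

    if scale == 4:
        if base is None:
            base = calibrate_width(
                BUDGET_2X_KPARAMS, 2, num_blocks=num_blocks,
                esa_reduction=esa_reduction, max_width=max_width,
            )
        for m2 in range(4, max(2 * base.feature_width, 96) + 1):
            cfg = replace(base, scale=4, head_width2=m2)
            if round(_arch_params(cfg) / 1000) == budget_kparams:
                return _verified(cfg)
        raise CalibrationError(
            f"no 4x head width reaches {budget_kparams}K on the given trunk"
        )

    for c in range(2 * esa_reduction, max_width + 1, esa_reduction):
        for m in range(4, max(2 * c, 96) + 1):
            cfg = ModelConfig(
                scale=2,
                feature_width=c,
                num_blocks=num_blocks,
                esa_reduction=esa_reduction,
                head_width=m,
            )
            if round(_arch_params(cfg) / 1000) == budget_kparams:
                return _verified(cfg)
    raise CalibrationError(
        f"no configuration within width {max_width} reaches {budget_kparams}K"
    )


def _verified(cfg: ModelConfig) -> ModelConfig:
    built = count_parameters(build_model(cfg))
    if built != _arch_params(cfg):
        raise AssertionError(
            f"calibration arithmetic ({_arch_params(cfg)}) disagrees with the "
            f"built model ({built}); architecture drift"
        )
    return cfg


# -- checkpointing -------------------------------------------------------


def save_checkpoint(model: Model, path) -> None:
    """Write weights + running stats + config as a flat named archive."""
    arrays = {f"param_{i}": p.data for i, p in enumerate(model.parameters())}
    arrays.update(
        {f"buffer_{i}": b for i, (_, b) in enumerate(model.buffers())}
    )
    arrays["config_json"] = np.frombuffer(
        json.dumps(asdict(model.config)).encode(), dtype=np.uint8
    )
    with open(path, "wb") as fh:
        np.savez(fh, **arrays)


def load_checkpoint(path) -> Model:
    """Rebuild a model from :func:`save_checkpoint` output; the rebuild is
    exact (same dtypes, bitwise-equal weights)."""
    with np.load(path) as archive:
        cfg = ModelConfig(**json.loads(bytes(archive["config_json"]).decode()))
        model = build_model(cfg)
        for i, p in enumerate(model.parameters()):
            data = archive[f"param_{i}"]
            if data.shape != p.data.shape:
                raise ContractError("checkpoint does not match architecture")
            p.data = data.astype(nn.DTYPE)
        for i, (_, buf) in enumerate(model.buffers()):
            buf[...] = archive[f"buffer_{i}"]
    return model
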