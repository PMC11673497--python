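"""Synthetic phantoms, degradation pipeline, bicubic baseline and I/O."""

import numpy as np
import pytest

from medsr import (
    ConfigError,
    ContractError,
    DegradationSpec,
    PhantomSpec,
    bicubic_upscale,
    degrade,
    make_dataset,
    make_phantom,
    psnr,
    read_dataset,
    read_image,
    write_dataset,
    write_image,
)


# -- phantoms ------------------------------------------------------------


@pytest.mark.parametrize("modality,size", [("ct_mri_like", 512), ("ultrasound_like", 256)])
def test_phantom_default_sizes(modality, size):
    img = make_phantom(PhantomSpec(modality=modality, seed=0))
    assert img.shape == (size, size)


@pytest.mark.parametrize("modality", ["ct_mri_like", "ultrasound_like"])
def test_phantom_deterministic_and_in_range(modality):
    spec = PhantomSpec(modality=modality, size=128, seed=11)
    a = make_phantom(spec)
    b = make_phantom(PhantomSpec(modality=modality, size=128, seed=11))
    assert np.array_equal(a, b)
    assert a.min() >= 0.0 and a.max() <= 1.0
    c = make_phantom(PhantomSpec(modality=modality, size=128, seed=12))
    assert not np.array_equal(a, c)


def test_phantom_has_structure():
    img = make_phantom(PhantomSpec(modality="ct_mri_like", size=128, seed=0))
    assert img.std() > 0.05  # not a constant field


def test_phantom_spec_errors():
    with pytest.raises(ConfigError):
        PhantomSpec(size=32)
    with pytest.raises(ConfigError):
        PhantomSpec(size=130)  # not divisible by 4
    with pytest.raises(ConfigError):
        PhantomSpec(modality="xray")


# -- degradation ---------------------------------------------------------


def test_degrade_shape_contract():
    hr = np.zeros((512, 512), dtype=np.float32)
    assert degrade(hr, DegradationSpec(scale=2)).shape == (256, 256)
    assert degrade(hr, DegradationSpec(scale=4)).shape == (128, 128)


def test_degrade_preserves_constant_without_noise():
    hr = np.full((64, 64), 0.6, dtype=np.float32)
    lr = degrade(hr, DegradationSpec(scale=2, blur_sigma=1.0, noise_sigma=0.0))
    assert np.allclose(lr[2:-2, 2:-2], 0.6, atol=1e-4)


def test_degrade_noise_deterministic_per_seed():
    hr = make_phantom(PhantomSpec(size=128, seed=0))
    spec = DegradationSpec(scale=2, noise_sigma=0.05, seed=9)
    assert np.array_equal(degrade(hr, spec), degrade(hr, spec))
    other = DegradationSpec(scale=2, noise_sigma=0.05, seed=10)
    assert not np.array_equal(degrade(hr, spec), degrade(hr, other))


def test_degrade_noise_statistics():
    """Mean ~ 0 and std ~ sigma within 3 standard errors over >= 1e4 px."""
    hr = np.full((256, 256), 0.5, dtype=np.float32)  # constant: clean LR known
    sigma = 0.02  # small vs the 0.5 offset, so clipping never triggers
    clean = degrade(hr, DegradationSpec(scale=2, noise_sigma=0.0))
    noisy = degrade(hr, DegradationSpec(scale=2, noise_sigma=sigma, seed=1))
    delta = (noisy - clean).astype(np.float64).ravel()
    n = delta.size
    assert n >= 10_000
    assert abs(delta.mean()) < 3 * sigma / np.sqrt(n)
    se_std = sigma / np.sqrt(2 * (n - 1))
    assert abs(delta.std(ddof=1) - sigma) < 3 * se_std


def test_degrade_rejects_nondivisible_dims():
    with pytest.raises(ContractError):
        degrade(np.zeros((65, 64)), DegradationSpec(scale=2))


# -- bicubic baseline ----------------------------------------------------


def test_bicubic_upscale_shapes():
    lr = np.zeros((128, 96), dtype=np.float32)
    assert bicubic_upscale(lr, 2).shape == (256, 192)
    assert bicubic_upscale(lr, 4).shape == (512, 384)


def test_bicubic_upscale_constant():
    lr = np.full((32, 32), 0.4, dtype=np.float32)
    assert np.allclose(bicubic_upscale(lr, 2), 0.4, atol=1e-6)


def test_bicubic_upscale_linear_ramp_oracle():
    """Cubic kernels reproduce linear functions exactly; the upscaled ramp
    must match the analytic ramp under half-pixel-center alignment, away
    from the clamped border."""
    w = 64
    ramp = np.tile(np.linspace(0.1, 0.9, w, dtype=np.float32), (16, 1))
    a = (0.9 - 0.1) / (w - 1)
    up = bicubic_upscale(ramp, 2)
    src = (np.arange(2 * w) + 0.5) / 2.0 - 0.5
    expected = 0.1 + a * src
    assert np.allclose(up[8, 4:-4], expected[4:-4], atol=1e-4)


# -- datasets ------------------------------------------------------------


def test_make_dataset_pairs_and_splits():
    ds = make_dataset(
        10, PhantomSpec(size=64, seed=0), DegradationSpec(scale=2, seed=100)
    )
    assert len(ds) == 10
    for lr, hr in zip(ds.lr, ds.hr):
        assert hr.shape == (lr.shape[0] * 2, lr.shape[1] * 2)
    all_idx = sorted(ds.train_idx + ds.val_idx + ds.test_idx)
    assert all_idx == list(range(10))  # disjoint, covering
    assert len(ds.train_idx) == 8 and len(ds.val_idx) == 1 and len(ds.test_idx) == 1


def test_make_dataset_reproducible():
    args = (
        5,
        PhantomSpec(size=64, seed=4),
        DegradationSpec(scale=2, noise_sigma=0.02, seed=7),
    )
    a, b = make_dataset(*args), make_dataset(*args)
    for i in range(5):
        assert np.array_equal(a.hr[i], b.hr[i])
        assert np.array_equal(a.lr[i], b.lr[i])


def test_roundtrip_bicubic_psnr_reasonable(small_dataset):
    """Degradation is lossy but bounded: bicubic reconstruction stays
    comfortably above 10 dB on default phantoms."""
    for lr, hr in small_dataset.pairs("test"):
        value = psnr(bicubic_upscale(lr, 2), hr, 1.0)
        assert np.isfinite(value) and value > 10.0


# -- I/O -----------------------------------------------------------------


@pytest.mark.parametrize("ext,atol", [("png", 1 / 255), ("tiff", 1 / 65535), ("npy", 0)])
def test_image_write_read_roundtrip(tmp_path, ext, atol):
    img = make_phantom(PhantomSpec(size=64, seed=2))
    path = tmp_path / f"img.{ext}"
    write_image(path, img)
    back = read_image(path)
    assert back.shape == img.shape
    assert np.allclose(back, img, atol=atol + 1e-7)


def test_dataset_write_read_roundtrip(tmp_path):
    ds = make_dataset(4, PhantomSpec(size=64, seed=1), DegradationSpec(scale=2, seed=5))
    manifest = write_dataset(ds, tmp_path / "d", fmt="npy")
    back = read_dataset(manifest)
    assert back.scale == 2
    assert len(back) == 4
    for i in range(4):
        assert np.array_equal(back.hr[i], ds.hr[i])
    assert back.train_idx == ds.train_idx
    assert back.test_idx == ds.test_idx
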