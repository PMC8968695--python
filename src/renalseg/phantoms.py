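"""Synthetic CT-like kidney phantoms.

Each slice shows one or two bright rotated-ellipse "kidneys" on a darker
background; a kidney may embed a round "tumor" of contrasting intensity
(darker or brighter than the parenchyma, chosen per kidney).  Gaussian noise
is added everywhere and a small fraction of isolated pixels is set to
extreme values, emulating metal-artifact voxels so that percentile clipping
in the preparation stage has something to remove.

The generator is a pure function of its configuration (including the seed):
identical configs produce bit-identical volumes.  The phantoms deliberately
carry the structure the segmentation cascade assumes — tumors strictly
inside kidneys, labels {0, 1, 2} — but make no attempt at anatomical realism
or Hounsfield-unit physics.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from skimage.draw import disk, ellipse

from .errors import ConfigurationError
from .preprocess import SliceSample

__all__ = ["PhantomConfig", "generate_phantom_volume", "generate_slice_dataset",
           "write_case_dir", "write_slice_png"]

# intensity palette (arbitrary CT-like units)
_BACKGROUND = 0.15
_KIDNEY = 0.55
_TUMOR_DARK = 0.32
_TUMOR_BRIGHT = 0.85
_ARTIFACT_VALUES = (-2.0, 3.0)


@dataclass(frozen=True)
class PhantomConfig:
    """Study conditions of the synthetic dataset."""

    image_size: int = 96
    n_slices: int = 16
    kidney_count_range: tuple[int, int] = (1, 2)
    tumor_probability: float = 0.6
    tumor_area_range: tuple[int, int] = (30, 150)
    noise_sd: float = 0.04
    artifact_rate: float = 0.002
    seed: int = 0

    def __post_init__(self):
        if self.image_size < 32:
            raise ConfigurationError("image_size must be >= 32")
        if self.n_slices < 1:
            raise ConfigurationError("n_slices must be >= 1")
        lo, hi = self.kidney_count_range
        if not (1 <= lo <= hi <= 2):
            raise ConfigurationError("kidney_count_range must lie within (1..2)")
        amin, amax = self.tumor_area_range
        if not (0 < amin <= amax):
            raise ConfigurationError("tumor_area_range must satisfy 0 < min <= max")
        if not (0.0 <= self.tumor_probability <= 1.0):
            raise ConfigurationError("tumor_probability must be in [0, 1]")
        if self.noise_sd < 0:
            raise ConfigurationError("noise_sd must be >= 0")
        if not (0.0 <= self.artifact_rate <= 1.0):
            raise ConfigurationError("artifact_rate must be in [0, 1]")


def _draw_tumor(label, kidney_mask, center, rng, amin, amax, r_cap):
    """Place a disk of amin..amax pixels fully inside the kidney; returns mask."""
    shape = label.shape
    a_target = rng.uniform(amin, amax)
    r = min(math.sqrt(a_target / math.pi), r_cap)
    for _ in range(200):
        rr, cc = disk(center, r, shape=shape)
        inside = kidney_mask[rr, cc]
        count = int(inside.sum())
        if count < amin:
            r += 0.25
        elif count > amax:
            r -= 0.25
            if r <= 0.5:
                return None
        else:
            keep = inside
            return rr[keep], cc[keep]
    return None


def _draw_slice(cfg: PhantomConfig, rng: np.random.Generator):
    n = cfg.image_size
    img = np.full((n, n), _BACKGROUND, dtype=np.float64)
    lab = np.zeros((n, n), dtype=np.int64)

    amin, amax = cfg.tumor_area_range
    r_tumor_max = math.sqrt(amax / math.pi)
    minor_min = r_tumor_max / 0.7 + 1.0
    k_lo, k_hi = cfg.kidney_count_range
    n_kidneys = int(rng.integers(k_lo, k_hi + 1))

    # geometry: minor axis sized so the largest requested tumor fits inside
    minor = rng.uniform(minor_min, minor_min * 1.15, size=2)
    major = minor * rng.uniform(1.1, 1.35, size=2)
    margin = major + 2.0

    # bilateral layout; fall back to a single centered kidney when the
    # canvas is too small for two
    half = n / 2.0
    if n_kidneys == 2 and (half - major.max() - 1.0) <= margin.max():
        n_kidneys = 1
    if margin.max() >= n - margin.max():
        raise ConfigurationError(
            "image_size too small for the requested tumor_area_range"
        )

    tumor_bearing = rng.random() < cfg.tumor_probability
    tumor_kidney = int(rng.integers(0, n_kidneys))

    for k in range(n_kidneys):
        if n_kidneys == 2:
            c_lo, c_hi = (margin[k], half - major[k] - 1.0) if k == 0 else (
                half + major[k] + 1.0, n - margin[k])
            col = rng.uniform(c_lo, c_hi)
        else:
            col = rng.uniform(margin[k], n - margin[k])
        row = rng.uniform(margin[k], n - margin[k])
        theta = rng.uniform(0.0, math.pi)
        rr, cc = ellipse(row, col, major[k], minor[k], shape=(n, n),
                         rotation=theta)
        kidney_mask = np.zeros((n, n), dtype=bool)
        kidney_mask[rr, cc] = True
        lab[kidney_mask] = 1
        img[kidney_mask] = _KIDNEY + rng.uniform(-0.05, 0.05)

        if tumor_bearing and k == tumor_kidney:
            # offset the tumor center along the major axis, leaving room
            r_cap = 0.72 * minor[k]
            max_off = max(0.0, 0.6 * major[k] - r_cap)
            off = rng.uniform(-max_off, max_off)
            t_center = (row + off * math.sin(theta), col + off * math.cos(theta))
            hit = _draw_tumor(lab, kidney_mask, t_center, rng, amin, amax, r_cap)
            if hit is None:  # retry dead-center, guaranteed room by r_cap
                hit = _draw_tumor(lab, kidney_mask, (row, col), rng, amin,
                                  amax, r_cap)
            if hit is not None:
                trr, tcc = hit
                lab[trr, tcc] = 2
                bright = bool(rng.random() < 0.5)
                img[trr, tcc] = _TUMOR_BRIGHT if bright else _TUMOR_DARK

    if cfg.noise_sd > 0:
        img += rng.normal(0.0, cfg.noise_sd, size=(n, n))
    if cfg.artifact_rate > 0:
        mask = rng.random((n, n)) < cfg.artifact_rate
        vals = rng.choice(_ARTIFACT_VALUES, size=int(mask.sum()))
        img[mask] = vals
    return img, lab


def generate_phantom_volume(cfg: PhantomConfig):
    """Generate an (n_slices, size, size) image volume and its label volume."""
    rng = np.random.default_rng(cfg.seed)
    imgs, labs = [], []
    for _ in range(cfg.n_slices):
        img, lab = _draw_slice(cfg, rng)
        imgs.append(img)
        labs.append(lab)
    return np.stack(imgs), np.stack(labs)


def generate_slice_dataset(n: int, cfg: PhantomConfig) -> list[SliceSample]:
    """Generate ``n`` labeled 2D samples, each containing at least one kidney."""
    if n < 1:
        raise ConfigurationError("n must be >= 1")
    rng = np.random.default_rng(cfg.seed)
    samples = []
    for i in range(n):
        img, lab = _draw_slice(cfg, rng)
        samples.append(
            SliceSample(image=img, label=lab, case_id="synthetic", slice_index=i)
        )
    return samples


def write_case_dir(case_dir, image_volume, label_volume) -> Path:
    """Write a KiTS19-style case directory (imaging + segmentation NIfTI)."""
    import nibabel as nib

    case_dir = Path(case_dir)
    case_dir.mkdir(parents=True, exist_ok=True)
    affine = np.eye(4)
    nib.save(nib.Nifti1Image(np.asarray(image_volume, dtype=np.float32), affine),
             str(case_dir / "imaging.nii.gz"))
    nib.save(nib.Nifti1Image(np.asarray(label_volume, dtype=np.uint8), affine),
             str(case_dir / "segmentation.nii.gz"))
    return case_dir


def write_slice_png(path, image) -> Path:
    """Export one slice as an 8-bit PNG (min-max scaled)."""
    import imageio.v3 as iio

    a = np.asarray(image, dtype=np.float64)
    rng_ = a.max() - a.min()
    scaled = np.zeros_like(a) if rng_ == 0 else (a - a.min()) / rng_ * 255.0
    path = Path(path)
    iio.imwrite(path, np.clip(np.rint(scaled), 0, 255).astype(np.uint8))
    return path
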