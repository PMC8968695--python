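"""KiTS19-style data preparation.

3D volumes are cut into axial 2D slices; slices whose label map carries no
kidney marker are discarded.  Intensities are clipped to the [0.5, 99.5]
percentile range of the pooled training intensities (removing artifact
voxels such as metal streaks), then z-scored with the mean and standard
deviation of the *foreground* (label > 0) pixels.  The statistics are fit
once on the training pool and frozen for later application, so training and
test data receive the identical rule.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .errors import DegenerateInputError, RenalsegError

__all__ = ["SliceSample", "PreprocessStats", "slice_volume", "fit_stats",
           "apply_preprocess"]

_VALID_LABELS = frozenset({0, 1, 2})


@dataclass
class SliceSample:
    """One 2D gray image with its 3-class label mask (0 bg, 1 kidney, 2 tumor)."""

    image: np.ndarray
    label: np.ndarray
    case_id: str = ""
    slice_index: int = 0

    def __post_init__(self):
        self.image = np.asarray(self.image)
        self.label = np.asarray(self.label)
        if self.image.ndim != 2 or self.image.shape != self.label.shape:
            raise RenalsegError(
                f"image {self.image.shape} and label {self.label.shape} must be "
                "equal 2D shapes"
            )
        labels = set(np.unique(self.label).tolist())
        if not labels <= _VALID_LABELS:
            raise RenalsegError(f"label values {labels - _VALID_LABELS} outside {{0,1,2}}")


@dataclass(frozen=True)
class PreprocessStats:
    """Frozen clipping bounds and foreground z-scoring statistics."""

    clip_lo: float
    clip_hi: float
    fg_mean: float
    fg_sd: float

    def __post_init__(self):
        if self.clip_lo > self.clip_hi:
            raise RenalsegError("clip_lo must not exceed clip_hi")
        if self.fg_sd <= 0:
            raise DegenerateInputError("foreground standard deviation must be > 0")

    def to_dict(self) -> dict:
        return {
            "clip_lo": float(self.clip_lo),
            "clip_hi": float(self.clip_hi),
            "fg_mean": float(self.fg_mean),
            "fg_sd": float(self.fg_sd),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PreprocessStats":
        return cls(d["clip_lo"], d["clip_hi"], d["fg_mean"], d["fg_sd"])


def slice_volume(
    image_volume: np.ndarray, label_volume: np.ndarray, case_id: str = ""
) -> list[SliceSample]:
    """Cut (n_slices, rows, cols) volumes into labeled 2D samples.

    Slices with an all-zero label map are discarded; the surviving samples
    keep their original axial ``slice_index`` in slice order.
    """
    image_volume = np.asarray(image_volume)
    label_volume = np.asarray(label_volume)
    if image_volume.shape != label_volume.shape or image_volume.ndim != 3:
        raise RenalsegError(
            f"volumes must share a 3D shape, got {image_volume.shape} vs "
            f"{label_volume.shape}"
        )
    samples = []
    for k in range(image_volume.shape[0]):
        if np.any(label_volume[k] != 0):
            samples.append(
                SliceSample(
                    image=image_volume[k].copy(),
                    label=label_volume[k].astype(np.int64),
                    case_id=case_id,
                    slice_index=k,
                )
            )
    return samples


def fit_stats(
    samples: list[SliceSample], lo: float = 0.5, hi: float = 99.5
) -> PreprocessStats:
    """Fit clipping percentiles and foreground statistics on a sample pool.

    Clip bounds are the ``lo``/``hi`` percentiles (linear interpolation
    between order statistics) of all intensities pooled over the samples;
    the foreground mean/sd are computed over label>0 pixels *after* clipping.
    """
    if not samples:
        raise RenalsegError("cannot fit statistics on an empty sample list")
    pooled = np.concatenate([s.image.ravel() for s in samples]).astype(np.float64)
    clip_lo, clip_hi = np.percentile(pooled, [lo, hi], method="linear")
    fg = np.concatenate(
        [s.image[s.label > 0].ravel() for s in samples]
    ).astype(np.float64)
    if fg.size == 0:
        raise DegenerateInputError("no foreground pixels in the sample pool")
    fg = np.clip(fg, clip_lo, clip_hi)
    fg_mean = float(fg.mean())
    fg_sd = float(fg.std())
    if fg_sd == 0.0:
        raise DegenerateInputError("constant foreground: zero variance")
    return PreprocessStats(float(clip_lo), float(clip_hi), fg_mean, fg_sd)


def apply_preprocess(sample: SliceSample, stats: PreprocessStats) -> SliceSample:
    """Clamp to [clip_lo, clip_hi] then z-score with the foreground statistics."""
    img = np.clip(sample.image.astype(np.float64), stats.clip_lo, stats.clip_hi)
    img = (img - stats.fg_mean) / stats.fg_sd
    return replace(sample, image=img, label=sample.label.copy())
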