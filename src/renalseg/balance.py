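"""Tumor-size statistics and augmentation-based dataset balancing.

Tumor areas (8-connected components of label==2) are pooled over the
fine-stage training crops into a fixed-width histogram.  Bins that are
under-represented relative to the fullest bin are topped up with augmented
copies of their own samples — flips, right-angle rotations, integer shifts
and diagonal mirroring — until every non-empty bin reaches the maximum bin
count.  Originals are always retained; the procedure is deterministic given
its seed.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import ndimage

from .errors import RenalsegError
from .preprocess import SliceSample

__all__ = ["TumorSizeHistogram", "AugmentationOp", "tumor_areas",
           "build_histogram", "apply_augmentation", "balance_dataset",
           "AUGMENTATION_KINDS"]

_EIGHT = np.ones((3, 3), dtype=int)

AUGMENTATION_KINDS = ("horizontal_flip", "vertical_flip", "rotate90k",
                      "shift", "mirror")


@dataclass(frozen=True)
class TumorSizeHistogram:
    """Fixed-width area histogram; the final bin absorbs >= max_area."""

    bin_edges: np.ndarray
    counts: np.ndarray

    def __post_init__(self):
        if len(self.counts) != len(self.bin_edges) - 1:
            raise RenalsegError("counts/bin_edges length mismatch")
        if np.any(np.asarray(self.counts) < 0):
            raise RenalsegError("counts must be non-negative")

    def bin_of(self, area: float) -> int:
        """Right-open bin index; areas beyond the last edge go to the last bin."""
        idx = int(np.searchsorted(self.bin_edges, area, side="right") - 1)
        return min(max(idx, 0), len(self.counts) - 1)

    def to_frame(self):
        """(bin_lo, bin_hi, count) table, e.g. for CSV export."""
        import pandas as pd

        return pd.DataFrame({
            "bin_lo": self.bin_edges[:-1],
            "bin_hi": self.bin_edges[1:],
            "count": self.counts,
        })


@dataclass(frozen=True)
class AugmentationOp:
    """One spatial augmentation applied jointly to image and label."""

    kind: str
    k: int = 1            # rotate90k quarter turns (1..3)
    dx: int = 0           # shift, columns
    dy: int = 0           # shift, rows

    def __post_init__(self):
        if self.kind not in AUGMENTATION_KINDS:
            raise RenalsegError(f"unknown augmentation kind {self.kind!r}")
        if self.kind == "rotate90k" and self.k not in (1, 2, 3):
            raise RenalsegError("rotate90k requires k in 1..3")


def tumor_areas(samples: list[SliceSample]) -> list[int]:
    """Pixel areas of every 8-connected tumor component, pooled over samples."""
    areas: list[int] = []
    for s in samples:
        labeled, n = ndimage.label(s.label == 2, structure=_EIGHT)
        if n:
            areas.extend(
                int(a) for a in ndimage.sum_labels(
                    np.ones_like(labeled), labeled, index=range(1, n + 1))
            )
    return areas


def build_histogram(areas, bin_width: int = 500,
                    max_area: int | None = None) -> TumorSizeHistogram:
    """Right-open fixed-width binning of component areas."""
    if bin_width <= 0:
        raise RenalsegError("bin_width must be positive")
    areas = np.asarray(list(areas), dtype=np.float64)
    if np.any(areas < 0):
        raise RenalsegError("areas must be non-negative")
    if max_area is None:
        top = float(areas.max()) if areas.size else bin_width
        max_area = int(np.ceil(max(top, bin_width) / bin_width) * bin_width)
    edges = np.arange(0, max_area + bin_width, bin_width, dtype=np.float64)
    counts, _ = np.histogram(np.minimum(areas, max_area - 0.5) if areas.size
                             else areas, bins=edges)
    return TumorSizeHistogram(bin_edges=edges, counts=counts)


def _shift(arr: np.ndarray, dy: int, dx: int, fill):
    out = np.full_like(arr, fill)
    h, w = arr.shape
    ys = slice(max(dy, 0), min(h + dy, h))
    xs = slice(max(dx, 0), min(w + dx, w))
    ys_src = slice(max(-dy, 0), min(h - dy, h))
    xs_src = slice(max(-dx, 0), min(w - dx, w))
    out[ys, xs] = arr[ys_src, xs_src]
    return out


def apply_augmentation(sample: SliceSample, op: AugmentationOp) -> SliceSample:
    """Transform image and label with the same spatial map.

    Shifts pad the image with its clip-floor (minimum) intensity and the
    label with background.
    """
    img, lab = sample.image, sample.label
    if op.kind == "horizontal_flip":
        img, lab = img[:, ::-1], lab[:, ::-1]
    elif op.kind == "vertical_flip":
        img, lab = img[::-1, :], lab[::-1, :]
    elif op.kind == "rotate90k":
        img, lab = np.rot90(img, op.k), np.rot90(lab, op.k)
    elif op.kind == "mirror":  # flip about the main diagonal
        img, lab = img.T, lab.T
    elif op.kind == "shift":
        if abs(op.dx) >= img.shape[1] or abs(op.dy) >= img.shape[0]:
            raise RenalsegError("shift magnitude must be smaller than the patch")
        img = _shift(img, op.dy, op.dx, fill=float(img.min()))
        lab = _shift(lab, op.dy, op.dx, fill=0)
    return replace(sample, image=np.ascontiguousarray(img),
                   label=np.ascontiguousarray(lab))


def _random_op(rng: np.random.Generator, max_shift: int) -> AugmentationOp:
    kind = AUGMENTATION_KINDS[rng.integers(len(AUGMENTATION_KINDS))]
    if kind == "rotate90k":
        return AugmentationOp(kind, k=int(rng.integers(1, 4)))
    if kind == "shift":
        dy, dx = rng.integers(-max_shift, max_shift + 1, size=2)
        return AugmentationOp(kind, dy=int(dy), dx=int(dx))
    return AugmentationOp(kind)


def balance_dataset(samples: list[SliceSample], hist: TumorSizeHistogram,
                    rng_seed: int = 0) -> list[SliceSample]:
    """Top up under-represented tumor-size bins with augmented copies.

    Each tumor-bearing sample is binned by its total tumor pixel count.
    Augmented copies (ops drawn uniformly with the seeded generator) are
    appended until every non-empty bin reaches the maximum bin occupancy;
    shifts that clip tumor pixels off the patch are rejected and resampled.
    Originals appear exactly once, in their input order.
    """
    rng = np.random.default_rng(rng_seed)
    bins: dict[int, list[SliceSample]] = {}
    for s in samples:
        area = int(np.sum(s.label == 2))
        if area > 0:
            bins.setdefault(hist.bin_of(area), []).append(s)
    out = list(samples)
    if not bins:
        return out
    target = max(len(v) for v in bins.values())
    for b in sorted(bins):
        members = bins[b]
        max_shift = max(members[0].image.shape[0] // 8, 1)
        need = target - len(members)
        for _ in range(need):
            src = members[int(rng.integers(len(members)))]
            area = int(np.sum(src.label == 2))
            for _attempt in range(100):
                op = _random_op(rng, max_shift)
                aug = apply_augmentation(src, op)
                if int(np.sum(aug.label == 2)) == area:
                    out.append(aug)
                    break
            else:
                raise RenalsegError("could not find an area-preserving op")
    return out
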