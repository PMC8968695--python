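"""Coarse-to-fine ROI plumbing.

The coarse stage produces a binary kidney(+tumor) mask on the full slice.
Each 8-connected component yields a tight bounding box which is expanded to
a square window: ``small_size``² (128² by default) when both tight sides fit
within ``small_size``, otherwise ``large_size``² (256²).  The window is
centered on the tight box and translated — never shrunk — to lie inside the
canvas.  Large-class crops are down-scaled to the small size before entering
the fine model (bilinear for images, nearest for labels) and fine
predictions are up-scaled back by nearest neighbor before being pasted onto
the full-size canvas.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.transform import resize

from .errors import RenalsegError

__all__ = ["ROIBox", "mask_to_rois", "expand_roi", "crop", "to_fine_input",
           "rescale_prediction", "paste_back", "run_cascade"]

_EIGHT = np.ones((3, 3), dtype=int)  # 8-connectivity structuring element


@dataclass(frozen=True)
class ROIBox:
    """Axis-aligned square crop window, half-open pixel bounds."""

    row0: int
    col0: int
    row1: int
    col1: int
    size_class: int

    def __post_init__(self):
        if (self.row1 - self.row0 != self.size_class
                or self.col1 - self.col0 != self.size_class):
            raise RenalsegError("ROIBox sides must equal size_class")
        if self.row0 < 0 or self.col0 < 0:
            raise RenalsegError("ROIBox out of canvas")

    def to_dict(self) -> dict:
        """JSON-serializable form (per-case/slice ROI manifests)."""
        return {"row0": self.row0, "col0": self.col0, "row1": self.row1,
                "col1": self.col1, "size_class": self.size_class}

    @classmethod
    def from_dict(cls, d: dict) -> "ROIBox":
        return cls(**d)


def mask_to_rois(binary_mask: np.ndarray) -> list[tuple[int, int, int, int]]:
    """Tight (row0, col0, row1, col1) boxes of the 8-connected components,
    ordered by component pixel count, largest first."""
    mask = np.asarray(binary_mask)
    if mask.ndim != 2:
        raise RenalsegError("mask must be 2D")
    labeled, n = ndimage.label(mask != 0, structure=_EIGHT)
    if n == 0:
        return []
    slices = ndimage.find_objects(labeled)
    sizes = ndimage.sum_labels(np.ones_like(labeled), labeled,
                               index=range(1, n + 1))
    order = np.argsort(-sizes, kind="stable")
    return [
        (slices[i][0].start, slices[i][1].start,
         slices[i][0].stop, slices[i][1].stop)
        for i in order
    ]


def expand_roi(tight_box: tuple[int, int, int, int], canvas_size: int,
               small_size: int = 128, large_size: int = 256) -> ROIBox:
    """Expand a tight box to a square window of the small or large class.

    Both tight sides <= small_size selects the small class; anything larger
    selects the large class (there is no third case: oversize components are
    still assigned the large class and handled by the rescale step).  The
    window is centered on the tight box then translated to fit the canvas.
    """
    r0, c0, r1, c1 = tight_box
    if not (0 <= r0 < r1 <= canvas_size and 0 <= c0 < c1 <= canvas_size):
        raise RenalsegError(f"tight box {tight_box} outside canvas")
    size = small_size if (r1 - r0 <= small_size and c1 - c0 <= small_size) \
        else large_size
    if size > canvas_size:
        raise RenalsegError(
            f"window size {size} exceeds canvas {canvas_size}")

    def place(lo, hi):
        start = (lo + hi) // 2 - size // 2
        return int(np.clip(start, 0, canvas_size - size))

    rs, cs = place(r0, r1), place(c0, c1)
    return ROIBox(rs, cs, rs + size, cs + size, size)


def crop(array: np.ndarray, box: ROIBox) -> np.ndarray:
    """Exact sub-array copy of the window."""
    a = np.asarray(array)
    if box.row1 > a.shape[0] or box.col1 > a.shape[1]:
        raise RenalsegError("box exceeds array bounds")
    return a[box.row0:box.row1, box.col0:box.col1].copy()


def to_fine_input(patch: np.ndarray, size_class: int, small_size: int = 128,
                  is_label: bool = False) -> np.ndarray:
    """Bring a crop to the fine model's input side (= small_size).

    Small-class patches pass through; large-class patches (an integer
    multiple of small_size) are down-scaled — bilinear for images, nearest
    (top-left sample) for labels.
    """
    patch = np.asarray(patch)
    if patch.shape != (size_class, size_class):
        raise RenalsegError(
            f"patch shape {patch.shape} does not match size_class {size_class}")
    if size_class == small_size:
        return patch.copy()
    if size_class % small_size != 0:
        raise RenalsegError(
            f"size_class {size_class} is not a multiple of {small_size}")
    f = size_class // small_size
    if is_label:
        return patch[::f, ::f].copy()
    return resize(patch.astype(np.float64), (small_size, small_size),
                  order=1, anti_aliasing=False, preserve_range=True)


def rescale_prediction(pred: np.ndarray, size_class: int,
                       small_size: int = 128) -> np.ndarray:
    """Nearest-neighbor up-scale of a fine prediction back to its window size."""
    pred = np.asarray(pred)
    if pred.shape != (small_size, small_size):
        raise RenalsegError("prediction side must equal the fine input side")
    if size_class == small_size:
        return pred.copy()
    f = size_class // small_size
    return np.repeat(np.repeat(pred, f, axis=0), f, axis=1)


def paste_back(canvas: np.ndarray, patch: np.ndarray, box: ROIBox) -> np.ndarray:
    """Replace the canvas pixels inside the box with the patch predictions."""
    if patch.shape != (box.size_class, box.size_class):
        raise RenalsegError(
            f"patch shape {patch.shape} does not match box size "
            f"{box.size_class}")
    out = np.asarray(canvas).copy()
    out[box.row0:box.row1, box.col0:box.col1] = patch
    return out


def run_cascade(coarse_model, fine_model, slice_image: np.ndarray, *,
                small_size: int = 128, large_size: int = 256,
                enhance_fn=None) -> np.ndarray:
    """Full coarse -> ROI -> fine -> paste-back segmentation of one slice.

    ``coarse_model`` and ``fine_model`` are callables mapping an
    (N, 1, H, W) batch to (N, n_classes, H, W) scores (any object with a
    ``predict`` method is accepted too).  ``enhance_fn``, when given, is
    applied to each fine input patch (the fuzzy enhancement slot).
    Returns the full-size 3-class label map; no detected ROI means an
    all-background result.
    """
    img = np.asarray(slice_image, dtype=np.float64)
    h, w = img.shape
    if h != w:
        raise RenalsegError("cascade expects square slices")
    coarse_fn = getattr(coarse_model, "predict", coarse_model)
    fine_fn = getattr(fine_model, "predict", fine_model)

    coarse_scores = coarse_fn(img[None, None].astype(np.float32))
    mask = np.argmax(coarse_scores[0], axis=0) == 1
    out = np.zeros((h, w), dtype=np.int64)
    for tight in mask_to_rois(mask):  # component size descending
        box = expand_roi(tight, h, small_size, large_size)
        patch = crop(img, box)
        x = to_fine_input(patch, box.size_class, small_size)
        if enhance_fn is not None:
            x = enhance_fn(x)
        fine_scores = fine_fn(x[None, None].astype(np.float32))
        pred = np.argmax(fine_scores[0], axis=0)
        out = paste_back(out, rescale_prediction(pred, box.size_class,
                                                 small_size), box)
    return out
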