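"""Segmentation losses: soft Dice, pixel-wise cross-entropy, and their sum."""

from __future__ import annotations

import numpy as np

from .autodiff import Tensor, log_softmax, softmax

__all__ = ["one_hot", "cross_entropy_loss", "soft_dice_loss", "combined_loss",
           "make_loss"]


def one_hot(labels: np.ndarray, n_classes: int) -> np.ndarray:
    """(N, H, W) integer labels -> (N, C, H, W) float32 one-hot."""
    n, h, w = labels.shape
    out = np.zeros((n, n_classes, h, w), dtype=np.float32)
    for c in range(n_classes):
        out[:, c] = labels == c
    return out


def cross_entropy_loss(logits: Tensor, target_onehot: np.ndarray) -> Tensor:
    logp = log_softmax(logits, axis=1)
    return -(logp * Tensor(target_onehot)).sum() * (
        1.0 / (logits.shape[0] * logits.shape[2] * logits.shape[3]))


def soft_dice_loss(logits: Tensor, target_onehot: np.ndarray,
                   smooth: float = 1.0) -> Tensor:
    """1 - mean over classes of the smoothed soft Dice coefficient."""
    probs = softmax(logits, axis=1)
    t = Tensor(target_onehot)
    inter = (probs * t).sum(axis=(0, 2, 3))
    sizes = probs.sum(axis=(0, 2, 3)) + t.sum(axis=(0, 2, 3))
    dice = (2.0 * inter + smooth) / (sizes + smooth)
    return 1.0 - dice.mean()


def combined_loss(logits: Tensor, target_onehot: np.ndarray) -> Tensor:
    return soft_dice_loss(logits, target_onehot) \
        + cross_entropy_loss(logits, target_onehot)


def make_loss(name: str):
    table = {
        "soft_dice": soft_dice_loss,
        "cross_entropy": cross_entropy_loss,
        "sum_of_both": combined_loss,
    }
    if name not in table:
        raise ValueError(f"unknown loss {name!r}; choose from {sorted(table)}")
    return table[name]
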