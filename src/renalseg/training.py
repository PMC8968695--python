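"""Training of the coarse and fine models.

Both stages use Adam (learning rate 0.001, batch size 8 by default) on
seeded shuffled batches.  The coarse model sees full slices with the binary
kidney-union-tumor label; the fine model sees small square crops (the fine
input side) extracted around ground-truth kidney components, rebalanced by
tumor size and passed through the fuzzy enhancement.

The default step counts (steps_per_epoch 500, epochs 100) describe the
full-scale regime; the :func:`desk_profile` returns a configuration that
trains the whole cascade on synthetic phantoms on a single CPU in minutes
(96-pixel slices, depth 3, 8 base filters, <= 5 epochs).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from . import balance as bal
from . import fuzzy, roi
from .errors import ConfigurationError, DivergenceError, RenalsegError
from .nn import Adam, FR2PAttUNet, NetworkConfig, R2PBlockConfig, Tensor
from .nn.losses import make_loss, one_hot
from .phantoms import PhantomConfig
from .preprocess import PreprocessStats, SliceSample, apply_preprocess, fit_stats

__all__ = ["TrainConfig", "CascadeConfig", "CascadeModel", "train_model",
           "build_fine_dataset", "train_cascade", "desk_profile",
           "enhance_for_net"]


@dataclass(frozen=True)
class TrainConfig:
    learning_rate: float = 0.001
    batch_size: int = 8
    steps_per_epoch: int = 500
    epochs: int = 100
    loss: str = "sum_of_both"
    seed: int = 0

    def __post_init__(self):
        if self.learning_rate <= 0:
            raise ConfigurationError("learning_rate must be > 0")
        if min(self.batch_size, self.steps_per_epoch, self.epochs) < 1:
            raise ConfigurationError("counts must be positive")
        make_loss(self.loss)  # validates the name


@dataclass(frozen=True)
class CascadeConfig:
    """Everything needed to train and run the two-stage segmenter."""

    coarse_net: NetworkConfig
    fine_net: NetworkConfig
    coarse_train: TrainConfig
    fine_train: TrainConfig
    roi_small: int = 128
    roi_large: int = 256
    balance_bin_width: int = 500
    use_enhancement: bool = True

    def __post_init__(self):
        if self.roi_large != 2 * self.roi_small:
            raise ConfigurationError("roi_large must equal 2 * roi_small")
        if self.fine_net.input_size != self.roi_small:
            raise ConfigurationError(
                "fine input size must equal the small ROI class")
        if self.coarse_net.n_classes != 2 or self.fine_net.n_classes != 3:
            raise ConfigurationError(
                "coarse model must have 2 classes, fine model 3")


def enhance_for_net(patch: np.ndarray, anchor: float = 0.43,
                    spread: float = 8.0) -> np.ndarray:
    """Fuzzy-enhance a preprocessed (foreground-z-scored) crop for the network.

    The piecewise transform is defined on a normalized gray axis; crops
    arriving here are in foreground z-units (mean 0, sd 1 over kidney+tumor
    pixels), so the gray level is anchored by placing the foreground mean at
    the "gray" breakpoint b2 = 0.43 and mapping ``spread`` z-units to the
    full axis — the analogue of a fixed CT display window.  A per-crop
    min-max normalization would instead let single extreme noise pixels
    shift every tissue's gray level from crop to crop.  Output is rescaled
    to [0, 1].
    """
    m = np.clip(anchor + np.asarray(patch, dtype=np.float64) / spread, 0.0, 1.0)
    return np.asarray(fuzzy.enhance_pixel(m), dtype=np.float64) / 255.0


def _batches(n: int, batch_size: int, steps: int, rng: np.random.Generator):
    """Seeded shuffled index batches, cycling through the dataset."""
    order = rng.permutation(n)
    pos = 0
    for _ in range(steps):
        if pos + batch_size > n:
            order = rng.permutation(n)
            pos = 0
        yield order[pos:pos + batch_size]
        pos += batch_size


def train_model(model: FR2PAttUNet, dataset: list[tuple[np.ndarray, np.ndarray]],
                cfg: TrainConfig, log_every: int = 0) -> list[float]:
    """Run ``epochs * steps_per_epoch`` Adam steps; returns per-step losses."""
    if not dataset:
        raise RenalsegError("dataset is empty")
    n_classes = model.cfg.n_classes
    side = model.cfg.input_size
    images = np.stack([np.asarray(img, dtype=np.float32) for img, _ in dataset])
    labels = np.stack([np.asarray(lab, dtype=np.int64) for _, lab in dataset])
    if images.shape[1:] != (side, side):
        raise RenalsegError(
            f"dataset patches {images.shape[1:]} do not match model input "
            f"{side}x{side}")
    loss_fn = make_loss(cfg.loss)
    opt = Adam(model.parameters(), lr=cfg.learning_rate)
    rng = np.random.default_rng(cfg.seed)
    model.train()
    history: list[float] = []
    total = cfg.epochs * cfg.steps_per_epoch
    bs = min(cfg.batch_size, len(dataset))
    for step, idx in enumerate(_batches(len(dataset), bs, total, rng)):
        x = Tensor(images[idx][:, None])
        t = one_hot(labels[idx], n_classes)
        loss = loss_fn(model(x), t)
        value = float(loss.data)
        if not np.isfinite(value):
            raise DivergenceError(f"non-finite loss at step {step}",
                                  history=history)
        opt.zero_grad()
        loss.backward()
        opt.step()
        history.append(value)
        if log_every and (step + 1) % log_every == 0:
            print(f"step {step + 1}/{total}  loss {value:.4f}")
    return history


def build_fine_dataset(samples: list[SliceSample], cascade_cfg: CascadeConfig,
                       seed: int = 0) -> list[SliceSample]:
    """Crop ground-truth ROIs, balance by tumor size, apply enhancement.

    Training-time ROIs derive from the ground-truth masks (not coarse
    predictions) so the two stages can be trained independently and
    reproducibly.
    """
    small, large = cascade_cfg.roi_small, cascade_cfg.roi_large
    crops: list[SliceSample] = []
    for s in samples:
        for tight in roi.mask_to_rois(s.label > 0):
            box = roi.expand_roi(tight, s.image.shape[0], small, large)
            img = roi.to_fine_input(roi.crop(s.image, box), box.size_class, small)
            lab = roi.to_fine_input(roi.crop(s.label, box), box.size_class,
                                    small, is_label=True)
            crops.append(SliceSample(image=img, label=lab.astype(np.int64),
                                     case_id=s.case_id,
                                     slice_index=s.slice_index))
    hist = bal.build_histogram(bal.tumor_areas(crops),
                               bin_width=cascade_cfg.balance_bin_width)
    balanced = bal.balance_dataset(crops, hist, rng_seed=seed)
    if cascade_cfg.use_enhancement:
        balanced = [replace(s, image=enhance_for_net(s.image))
                    for s in balanced]
    return balanced


@dataclass
class CascadeModel:
    """Trained two-stage segmenter plus its frozen preprocessing statistics."""

    coarse: FR2PAttUNet
    fine: FR2PAttUNet
    stats: PreprocessStats
    cfg: CascadeConfig

    def segment(self, raw_slice: np.ndarray) -> np.ndarray:
        """Raw slice -> full-size 3-class label map."""
        sample = SliceSample(image=np.asarray(raw_slice, dtype=np.float64),
                             label=np.zeros_like(raw_slice, dtype=np.int64))
        pre = apply_preprocess(sample, self.stats)
        enhance = enhance_for_net if self.cfg.use_enhancement else None
        return roi.run_cascade(self.coarse, self.fine, pre.image,
                               small_size=self.cfg.roi_small,
                               large_size=self.cfg.roi_large,
                               enhance_fn=enhance)


def train_cascade(samples: list[SliceSample], cascade_cfg: CascadeConfig,
                  seed: int = 0, log_every: int = 0) -> CascadeModel:
    """Fit preprocessing stats, then train the coarse and fine models.

    The coarse stage trains on full preprocessed slices with binary
    (kidney ∪ tumor) labels; the fine stage on balanced, enhanced 3-class
    ROI crops.
    """
    if not samples:
        raise RenalsegError("no training samples")
    stats = fit_stats(samples)
    pre = [apply_preprocess(s, stats) for s in samples]

    coarse_ds = [(s.image, (s.label > 0).astype(np.int64)) for s in pre]
    coarse = FR2PAttUNet(cascade_cfg.coarse_net, seed=seed)
    train_model(coarse, coarse_ds, cascade_cfg.coarse_train,
                log_every=log_every)

    fine_samples = build_fine_dataset(pre, cascade_cfg, seed=seed + 1)
    fine_ds = [(s.image, s.label) for s in fine_samples]
    fine = FR2PAttUNet(cascade_cfg.fine_net, seed=seed + 2)
    train_model(fine, fine_ds, cascade_cfg.fine_train, log_every=log_every)

    return CascadeModel(coarse=coarse, fine=fine, stats=stats, cfg=cascade_cfg)


def desk_profile(seed: int = 0) -> tuple[PhantomConfig, CascadeConfig]:
    """Single-CPU study conditions: 96-pixel phantoms, depth-3 models.

    Kernel sizes, recurrence and filter counts are scaled to finish the full
    cascade training in minutes while keeping every architectural element
    (R2P blocks, attention gates, enhancement, balancing) on its real code
    path.
    """
    phantom = PhantomConfig(image_size=96, seed=seed)
    block = R2PBlockConfig(kernel_sizes=(3,), recurrence_steps=1,
                           dropout_rate=0.1)
    coarse_net = NetworkConfig(input_size=96, depth=3, base_filters=8,
                               n_classes=2, block=block)
    fine_net = NetworkConfig(input_size=48, depth=3, base_filters=8,
                             n_classes=3, block=block)
    coarse_train = TrainConfig(steps_per_epoch=40, epochs=4, seed=seed)
    fine_train = TrainConfig(steps_per_epoch=80, epochs=5, seed=seed + 1)
    cascade = CascadeConfig(coarse_net=coarse_net, fine_net=fine_net,
                            coarse_train=coarse_train, fine_train=fine_train,
                            roi_small=48, roi_large=96, balance_bin_width=25)
    return phantom, cascade
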