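"""Tumor-area statistics, augmentations, and histogram balancing."""

import numpy as np
import pytest

from renalseg.balance import (AugmentationOp, apply_augmentation,
                              balance_dataset, build_histogram, tumor_areas)
from renalseg.errors import RenalsegError
from renalseg.preprocess import SliceSample

from test_phantoms import flood_fill_areas


def sample_with_tumors(blocks, side=64, seed=0):
    """blocks: list of (r, c, h, w) tumor rectangles inside one kidney."""
    rng = np.random.default_rng(seed)
    lab = np.zeros((side, side), dtype=int)
    lab[2:side - 2, 2:side - 2] = 1
    for r, c, h, w in blocks:
        lab[r:r + h, c:c + w] = 2
    return SliceSample(image=rng.normal(size=(side, side)), label=lab)


class TestTumorAreas:
    def test_single_square(self):
        s = sample_with_tumors([(10, 10, 7, 7)])
        assert tumor_areas([s]) == [49]

    def test_two_disjoint_components_match_flood_fill(self):
        s = sample_with_tumors([(5, 5, 10, 10), (30, 30, 10, 25)])
        got = sorted(tumor_areas([s]))
        oracle = sorted(flood_fill_areas(s.label == 2))
        assert got == oracle == [100, 250]

    def test_no_tumors(self):
        s = sample_with_tumors([])
        assert tumor_areas([s]) == []


class TestHistogram:
    def test_small_example(self):
        hist = build_histogram([100, 450, 600], bin_width=500, max_area=1000)
        assert list(hist.counts) == [2, 1]

    def test_conservation_against_counting_oracle(self, rng):
        areas = rng.integers(0, 3000, 1000)
        hist = build_histogram(areas, bin_width=500)
        assert hist.counts.sum() == 1000
        # brute-force counting loop
        for i, (lo, hi) in enumerate(zip(hist.bin_edges, hist.bin_edges[1:])):
            last = i == len(hist.counts) - 1
            expected = sum(1 for a in areas
                           if (lo <= a < hi) or (last and a >= hi))
            assert hist.counts[i] == expected

    def test_overflow_absorbed_by_last_bin(self):
        hist = build_histogram([10, 9999], bin_width=500, max_area=1000)
        assert hist.counts[-1] == 1

    def test_invalid_bin_width(self):
        with pytest.raises(RenalsegError):
            build_histogram([1], bin_width=0)


class TestAugmentation:
    def test_horizontal_flip_involution(self):
        s = sample_with_tumors([(10, 20, 5, 9)])
        op = AugmentationOp("horizontal_flip")
        twice = apply_augmentation(apply_augmentation(s, op), op)
        assert np.array_equal(twice.image, s.image)
        assert np.array_equal(twice.label, s.label)

    def test_rotate_period_four(self):
        s = sample_with_tumors([(10, 20, 5, 9)])
        op = AugmentationOp("rotate90k", k=1)
        out = s
        for _ in range(4):
            out = apply_augmentation(out, op)
        assert np.array_equal(out.image, s.image)
        assert np.array_equal(out.label, s.label)

    def test_mirror_is_transpose_and_involution(self):
        s = sample_with_tumors([(10, 20, 5, 9)])
        op = AugmentationOp("mirror")
        once = apply_augmentation(s, op)
        assert np.array_equal(once.label, s.label.T)
        assert np.array_equal(apply_augmentation(once, op).label, s.label)

    @pytest.mark.parametrize("op", [
        AugmentationOp("horizontal_flip"),
        AugmentationOp("vertical_flip"),
        AugmentationOp("rotate90k", k=2),
        AugmentationOp("mirror"),
    ])
    def test_tumor_area_invariant(self, op):
        s = sample_with_tumors([(10, 20, 5, 9), (40, 40, 6, 6)])
        before = int((s.label == 2).sum())
        after = int((apply_augmentation(s, op).label == 2).sum())
        assert before == after

    def test_shift_pads_with_background(self):
        s = sample_with_tumors([(10, 20, 5, 9)])
        out = apply_augmentation(s, AugmentationOp("shift", dy=3, dx=-2))
        assert np.all(out.label[:3, :] == 0)
        assert np.all(out.image[:3, :] == s.image.min())
        assert set(np.unique(out.label)) <= {0, 1, 2}

    def test_oversize_shift_rejected(self):
        s = sample_with_tumors([])
        with pytest.raises(RenalsegError):
            apply_augmentation(s, AugmentationOp("shift", dx=64))

    def test_unknown_kind_rejected(self):
        with pytest.raises(RenalsegError):
            AugmentationOp("elastic")


class TestBalance:
    def _skewed(self):
        # bin widths 50: bin0 areas < 50 (10 samples), bin1 areas 50..99 (20)
        small = [sample_with_tumors([(10, 10, 5, 5)], seed=i)
                 for i in range(10)]                     # area 25
        large = [sample_with_tumors([(10, 10, 8, 8)], seed=100 + i)
                 for i in range(20)]                     # area 64
        samples = small + large
        hist = build_histogram(tumor_areas(samples), bin_width=50)
        return samples, hist

    def test_bins_equalized_to_max(self):
        samples, hist = self._skewed()
        out = balance_dataset(samples, hist, rng_seed=3)
        assert len(out) == 40  # 10 added
        areas = [int((s.label == 2).sum()) for s in out]
        counts = {}
        for a in areas:
            counts[hist.bin_of(a)] = counts.get(hist.bin_of(a), 0) + 1
        assert set(counts.values()) == {20}

    def test_originals_retained_once_in_order(self):
        samples, hist = self._skewed()
        out = balance_dataset(samples, hist, rng_seed=3)
        for orig, kept in zip(samples, out):
            assert kept is orig

    def test_already_uniform_is_identity(self):
        samples = [sample_with_tumors([(10, 10, 5, 5)], seed=i)
                   for i in range(4)]
        hist = build_histogram(tumor_areas(samples), bin_width=50)
        out = balance_dataset(samples, hist, rng_seed=0)
        assert len(out) == len(samples)
        assert all(a is b for a, b in zip(out, samples))

    def test_seed_determinism(self):
        samples, hist = self._skewed()
        a = balance_dataset(samples, hist, rng_seed=9)
        b = balance_dataset(samples, hist, rng_seed=9)
        assert len(a) == len(b)
        for x, y in zip(a, b):
            assert np.array_equal(x.image, y.image)
            assert np.array_equal(x.label, y.label)

    def test_augmented_copies_keep_label_alphabet(self):
        samples, hist = self._skewed()
        out = balance_dataset(samples, hist, rng_seed=1)
        for s in out:
            assert set(np.unique(s.label)) <= {0, 1, 2}
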