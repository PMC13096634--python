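"""Synthetic dataset generator, preprocessing and augmentation operators."""

import itertools

import numpy as np
import pytest

from aohho.synth import (
    CLASS_NAMES,
    SynthesisParams,
    augment,
    decode_labels,
    encode_labels,
    generate_dataset,
    generate_train_test,
    normalize,
)


class TestGeneration:
    def test_counts_balance_and_range(self):
        ds = generate_dataset(SynthesisParams((10, 10, 10, 10), seed=0))
        assert len(ds) == 40
        np.testing.assert_array_equal(np.bincount(ds.labels), [10, 10, 10, 10])
        assert ds.images.min() >= 0.0 and ds.images.max() <= 1.0
        assert ds.images.shape == (40, 64, 64)

    def test_bit_identical_under_same_seed(self):
        p = SynthesisParams((5, 5, 5, 5), noise_sd=0.07, class_overlap=0.2, seed=9)
        a, b = generate_dataset(p), generate_dataset(p)
        np.testing.assert_array_equal(a.images, b.images)
        np.testing.assert_array_equal(a.labels, b.labels)

    def test_nearest_template_classifier_is_perfect_without_noise(self):
        """A cosine nearest-class-mean classifier separates a fresh noise-free
        draw perfectly at zero overlap."""
        ref = generate_dataset(SynthesisParams((50,) * 4, 0.0, 0.0, seed=1))
        means = np.stack([ref.images[ref.labels == c].mean(0) for c in range(4)])
        tm = means.reshape(4, -1)
        tm = tm - tm.mean(axis=1, keepdims=True)
        tm /= np.linalg.norm(tm, axis=1, keepdims=True)
        fresh = generate_dataset(SynthesisParams((50,) * 4, 0.0, 0.0, seed=2))
        X = fresh.images.reshape(len(fresh), -1)
        X = X - X.mean(axis=1, keepdims=True)
        pred = (X @ tm.T).argmax(axis=1)
        assert (pred == fresh.labels).mean() == 1.0

    def test_class_means_well_separated_relative_to_within_class_spread(self):
        ds = generate_dataset(SynthesisParams((50,) * 4, 0.0, 0.0, seed=1))
        means = np.stack([ds.images[ds.labels == c].mean(0) for c in range(4)])
        within = np.mean([
            np.linalg.norm(ds.images[ds.labels == c] - means[c], axis=(1, 2)).mean()
            for c in range(4)])
        between = min(np.linalg.norm(means[a] - means[b])
                      for a, b in itertools.combinations(range(4), 2))
        assert between > 5.0 * within

    def test_overlap_dial_reduces_separation(self):
        def min_between(overlap):
            ds = generate_dataset(SynthesisParams((30,) * 4, 0.0, overlap, seed=3))
            means = np.stack([ds.images[ds.labels == c].mean(0) for c in range(4)])
            return min(np.linalg.norm(means[a] - means[b])
                       for a, b in itertools.combinations(range(4), 2))
        assert min_between(0.8) < 0.5 * min_between(0.0)

    def test_train_test_draws_are_distinct(self):
        train, test = generate_train_test((5,) * 4, (3,) * 4, seed=0)
        assert len(train) == 20 and len(test) == 12
        assert train.split_tag == "train" and test.split_tag == "test"

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            SynthesisParams((0, 5, 5, 5))
        with pytest.raises(ValueError):
            SynthesisParams((5,) * 4, noise_sd=-0.1)
        with pytest.raises(ValueError):
            SynthesisParams((5,) * 4, class_overlap=1.5)


class TestNormalize:
    @pytest.mark.parametrize("value, expected", [(255, 1.0), (0, 0.0), (51, 0.2)])
    def test_exact_division_by_255(self, value, expected):
        assert normalize(np.array([[value]]))[0, 0] == pytest.approx(expected, abs=1e-12)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            normalize(np.array([[256]]))


class TestAugment:
    @pytest.fixture
    def image(self):
        rng = np.random.default_rng(0)
        return rng.random((32, 32))

    def test_forced_identity_returns_image_exactly(self, image):
        out = augment(image, np.random.default_rng(0), angle=0.0, flip=False,
                      zoom=1.0, shift=(0.0, 0.0))
        np.testing.assert_array_equal(out, image)

    def test_two_forced_flips_are_an_involution(self, image):
        once = augment(image, np.random.default_rng(0), angle=0.0, flip=True,
                       zoom=1.0, shift=(0.0, 0.0))
        twice = augment(once, np.random.default_rng(0), angle=0.0, flip=True,
                        zoom=1.0, shift=(0.0, 0.0))
        np.testing.assert_array_equal(twice, image)

    def test_flip_frequency_is_one_half(self):
        rng = np.random.default_rng(1)
        marker = np.zeros((8, 8))
        marker[:, 0] = 1.0  # asymmetric probe
        flips = 0
        for _ in range(10_000):
            out = augment(marker, rng, angle=0.0, zoom=1.0, shift=(0.0, 0.0))
            flips += out[0, -1] == 1.0
        assert abs(flips / 10_000 - 0.5) < 0.02

    def test_preserves_shape_and_range(self, image):
        rng = np.random.default_rng(2)
        for _ in range(20):
            out = augment(image, rng)
            assert out.shape == image.shape
            assert out.min() >= 0.0 and out.max() <= 1.0

    def test_forced_rotation_moves_probe_to_the_expected_angle(self):
        """A bright off-center probe rotated by a forced angle lands at that
        angle (by center of mass, within a pixel of discretization)."""
        img = np.zeros((65, 65))
        img[32, 62] = 1.0  # radius-30 probe at angle 0
        for angle in (-15.0, -7.5, 7.5, 15.0):
            out = augment(img, np.random.default_rng(0), angle=angle, flip=False,
                          zoom=1.0, shift=(0.0, 0.0))
            ys, xs = np.nonzero(out > 0.01)
            weights = out[ys, xs]
            cy = (ys * weights).sum() / weights.sum()
            cx = (xs * weights).sum() / weights.sum()
            measured = np.degrees(np.arctan2(32 - cy, cx - 32))
            assert measured == pytest.approx(angle, abs=2.0)


class TestLabels:
    def test_integer_encoding_is_alphabetical(self):
        codes = encode_labels(["glioma", "meningioma", "notumor", "pituitary"])
        np.testing.assert_array_equal(codes, [0, 1, 2, 3])

    def test_one_hot_rows(self):
        onehot = encode_labels(["notumor"], mode="one_hot")
        np.testing.assert_array_equal(onehot, [[0, 0, 1, 0]])

    def test_round_trip(self):
        names = ["pituitary", "glioma", "glioma", "meningioma"]
        assert decode_labels(encode_labels(names)) == names

    def test_unknown_name_rejected(self):
        with pytest.raises(ValueError):
            encode_labels(["astrocytoma"])
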