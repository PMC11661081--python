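"""Augmentation chain: branch statistics, invariants, determinism."""

import numpy as np
import pytest

from mrsynth import (
    AugmentConfig,
    augment,
    bias_field,
    downsample_cascade,
    nonuniform_noise,
    reorient_flip_translate,
    synth_neck,
    uniform_noise,
)
from mrsynth.augment import apply_skull_mode, compute_nonbrain_stats
from mrsynth.errors import ConfigurationError


@pytest.fixture()
def head():
    """Tiny head: brain labels 1-3, skull 4, zero background."""
    labels = np.zeros((12, 12, 12), dtype=int)
    labels[2:10, 2:10, 2:10] = 4
    labels[3:9, 3:9, 3:9] = 3
    labels[4:8, 4:8, 4:8] = 2
    labels[5:7, 5:7, 5:7] = 1
    image = np.where(labels > 0, labels * 0.2 + 0.1, 0.0)
    return image, labels


class TestSkullMode:
    def test_strip_zeroes_outside_brain(self, head, rng):
        image, labels = head
        strip_rng = np.random.default_rng(1)  # weights force strip
        img, lab, mode = apply_skull_mode(image, labels, strip_rng,
                                          weights=(0.0, 1.0, 0.0))
        assert mode == "strip"
        outside = ~np.isin(labels, (1, 2, 3))
        assert np.all(img[outside] == 0.0)
        np.testing.assert_array_equal(img[~outside], image[~outside])

    def test_keep_is_identity(self, head, rng):
        image, labels = head
        img, lab, mode = apply_skull_mode(image, labels, rng,
                                          weights=(1.0, 0.0, 0.0))
        assert mode == "keep"
        np.testing.assert_array_equal(img, image)

    def test_neck_requires_nonbrain_labels(self, head, rng):
        image, labels = head
        with pytest.raises(ConfigurationError):
            apply_skull_mode(image, labels, rng, weights=(0.0, 0.0, 1.0))

    def test_branch_frequencies(self, head):
        """Over 9999 seeded draws each mode appears ~1/3 of the time."""
        image, labels = head
        rng = np.random.default_rng(8)
        n = 9999
        counts = {"keep": 0, "strip": 0, "neck": 0}
        nonbrain = np.zeros_like(labels)
        nonbrain[0] = 10  # trivially satisfiable neck region
        stats = {10: (0.5, 0.0)}
        for _ in range(n):
            _, _, mode = apply_skull_mode(image, labels, rng,
                                          nonbrain_labels=nonbrain,
                                          stats=stats)
            counts[mode] += 1
        p = 1 / 3
        se = np.sqrt(p * (1 - p) / n)
        for mode in counts:
            assert abs(counts[mode] / n - p) < 3 * se


class TestSynthNeck:
    def test_zero_std_constant_fill(self, head, rng):
        image, labels = head
        nonbrain = np.zeros_like(labels)
        nonbrain[0, :, :] = 10
        out = synth_neck(image, nonbrain, {10: (0.7, 0.0)}, rng)
        fill = (nonbrain == 10) & (image == 0)
        assert np.all(out[fill] == 0.7)

    def test_fov_untouched_and_deterministic(self, head):
        image, labels = head
        nonbrain = np.zeros_like(labels)
        nonbrain[:2] = 11
        stats = {11: (0.4, 0.1)}
        a = synth_neck(image, nonbrain, stats, np.random.default_rng(5))
        b = synth_neck(image, nonbrain, stats, np.random.default_rng(5))
        fov = image != 0
        np.testing.assert_array_equal(a[fov], image[fov])
        np.testing.assert_array_equal(a, b)

    def test_missing_stats_falls_back_with_warning(self, head, rng):
        image, labels = head
        nonbrain = np.zeros_like(labels)
        nonbrain[0, :, :] = 99
        with pytest.warns(UserWarning, match="no stats"):
            synth_neck(image, nonbrain, {}, rng)

    def test_stats_computed_within_fov(self, head):
        image, labels = head
        nonbrain = np.zeros_like(labels)
        nonbrain[2:10, 2:10, 2:10] = 10  # overlaps the skull shell
        stats = compute_nonbrain_stats(image, nonbrain)
        vox = image[(nonbrain == 10) & (image != 0)]
        assert stats[10][0] == pytest.approx(vox.mean())


class TestBiasField:
    def test_zero_hyperparameter_uniform_field(self, rng):
        field = bias_field((8, 9, 10), 0.0, rng)
        np.testing.assert_allclose(field, 1.0, atol=1e-12)

    def test_range_and_shape(self, rng):
        field = bias_field((16, 16, 16), 0.6, rng)
        assert field.shape == (16, 16, 16)
        assert field.min() > 0.0 and field.max() <= 1.0
        assert field.max() == pytest.approx(1.0)

    def test_multiplicative_preserves_zero_set(self, head, rng):
        image, _ = head
        field = bias_field(image.shape, 0.6, rng)
        corrupted = image * field
        np.testing.assert_array_equal(corrupted == 0.0, image == 0.0)


class TestGeometry:
    def test_all_gates_off_is_identity(self, head, rng):
        image, labels = head
        img, lab, log = reorient_flip_translate(image, labels, rng,
                                                reorient_prob=0.0,
                                                flip_prob=0.0,
                                                translate_prob=0.0)
        np.testing.assert_array_equal(img, image)
        np.testing.assert_array_equal(lab, labels)

    def test_intensity_multiset_preserved(self, head):
        image, labels = head
        img, lab, log = reorient_flip_translate(
            image, labels, np.random.default_rng(3), translate_prob=0.0)
        np.testing.assert_array_equal(np.sort(img.ravel()),
                                      np.sort(image.ravel()))

    def test_foreground_count_invariant(self, head):
        image, labels = head
        for seed in range(20):
            _, lab, _ = reorient_flip_translate(image, labels,
                                                np.random.default_rng(seed))
            assert np.count_nonzero(lab) == np.count_nonzero(labels)
            np.testing.assert_array_equal(np.bincount(lab.ravel()),
                                          np.bincount(labels.ravel()))

    def test_labels_follow_image(self, head):
        image, labels = head
        img, lab, _ = reorient_flip_translate(image, labels,
                                              np.random.default_rng(9))
        # the image was built as a function of the labels; the relation
        # must survive any rigid transform
        np.testing.assert_allclose(img, np.where(lab > 0, lab * 0.2 + 0.1, 0.0))


class TestDownsampleCascade:
    def test_shape_always_preserved(self, rng):
        image = rng.normal(0, 1, (11, 12, 13))
        for _ in range(20):
            out = downsample_cascade(image, rng)
            assert out.shape == image.shape

    def test_branch_fractions(self):
        """~50% untouched, ~25% one axis, ~12.5% two, ~12.5% three."""
        rng = np.random.default_rng(17)
        image = np.zeros((6, 6, 6))
        n = 4000
        counts = np.zeros(4, dtype=int)
        for _ in range(n):
            log = {}
            downsample_cascade(image, rng, log=log)
            counts[len(log["axes"])] += 1
        for k, p in enumerate((0.5, 0.25, 0.125, 0.125)):
            se = np.sqrt(p * (1 - p) / n)
            assert abs(counts[k] / n - p) < 3 * se

    def test_identity_branch_is_exact_copy(self, rng):
        image = rng.normal(0, 1, (8, 8, 8))
        for _ in range(10):
            log = {}
            out = downsample_cascade(image, rng, log=log)
            if not log["axes"]:
                np.testing.assert_array_equal(out, image)
                break
        else:  # pragma: no cover - probability 2^-10
            pytest.fail("identity branch never drawn")


class TestNoise:
    def test_uniform_noise_foreground_untouched(self, head):
        image, labels = head
        out = uniform_noise(image, labels, np.random.default_rng(2),
                            fg_labels=(1, 2, 3))
        fg = np.isin(labels, (1, 2, 3))
        np.testing.assert_array_equal(out[fg], image[fg])
        assert not np.array_equal(out[~fg], image[~fg])

    def test_uniform_noise_zero_mean(self):
        labels = np.zeros((40, 40, 40), dtype=int)
        labels[18:22, 18:22, 18:22] = 1
        image = np.where(labels > 0, 0.5, 0.0)
        out = uniform_noise(image, labels, np.random.default_rng(4))
        bg = labels == 0
        shift = out[bg].mean() - image[bg].mean()
        q5 = 0.5  # constant foreground
        level_max = 4 * q5  # |N(q5, q5^2)| rarely exceeds this
        se = level_max / np.sqrt(bg.sum())
        assert abs(shift) < 3 * se

    def test_uniform_noise_deterministic(self, head):
        image, labels = head
        a = uniform_noise(image, labels, np.random.default_rng(6))
        b = uniform_noise(image, labels, np.random.default_rng(6))
        np.testing.assert_array_equal(a, b)

    def test_nonuniform_noise_outside_foreground_only(self, head):
        image, labels = head
        fg = labels > 0
        for seed in range(10):
            out = nonuniform_noise(image, labels,
                                   np.random.default_rng(seed))
            np.testing.assert_array_equal(out[fg], image[fg])

    def test_nonuniform_prism_count_geometric(self, head):
        image, labels = head
        rng = np.random.default_rng(19)
        n = 2000
        counts = []
        for _ in range(n):
            log = {}
            nonuniform_noise(image, labels, rng, log=log)
            counts.append(len(log["prisms"]))
        mean = np.mean(counts)
        se = np.sqrt(2.0 / n)  # geometric(1/2) on {1,2,...}: var = 2
        assert abs(mean - 2.0) < 3 * se


class TestAugmentChain:
    def test_identity_configuration(self, head, rng):
        image, labels = head
        img, lab, log = augment(image, labels, AugmentConfig.identity(), rng)
        np.testing.assert_array_equal(img, image)
        np.testing.assert_array_equal(lab, labels)
        assert log["skull_mode"] == "keep"

    def test_seeded_replay_bit_identical(self, head):
        image, labels = head
        config = AugmentConfig(skull_weights=(0.5, 0.5, 0.0))
        a_img, a_lab, a_log = augment(image, labels, config, 123)
        b_img, b_lab, _ = augment(image, labels, config, a_log["seed"])
        np.testing.assert_array_equal(a_img, b_img)
        np.testing.assert_array_equal(a_lab, b_lab)

    def test_output_finite_and_same_shape(self, head):
        image, labels = head
        config = AugmentConfig(skull_weights=(0.5, 0.5, 0.0))
        for seed in range(5):
            img, lab, log = augment(image, labels, config, seed)
            assert img.shape == image.shape
            assert np.all(np.isfinite(img))

    def test_config_validation(self):
        with pytest.raises(ConfigurationError):
            AugmentConfig(flip_prob=1.5)
        with pytest.raises(ConfigurationError):
            AugmentConfig(skull_weights=(0.5, 0.5, 0.5))
        with pytest.raises(ConfigurationError):
            AugmentConfig(bias_b=-0.1)

    def test_yaml_roundtrip(self, tmp_path):
        config = AugmentConfig(bias_b=0.3, flip_prob=0.25)
        path = tmp_path / "aug.yaml"
        config.to_yaml(path)
        assert AugmentConfig.from_yaml(path) == config
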