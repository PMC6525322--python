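import numpy as np
import pytest

from plastwm import (
    DecodeDataset,
    bootstrap_greater,
    cross_decode,
    decode_timecourse,
    pattern_similarity,
    train_linear_decoder,
)


def _one_hot_data(n_per_class=8, n_classes=4, noise=0.0, seed=0):
    rng = np.random.default_rng(seed)
    X, y = [], []
    for c in range(n_classes):
        for _ in range(n_per_class):
            v = np.zeros(n_classes)
            v[c] = 1.0
            X.append(v + noise * rng.standard_normal(n_classes))
            y.append(c)
    return DecodeDataset(np.asarray(X), np.asarray(y))


class TestDecoder:
    def test_separable_classes_decode_perfectly(self):
        _, rep = train_linear_decoder(_one_hot_data())
        assert rep.accuracy == 1.0
        assert rep.chance == 0.25

    def test_shuffled_labels_fall_to_chance(self):
        data = _one_hot_data(n_per_class=24)
        rng = np.random.default_rng(1)
        shuffled = DecodeDataset(data.samples, rng.permutation(data.labels))
        _, rep = train_linear_decoder(shuffled, seed=1)
        assert abs(rep.accuracy - rep.chance) < 0.15

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            DecodeDataset(np.zeros((4, 3)), np.zeros(4))

    def test_train_accuracy_at_least_cv(self):
        data = _one_hot_data(noise=0.6, seed=3)
        clf, rep = train_linear_decoder(data, seed=3)
        train_acc = np.mean(clf.predict(data.samples) == data.labels)
        assert train_acc >= rep.accuracy - 1e-9


class TestCrossDecode:
    def test_train_equals_test_recovers_within_accuracy(self):
        data = _one_hot_data(noise=0.1)
        rep = cross_decode(data, data, n_shuffles=50)
        assert rep.cross_accuracy == pytest.approx(rep.accuracy)

    def test_label_space_mismatch_rejected(self):
        a = _one_hot_data()
        b = DecodeDataset(a.samples, a.labels + 10)
        with pytest.raises(ValueError):
            cross_decode(a, b, n_shuffles=10)

    def test_orthogonal_random_patterns_sit_at_chance(self):
        rng = np.random.default_rng(4)
        train = _one_hot_data(n_per_class=16)
        test = DecodeDataset(rng.standard_normal(train.samples.shape),
                             rng.permutation(train.labels))
        rep = cross_decode(train, test, n_shuffles=200, seed=4)
        lo, hi = rep.null_quantiles
        assert lo <= rep.cross_accuracy <= hi


class TestPatternSimilarity:
    def test_identical_vectors(self):
        v = np.array([0.2, 0.9, 0.1, 0.5])
        assert pattern_similarity(v, v) == pytest.approx(1.0)

    def test_sign_flip_about_mean(self):
        v = np.array([0.2, 0.9, 0.1, 0.5])
        flipped = 2 * v.mean() - v
        assert pattern_similarity(v, flipped) == pytest.approx(-1.0)

    def test_independent_vectors_average_to_zero(self):
        """Monte-Carlo check: mean correlation of independent random
        4-vectors is ~0 (sd of the mean ~ 1/sqrt(3 n))."""
        rng = np.random.default_rng(5)
        rhos = [pattern_similarity(rng.standard_normal(4), rng.standard_normal(4))
                for _ in range(4000)]
        assert abs(np.mean(rhos)) < 0.03

    def test_zero_variance_reported_missing(self):
        assert np.isnan(pattern_similarity(np.ones(4), np.arange(4)))

    def test_affine_invariance_and_symmetry(self):
        rng = np.random.default_rng(6)
        a, b = rng.standard_normal(6), rng.standard_normal(6)
        assert pattern_similarity(a, b) == pytest.approx(pattern_similarity(b, a))
        assert pattern_similarity(2 * a + 1, 2 * b + 1) == pytest.approx(
            pattern_similarity(a, b)
        )

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            pattern_similarity(np.ones(3), np.ones(4))


class TestTimecourse:
    def test_informative_window_found(self):
        rng = np.random.default_rng(7)
        n, steps, units = 40, 30, 4
        labels = np.repeat(np.arange(4), 10)
        traces = 0.05 * rng.standard_normal((n, steps, units))
        for i, lab in enumerate(labels):   # signal only in steps 20..30
            traces[i, 20:, lab] += 1.0
        rep = decode_timecourse(traces, labels, [(0, 10), (20, 30)], seed=7)
        accs = {(a, b): acc for a, b, acc in rep.per_window}
        assert accs[(20, 30)] > accs[(0, 10)]
        assert rep.accuracy == accs[(20, 30)]


class TestBootstrap:
    def test_clear_separation_detected(self, rng):
        a = rng.normal(0.7, 0.1, size=100)
        b = rng.normal(0.3, 0.1, size=100)
        assert bootstrap_greater(a, b, seed=0)
        assert not bootstrap_greater(b, a, seed=0)

    def test_equal_samples_not_called_different(self, rng):
        a = rng.normal(0.5, 0.1, size=100)
        b = rng.normal(0.5, 0.1, size=100)
        assert not bootstrap_greater(a, b, seed=0)
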