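from types import SimpleNamespace

import numpy as np
import pytest

from dacl.colbgan import (ColBGaNClassifier, ColBGaNConfig, ColBGaNModel,
                          augment_minority, discriminator_value,
                          embed_condition, generate_samples, generator_loss,
                          predict, refit_classifier)
from dacl.schema import EncodedMatrix


def _enc(X, y):
    emap = {f"c{j}": {"kind": "numeric", "indices": [j], "min": 0.0, "max": 1.0}
            for j in range(X.shape[1])}
    return EncodedMatrix(X, np.zeros_like(X, dtype=bool), emap,
                         np.asarray(y, dtype=int))


def _gaussian_blobs(n=600, d=4, sep=0.4, seed=0):
    rng = np.random.default_rng(seed)
    y = np.repeat([0, 1], n // 2)
    X = np.vstack([rng.normal(0.5 - sep / 2, 0.08, size=(n // 2, d)),
                   rng.normal(0.5 + sep / 2, 0.08, size=(n // 2, d))])
    return _enc(np.clip(X, 0, 1), y)


class TestEmbedding:
    def test_output_dimension(self):
        model = ColBGaNModel(6, ColBGaNConfig(noise_dim=4, embed_dim=8, seed=0))
        out = embed_condition(np.zeros(4), 1, model)
        assert out.shape == (8,)

    def test_zero_weights_zero_output(self):
        model = ColBGaNModel(6, ColBGaNConfig(noise_dim=4, embed_dim=8, seed=0))
        model.noise_embed.W[:] = 0.0
        model.noise_embed.b[:] = 0.0
        model.label_embed[:] = 0.0
        np.testing.assert_allclose(embed_condition(np.ones(4), 0, model), 0.0)

    def test_additive_decomposition(self):
        model = ColBGaNModel(6, ColBGaNConfig(noise_dim=4, embed_dim=8, seed=1))
        noise = np.random.default_rng(0).normal(size=4)
        gamma_t = embed_condition(noise, 1, model)
        alpha_t = model.noise_embed.forward(noise[None, :])[0]
        np.testing.assert_allclose(gamma_t - model.label_embed[1], alpha_t)

    def test_unknown_label_rejected(self):
        model = ColBGaNModel(6, ColBGaNConfig(seed=0))
        with pytest.raises(ValueError):
            embed_condition(np.zeros(16), 5, model)


class TestGeneration:
    def test_width_range_determinism(self):
        model = ColBGaNModel(7, ColBGaNConfig(seed=3))
        s1 = generate_samples([0, 1, 1], model, seed=11)
        s2 = generate_samples([0, 1, 1], model, seed=11)
        assert s1.shape == (3, 7)
        assert (s1 >= 0).all() and (s1 <= 1).all()
        np.testing.assert_array_equal(s1, s2)


class TestDiscriminatorValue:
    def _stub(self, fn):
        return SimpleNamespace(discriminator=SimpleNamespace(forward=fn))

    def test_indifferent_discriminator(self):
        model = self._stub(lambda x: np.full((len(x), 1), 0.5))
        assert discriminator_value(np.zeros((4, 2)), np.ones((4, 2)), model) \
            == pytest.approx(1.0)

    def test_perfect_discriminator(self):
        real, fake = np.zeros((3, 2)), np.ones((3, 2))
        model = self._stub(lambda x: (x[:, :1] == 0).astype(float))
        assert discriminator_value(real, fake, model) == pytest.approx(2.0)

    def test_bounded(self):
        model = ColBGaNModel(2, ColBGaNConfig(seed=0))
        rng = np.random.default_rng(0)
        v = discriminator_value(rng.uniform(size=(10, 2)),
                                rng.uniform(size=(10, 2)), model)
        assert 0.0 < v < 2.0

    def test_empty_batch_rejected(self):
        model = ColBGaNModel(2, ColBGaNConfig(seed=0))
        with pytest.raises(ValueError):
            discriminator_value(np.zeros((0, 2)), np.ones((3, 2)), model)


class TestGeneratorLoss:
    def test_fooled_discriminator_zero_loss(self):
        model = SimpleNamespace(
            discriminator=SimpleNamespace(forward=lambda x: np.ones((len(x), 1))))
        loss = generator_loss(np.zeros((4, 2)), np.zeros(4, int), model, 0.0)
        assert loss == pytest.approx(0.0, abs=1e-6)

    def test_monotone_in_delta(self):
        model = ColBGaNModel(3, ColBGaNConfig(seed=1))
        fake = np.random.default_rng(0).uniform(size=(8, 3))
        labels = np.array([0, 1] * 4)
        l0 = generator_loss(fake, labels, model, 0.0)
        l1 = generator_loss(fake, labels, model, 1.0)
        l2 = generator_loss(fake, labels, model, 2.0)
        assert l0 <= l1 <= l2


class TestTraining:
    def test_log_lengths_and_finiteness(self):
        enc = _gaussian_blobs(n=200)
        res = ColBGaNClassifier(enc, ColBGaNConfig(epochs=8, seed=0)).fit()
        for series in (res.log.discriminator_value, res.log.generator_loss,
                       res.log.classifier_loss):
            assert len(series) == 8
            assert np.isfinite(series).all()

    def test_separable_blobs_high_accuracy(self):
        enc = _gaussian_blobs(n=600, sep=0.4, seed=0)
        res = ColBGaNClassifier(enc, ColBGaNConfig(epochs=40, seed=1)).fit()
        pred, probs = res.predict(enc.matrix)
        assert (pred == enc.label_vector).mean() >= 0.95
        np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-6)

    def test_same_seed_same_losses(self):
        enc = _gaussian_blobs(n=200)
        cfg = ColBGaNConfig(epochs=5, seed=9)
        r1 = ColBGaNClassifier(enc, cfg).fit()
        r2 = ColBGaNClassifier(enc, cfg).fit()
        assert r1.log.generator_loss == r2.log.generator_loss
        assert r1.log.discriminator_value == r2.log.discriminator_value

    def test_delta_zero_reduces_to_plain_conditional_gan(self):
        """With delta = 0 the auxiliary classifier must not influence the
        adversarial pair: its updates on or off give identical GAN losses."""
        enc = _gaussian_blobs(n=200)
        on = ColBGaNClassifier(enc, ColBGaNConfig(epochs=6, delta=0.0, seed=4,
                                                  classifier_enabled=True)).fit()
        off = ColBGaNClassifier(enc, ColBGaNConfig(epochs=6, delta=0.0, seed=4,
                                                   classifier_enabled=False)).fit()
        assert on.log.generator_loss == off.log.generator_loss
        assert on.log.discriminator_value == off.log.discriminator_value

    def test_single_class_rejected(self):
        X = np.random.default_rng(0).uniform(size=(20, 3))
        with pytest.raises(ValueError):
            ColBGaNClassifier(_enc(X, np.zeros(20)))


class TestAugmentation:
    def test_counts_balanced_exactly(self):
        rng = np.random.default_rng(0)
        X = rng.uniform(size=(100, 3))
        y = np.array([0] * 90 + [1] * 10)
        enc = _enc(X, y)
        model = ColBGaNModel(3, ColBGaNConfig(seed=0))
        aug, flags = augment_minority(enc, model, seed=1)
        assert flags.sum() == 80
        counts = np.bincount(np.asarray(aug.label_vector, int))
        assert counts[0] == counts[1] == 90

    def test_balanced_input_unchanged(self):
        X = np.random.default_rng(0).uniform(size=(20, 3))
        y = np.repeat([0, 1], 10)
        enc = _enc(X, y)
        model = ColBGaNModel(3, ColBGaNConfig(seed=0))
        aug, flags = augment_minority(enc, model, seed=1)
        assert not flags.any()
        assert aug is enc

    def test_real_rows_untouched(self):
        rng = np.random.default_rng(1)
        X = rng.uniform(size=(50, 3))
        y = np.array([0] * 40 + [1] * 10)
        enc = _enc(X, y)
        model = ColBGaNModel(3, ColBGaNConfig(seed=0))
        aug, flags = augment_minority(enc, model, seed=1)
        np.testing.assert_array_equal(aug.matrix[:50], X)
        assert (aug.matrix >= 0).all() and (aug.matrix <= 1).all()


def test_predict_duplicates_identical():
    model = ColBGaNModel(4, ColBGaNConfig(seed=0))
    row = np.random.default_rng(0).uniform(size=(1, 4))
    rows = np.vstack([row, row])
    labels, probs = predict(rows, model)
    assert labels[0] == labels[1]
    np.testing.assert_array_equal(probs[0], probs[1])


def test_refit_classifier_reduces_loss():
    enc = _gaussian_blobs(n=200, sep=0.5)
    model = ColBGaNModel(4, ColBGaNConfig(seed=2))
    losses = refit_classifier(model, enc, epochs=20, seed=0)
    assert losses[-1] < losses[0]
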