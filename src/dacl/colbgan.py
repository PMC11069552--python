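"""Collaborative bias-integrated GAN for imbalanced tabular classification.

Three networks trained in two adversarial pairings:

* a conditional **generator** that maps an additive embedding of Gaussian
  noise and a learned per-class label vector to a synthetic encoded row
  (sigmoid outputs, so samples live in the [0, 1] encoded hypercube);
* a **discriminator** scoring real vs generated rows;
* an auxiliary **classifier** trained on real labeled rows.

The generator objective is the non-saturating adversarial cross-entropy
toward "real" plus ``delta`` times the classifier cross-entropy on the
generated rows' intended labels — the collaboration term that keeps
minority-class samples classifiable rather than drifting to the majority
mode.  ``delta`` is the knob the water-drop tuner optimizes.  After
training, the generator balances the classes by synthesizing minority rows
and the classifier head predicts labels.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._nn import MLP, Adam, Dense, bce, softmax, softmax_ce
from .schema import EncodedMatrix

__all__ = ["ColBGaNConfig", "ColBGaNModel", "TrainingLog",
           "ColBGaNClassifier", "ColBGaNResults",
           "embed_condition", "generate_samples", "discriminator_value",
           "generator_loss", "train_colbgan", "augment_minority", "predict",
           "refit_classifier"]

_EPS = 1e-7


@dataclass(frozen=True)
class ColBGaNConfig:
    noise_dim: int = 16
    embed_dim: int = 32
    gen_hidden: tuple[int, ...] = (64, 64)
    disc_hidden: tuple[int, ...] = (64, 64)
    clf_hidden: tuple[int, ...] = (64, 64)
    delta: float = 1.0
    feature_match_weight: float = 5.0  # class-conditional mean matching
    epochs: int = 300
    batch_size: int = 64
    lr_gen: float = 2e-4
    lr_disc: float = 2e-4
    lr_clf: float = 1e-3
    augment_to_balance: bool = True
    classifier_enabled: bool = True
    seed: int = 0

    def __post_init__(self):
        if self.noise_dim < 1:
            raise ValueError("noise_dim must be >= 1")
        if not np.isfinite(self.delta) or self.delta < 0:
            raise ValueError("delta must be finite and >= 0")


class ColBGaNModel:
    """Parameter container: embeddings, generator, discriminator, classifier."""

    def __init__(self, d_out: int, config: ColBGaNConfig, n_classes: int = 2):
        rng = np.random.default_rng(config.seed)
        self.config = config
        self.d_out = d_out
        self.n_classes = n_classes
        self.noise_embed = Dense(config.noise_dim, config.embed_dim, rng, "lrelu")
        self.label_embed = rng.normal(0.0, 0.1, size=(n_classes, config.embed_dim))
        self._label_embed_grad = np.zeros_like(self.label_embed)
        self.generator = MLP([config.embed_dim, *config.gen_hidden, d_out], rng,
                             output_activation="sigmoid")
        self.discriminator = MLP([d_out, *config.disc_hidden, 1], rng,
                                 output_activation="sigmoid")
        self.classifier = MLP([d_out, *config.clf_hidden, n_classes], rng,
                              output_activation=None)

    # --- conditional generation -------------------------------------------
    def embed(self, noise: np.ndarray, labels: np.ndarray) -> np.ndarray:
        if np.any(labels < 0) or np.any(labels >= self.n_classes):
            raise ValueError("unknown label in conditioning batch")
        alpha_t = self.noise_embed.forward(np.atleast_2d(noise))
        beta_t = self.label_embed[labels]
        return alpha_t + beta_t

    def generate(self, labels: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        labels = np.asarray(labels, dtype=int)
        noise = rng.normal(size=(len(labels), self.config.noise_dim))
        return self.generator.forward(self.embed(noise, labels))

    def class_probabilities(self, rows: np.ndarray) -> np.ndarray:
        rows = np.atleast_2d(rows)
        if rows.shape[1] != self.d_out:
            raise ValueError(f"row width {rows.shape[1]} != {self.d_out}")
        return softmax(self.classifier.forward(rows))


@dataclass
class TrainingLog:
    discriminator_value: list[float] = field(default_factory=list)  # empirical minimax value
    generator_loss: list[float] = field(default_factory=list)
    classifier_loss: list[float] = field(default_factory=list)
    minority_generated: list[int] = field(default_factory=list)


# ---------------------------------------------------------------------------
# module-level operations (thin views over the model, used by tests and CLI)

def embed_condition(noise: np.ndarray, label: int, model: ColBGaNModel) -> np.ndarray:
    """Additive conditioning vector gamma_t = embed(noise) + embed(label)."""
    out = model.embed(np.atleast_2d(noise), np.asarray([label], dtype=int))
    return out[0]


def generate_samples(labels, model: ColBGaNModel, seed: int = 0) -> np.ndarray:
    return model.generate(np.asarray(labels, dtype=int), np.random.default_rng(seed))


def discriminator_value(real: np.ndarray, fake: np.ndarray,
                        model: ColBGaNModel) -> float:
    """Empirical minimax value: mean D(real) + mean (1 - D(fake)) in (0, 2)."""
    if len(real) == 0 or len(fake) == 0:
        raise ValueError("batches must be non-empty")
    d_real = model.discriminator.forward(np.atleast_2d(real)).ravel()
    d_fake = model.discriminator.forward(np.atleast_2d(fake)).ravel()
    return float(d_real.mean() + (1.0 - d_fake).mean())


def generator_loss(fake: np.ndarray, fake_labels: np.ndarray,
                   model: ColBGaNModel, delta: float) -> float:
    """CE(D(fake), 1) + delta * CE(classifier(fake), intended labels)."""
    d_fake = model.discriminator.forward(np.atleast_2d(fake))
    adv = bce(d_fake, 1.0)
    if delta == 0.0:
        return adv
    probs = model.class_probabilities(fake)
    return adv + delta * softmax_ce(probs, np.asarray(fake_labels, dtype=int))


# ---------------------------------------------------------------------------
# training

def _bce_grad(p: np.ndarray, target: float, n: int) -> np.ndarray:
    p = np.clip(p, _EPS, 1.0 - _EPS)
    return (p - target) / (p * (1.0 - p)) / n


class ColBGaNClassifier:
    """GAN-classifier model over an encoded training matrix.

    Statsmodels-style usage::

        results = ColBGaNClassifier(enc, config).fit()
        labels, probs = results.predict(test_matrix)
    """

    def __init__(self, enc: EncodedMatrix, config: ColBGaNConfig | None = None):
        y = np.asarray(enc.label_vector, dtype=int)
        if len(np.unique(y)) < 2:
            raise ValueError("both classes must be present for adversarial training")
        self.enc = enc
        self.config = config or ColBGaNConfig()

    def fit(self) -> "ColBGaNResults":
        cfg = self.config
        X = self.enc.matrix
        y = np.asarray(self.enc.label_vector, dtype=int)
        n, d = X.shape
        model = ColBGaNModel(d, cfg)
        rng = np.random.default_rng(cfg.seed + 1)

        gen_params = (model.generator.params + model.noise_embed.params
                      + [model.label_embed])
        opt_gen = Adam(gen_params, lr=cfg.lr_gen)
        opt_disc = Adam(model.discriminator.params, lr=cfg.lr_disc)
        opt_clf = Adam(model.classifier.params, lr=cfg.lr_clf)

        # class-conditional real means, the anchors for feature matching: the
        # generator's per-class output means are pulled toward the real
        # per-class means, which pins the conditional marginals the
        # adversarial signal alone leaves underdetermined
        class_means = {c: X[y == c].mean(axis=0) for c in range(model.n_classes)}

        log = TrainingLog()
        for _ in range(cfg.epochs):
            order = rng.permutation(n)
            ep_disc, ep_gen, ep_clf, nb = 0.0, 0.0, 0.0, 0
            for start in range(0, n, cfg.batch_size):
                idx = order[start:start + cfg.batch_size]
                real, real_y = X[idx], y[idx]
                bs = len(idx)

                # (i) discriminator ascent: real -> 1, generated -> 0
                fake_y = rng.integers(model.n_classes, size=bs)
                fake = model.generate(fake_y, rng)
                d_real = model.discriminator.forward(real)
                model.discriminator.backward(_bce_grad(d_real, 1.0, bs))
                g_real = [g.copy() for g in model.discriminator.grads]
                d_fake = model.discriminator.forward(fake)
                model.discriminator.backward(_bce_grad(d_fake, 0.0, bs))
                opt_disc.step([gr + gf for gr, gf in
                               zip(g_real, model.discriminator.grads)])
                ep_disc += float(d_real.mean() + (1.0 - d_fake).mean())

                # (ii) classifier descent on real labeled rows
                if cfg.classifier_enabled:
                    logits = model.classifier.forward(real)
                    probs = softmax(logits)
                    ep_clf += softmax_ce(probs, real_y)
                    grad = probs.copy()
                    grad[np.arange(bs), real_y] -= 1.0
                    model.classifier.backward(grad / bs)
                    opt_clf.step(model.classifier.grads)

                # (iii) generator descent: fool D, satisfy classifier (delta)
                fake_y = rng.integers(model.n_classes, size=bs)
                noise = rng.normal(size=(bs, cfg.noise_dim))
                gamma = model.embed(noise, fake_y)
                fake = model.generator.forward(gamma)
                d_fake = model.discriminator.forward(fake)
                gen_l = bce(d_fake, 1.0)
                grad_fake = model.discriminator.backward(_bce_grad(d_fake, 1.0, bs))
                if cfg.delta > 0.0:
                    logits = model.classifier.forward(fake)
                    probs = softmax(logits)
                    gen_l += cfg.delta * softmax_ce(probs, fake_y)
                    gclf = probs.copy()
                    gclf[np.arange(bs), fake_y] -= 1.0
                    grad_fake = grad_fake + cfg.delta * \
                        model.classifier.backward(gclf / bs)
                if cfg.feature_match_weight > 0.0:
                    for c in range(model.n_classes):
                        sel = fake_y == c
                        if not sel.any():
                            continue
                        diff = fake[sel].mean(axis=0) - class_means[c]
                        gfm = np.zeros_like(fake)
                        gfm[sel] = 2.0 * diff / sel.sum()
                        grad_fake = grad_fake + cfg.feature_match_weight * gfm
                if not np.isfinite(gen_l):
                    raise FloatingPointError("generator loss diverged")
                grad_gamma = model.generator.backward(grad_fake)
                model.noise_embed.backward(grad_gamma)
                emb_grad = np.zeros_like(model.label_embed)
                np.add.at(emb_grad, fake_y, grad_gamma)
                opt_gen.step(model.generator.grads + model.noise_embed.grads
                             + [emb_grad])
                ep_gen += gen_l
                nb += 1

            log.discriminator_value.append(ep_disc / nb)
            log.generator_loss.append(ep_gen / nb)
            log.classifier_loss.append(ep_clf / nb if cfg.classifier_enabled else 0.0)
            log.minority_generated.append(0)

        return ColBGaNResults(model=model, config=cfg, log=log, enc=self.enc)


@dataclass
class ColBGaNResults:
    model: ColBGaNModel
    config: ColBGaNConfig
    log: TrainingLog
    enc: EncodedMatrix

    def predict(self, rows: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        probs = self.model.class_probabilities(rows)
        return probs.argmax(axis=1), probs

    def generate(self, labels, seed: int = 0) -> np.ndarray:
        return generate_samples(labels, self.model, seed)

    def augment_minority(self, enc: EncodedMatrix | None = None,
                         seed: int = 0) -> tuple[EncodedMatrix, np.ndarray]:
        return augment_minority(enc or self.enc, self.model, seed=seed)

    def summary(self) -> str:
        y = np.asarray(self.enc.label_vector, dtype=int)
        counts = np.bincount(y, minlength=2)
        lines = [
            "ColBGaN classification results",
            "=" * 40,
            f"training rows:          {len(y)} (class counts {counts.tolist()})",
            f"encoded width:          {self.model.d_out}",
            f"delta (collaboration):  {self.config.delta}",
            f"epochs:                 {self.config.epochs}",
            f"final disc value:       {self.log.discriminator_value[-1]:.4f}",
            f"final generator loss:   {self.log.generator_loss[-1]:.4f}",
            f"final classifier loss:  {self.log.classifier_loss[-1]:.4f}",
        ]
        return "\n".join(lines)


def train_colbgan(enc: EncodedMatrix,
                  config: ColBGaNConfig | None = None) -> tuple[ColBGaNModel, TrainingLog]:
    """Functional wrapper returning (model, log)."""
    res = ColBGaNClassifier(enc, config).fit()
    return res.model, res.log


def augment_minority(enc: EncodedMatrix, model: ColBGaNModel,
                     seed: int = 0) -> tuple[EncodedMatrix, np.ndarray]:
    """Append generated minority rows until class counts are equal.

    Returns (augmented matrix, synthetic-row flags); real rows come first
    and are untouched.
    """
    y = np.asarray(enc.label_vector, dtype=int)
    counts = np.bincount(y, minlength=2)
    deficit = int(abs(counts[0] - counts[1]))
    if deficit == 0:
        return enc, np.zeros(len(y), dtype=bool)
    minority = int(counts.argmin())
    fake = generate_samples([minority] * deficit, model, seed=seed)
    matrix = np.vstack([enc.matrix, fake])
    mask = np.vstack([enc.mask, np.zeros((deficit, enc.matrix.shape[1]), dtype=bool)])
    labels = np.concatenate([y, np.full(deficit, minority, dtype=int)])
    flags = np.concatenate([np.zeros(len(y), dtype=bool), np.ones(deficit, dtype=bool)])
    out = EncodedMatrix(matrix, mask, enc.encoding_map, labels)
    return out, flags


def predict(rows: np.ndarray, model: ColBGaNModel) -> tuple[np.ndarray, np.ndarray]:
    probs = model.class_probabilities(rows)
    return probs.argmax(axis=1), probs


def refit_classifier(model: ColBGaNModel, enc: EncodedMatrix,
                     epochs: int = 50, lr: float = 1e-3, batch_size: int = 64,
                     seed: int = 0) -> list[float]:
    """Continue training the classifier head alone (e.g. on augmented data)."""
    X = enc.matrix
    y = np.asarray(enc.label_vector, dtype=int)
    rng = np.random.default_rng(seed)
    opt = Adam(model.classifier.params, lr=lr)
    losses = []
    for _ in range(epochs):
        order = rng.permutation(len(y))
        ep, nb = 0.0, 0
        for start in range(0, len(y), batch_size):
            idx = order[start:start + batch_size]
            probs = softmax(model.classifier.forward(X[idx]))
            ep += softmax_ce(probs, y[idx])
            grad = probs.copy()
            grad[np.arange(len(idx)), y[idx]] -= 1.0
            model.classifier.backward(grad / len(idx))
            opt.step(model.classifier.grads)
            nb += 1
        losses.append(ep / nb)
    return losses
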