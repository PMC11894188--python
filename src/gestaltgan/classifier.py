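"""Phenotype classifier: ranked predictions, embeddings, rank and top-k.

A small fully-connected network trained with softmax cross-entropy stands in
for a large pre-trained dysmorphology ensemble: it provides (a) ranked class
predictions, from which the rank of a target class is read off (the quantity
penalized during GAN training), (b) a penultimate-layer embedding space used
as the feature loss for GAN inversion, and (c) top-k accuracy for evaluating
generated images.  Once fitted the classifier is frozen: it acts as a fixed
judge and its weights never change during GAN training.

The model/results split follows the usual statistical-modelling convention:
:class:`PhenotypeClassifier` holds data and configuration,
:meth:`PhenotypeClassifier.fit` returns a :class:`ClassifierFit` carrying
the trained weights and diagnostics.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._rng import substream
from .faces import LabeledImage
from .nn import MLP, Adam, save_params, load_params, softmax, softmax_cross_entropy

MIN_IMAGES_PER_CLASS = 10


@dataclass
class RankedPrediction:
    """Post-softmax class scores and the induced ranking.

    ``order[i]`` is the class id with the i-th highest score; ties are
    broken by ascending class id so the ranking is always deterministic.
    """

    scores: np.ndarray
    order: np.ndarray

    def __post_init__(self):
        self.scores = np.asarray(self.scores, dtype=float)
        self.order = np.asarray(self.order, dtype=int)
        if np.any(self.scores < 0) or abs(self.scores.sum() - 1.0) > 1e-6:
            raise ValueError("scores must be nonnegative and sum to 1")
        if sorted(self.order.tolist()) != list(range(len(self.scores))):
            raise ValueError("order must be a permutation of the class ids")


def ranked_from_scores(scores: np.ndarray) -> RankedPrediction:
    scores = np.asarray(scores, dtype=float)
    # stable argsort on -scores: ties keep ascending class id
    order = np.argsort(-scores, kind="stable")
    return RankedPrediction(scores=scores, order=order)


def rank_of(pred: RankedPrediction, target_class: int) -> int:
    """0-based position of ``target_class`` in the ranking (0 = top)."""
    hits = np.nonzero(pred.order == int(target_class))[0]
    if hits.size == 0:
        raise ValueError(f"unknown class id {target_class}")
    return int(hits[0])


@dataclass
class FeatureVector:
    """Penultimate-layer embedding of an image."""

    values: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)

    @property
    def norm(self) -> float:
        return float(np.linalg.norm(self.values))


@dataclass
class ClassifierConfig:
    size: int = 64
    channels: int = 1
    n_classes: int = 6  # affected classes + unaffected
    hidden: tuple = (128, 64)  # last entry is the embedding dimension
    epochs: int = 12
    batch_size: int = 64
    lr: float = 1e-3
    val_fraction: float = 0.15
    occlude_prob: float = 0.5  # random-erasing augmentation probability
    occlude_size: int = 16  # occluded square side (px); forces distributed cues
    occlude_fill: float = 0.72  # fill shade (skin tone)
    seed: int = 0

    @property
    def input_dim(self) -> int:
        return self.size * self.size * self.channels

    @property
    def embed_dim(self) -> int:
        return self.hidden[-1]


def _flatten(images, size, channels) -> np.ndarray:
    if isinstance(images, np.ndarray):
        x = images.reshape(images.shape[0], -1).astype(float)
    else:
        arrs = []
        for im in images:
            px = im.pixels if isinstance(im, LabeledImage) else np.asarray(im, dtype=float)
            arrs.append(px.reshape(-1))
        x = np.stack(arrs)
    expect = size * size * channels
    if x.shape[1] != expect:
        raise ValueError(f"input size mismatch: got {x.shape[1]} values, expected {expect} "
                         f"({size}x{size}x{channels})")
    return x


class PhenotypeClassifier:
    """Trainable surrogate phenotype classifier (model object).

    Parameters
    ----------
    images, labels :
        Training images (``LabeledImage`` or arrays in [0, 1]) and integer
        class ids covering ``config.n_classes`` classes.
    config :
        Architecture and optimization settings.
    """

    def __init__(self, images, labels, config: ClassifierConfig | None = None):
        self.config = config or ClassifierConfig()
        self.x = _flatten(images, self.config.size, self.config.channels)
        self.y = np.asarray(labels, dtype=int)
        if self.x.shape[0] != self.y.shape[0]:
            raise ValueError("images and labels must have equal length")
        classes, counts = np.unique(self.y, return_counts=True)
        if classes.size < 2:
            raise ValueError("need at least 2 classes")
        for c, n in zip(classes, counts):
            if n < MIN_IMAGES_PER_CLASS:
                raise ValueError(f"class {c} has only {n} images (< {MIN_IMAGES_PER_CLASS})")

    def fit(self, seed: int | None = None) -> "ClassifierFit":
        cfg = self.config
        seed = cfg.seed if seed is None else seed
        rng_split = substream(seed, "classifier-split")
        rng_order = substream(seed, "classifier-batches")

        n = self.x.shape[0]
        perm = rng_split.permutation(n)
        n_val = max(int(round(cfg.val_fraction * n)), 1)
        val_idx, train_idx = perm[:n_val], perm[n_val:]

        trunk = MLP([cfg.input_dim, *cfg.hidden], out_activation="lrelu",
                    seed=int(substream(seed, "classifier-init").integers(2**31)), name="trunk")
        head = MLP([cfg.embed_dim, cfg.n_classes], seed=int(
            substream(seed, "classifier-init-head").integers(2**31)), name="head")
        params = {**trunk.params, **head.params}
        trunk.params = params
        head.params = params
        opt = Adam(lr=cfg.lr)

        rng_aug = substream(seed, "classifier-occlude")
        history = []
        xt, yt = self.x[train_idx], self.y[train_idx]
        for epoch in range(cfg.epochs):
            order = rng_order.permutation(len(xt))
            losses = []
            for start in range(0, len(xt), cfg.batch_size):
                idx = order[start:start + cfg.batch_size]
                xb = xt[idx]
                if cfg.occlude_prob > 0:
                    # random erasing: hide a patch so no single facial cue
                    # suffices to identify a class
                    xb = xb.copy().reshape(-1, cfg.size, cfg.size, cfg.channels)
                    for i in range(len(xb)):
                        if rng_aug.random() < cfg.occlude_prob:
                            r = int(rng_aug.integers(0, cfg.size - cfg.occlude_size))
                            c = int(rng_aug.integers(0, cfg.size - cfg.occlude_size))
                            xb[i, r:r + cfg.occlude_size,
                               c:c + cfg.occlude_size] = cfg.occlude_fill
                    xb = xb.reshape(len(xb), -1)
                h, cache_t = trunk.forward(xb)
                logits, cache_h = head.forward(h)
                loss, dlogits = softmax_cross_entropy(logits, yt[idx])
                dh, g_head = head.backward(cache_h, dlogits)
                _, g_trunk = trunk.backward(cache_t, dh)
                opt.step(params, {**g_head, **g_trunk})
                losses.append(loss)
            val_logits = head(trunk(self.x[val_idx]))
            val_acc = float(np.mean(np.argmax(val_logits, axis=1) == self.y[val_idx]))
            history.append({"epoch": epoch, "train_loss": float(np.mean(losses)),
                            "val_top1": val_acc})
        return ClassifierFit(config=cfg, params=params, history=history,
                             heldout_top1=history[-1]["val_top1"])


@dataclass
class ClassifierFit:
    """Fitted, frozen classifier (results object)."""

    config: ClassifierConfig
    params: dict
    history: list = field(default_factory=list)
    heldout_top1: float = float("nan")
    frozen: bool = True

    def __post_init__(self):
        cfg = self.config
        self._trunk = MLP([cfg.input_dim, *cfg.hidden], out_activation="lrelu", name="trunk")
        self._head = MLP([cfg.embed_dim, cfg.n_classes], name="head")
        self._trunk.params = self.params
        self._head.params = self.params

    # -- forward passes -----------------------------------------------------

    def _as_batch(self, images) -> np.ndarray:
        if isinstance(images, (LabeledImage, np.ndarray)) and not (
                isinstance(images, np.ndarray) and images.ndim == 4):
            images = [images]
        return _flatten(images, self.config.size, self.config.channels)

    def logits(self, images) -> np.ndarray:
        return self._head(self._trunk(self._as_batch(images)))

    def predict_proba(self, images) -> np.ndarray:
        return softmax(self.logits(images))

    def predict_ranked(self, image) -> RankedPrediction:
        """Deterministic ranked prediction for a single image."""
        scores = self.predict_proba(image)[0]
        return ranked_from_scores(scores)

    def embed(self, image) -> FeatureVector:
        """Penultimate-layer embedding of a single image."""
        return FeatureVector(self._trunk(self._as_batch(image))[0])

    def embed_batch(self, images) -> np.ndarray:
        return self._trunk(self._as_batch(images))

    def topk_accuracy(self, images, labels, k: int = 5) -> float:
        """Fraction of images whose label ranks in the top k predictions."""
        if k < 1:
            raise ValueError("k must be >= 1")
        labels = np.asarray(labels, dtype=int)
        if labels.size == 0:
            raise ValueError("empty input")
        proba = self.predict_proba(images)
        if proba.shape[0] != labels.size:
            raise ValueError("images and labels must have equal length")
        ranks = np.array([rank_of(ranked_from_scores(p), y) for p, y in zip(proba, labels)])
        return float(np.mean(ranks < k))

    # -- gradient access for downstream losses ------------------------------

    def loss_and_input_grad(self, x_flat: np.ndarray, labels: np.ndarray):
        """Cross-entropy of the frozen judge and its gradient w.r.t. pixels."""
        h, cache_t = self._trunk.forward(x_flat)
        logits, cache_h = self._head.forward(h)
        loss, dlogits = softmax_cross_entropy(logits, labels)
        dh, _ = self._head.backward(cache_h, dlogits)
        dx, _ = self._trunk.backward(cache_t, dh)
        return loss, dx, logits

    def embed_and_input_grad_fn(self, x_flat: np.ndarray):
        """Forward to the embedding; returns (embedding, backward(d_embed) -> dx)."""
        h, cache_t = self._trunk.forward(x_flat)

        def backward(dh):
            dx, _ = self._trunk.backward(cache_t, dh)
            return dx

        return h, backward

    # -- reporting / persistence --------------------------------------------

    def summary(self) -> str:
        cfg = self.config
        lines = [
            "Phenotype classifier (frozen judge)",
            "===================================",
            f"input            {cfg.size}x{cfg.size}x{cfg.channels}",
            f"hidden layers    {cfg.hidden} (embedding dim {cfg.embed_dim})",
            f"classes          {cfg.n_classes}",
            f"epochs           {cfg.epochs}",
            f"held-out top-1   {self.heldout_top1:.3f}",
        ]
        return "\n".join(lines)

    def save(self, path) -> None:
        meta = {
            "kind": "phenotype_classifier",
            "config": {
                "size": self.config.size,
                "channels": self.config.channels,
                "n_classes": self.config.n_classes,
                "hidden": list(self.config.hidden),
                "epochs": self.config.epochs,
                "batch_size": self.config.batch_size,
                "lr": self.config.lr,
                "val_fraction": self.config.val_fraction,
                "occlude_prob": self.config.occlude_prob,
                "occlude_size": self.config.occlude_size,
                "occlude_fill": self.config.occlude_fill,
                "seed": self.config.seed,
            },
            "heldout_top1": self.heldout_top1,
        }
        save_params(path, self.params, meta)

    @classmethod
    def load(cls, path) -> "ClassifierFit":
        params, header = load_params(path)
        if header.get("kind") != "phenotype_classifier":
            raise ValueError("checkpoint is not a phenotype classifier")
        raw = dict(header["config"])
        raw["hidden"] = tuple(raw["hidden"])
        cfg = ClassifierConfig(**raw)
        return cls(config=cfg, params=params, heldout_top1=header.get("heldout_top1", float("nan")))
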