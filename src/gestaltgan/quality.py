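"""Fail-case quality control for generated images.

A generated image with no recognizable face is a fail-case.  The detector
is a small binary face/not-face scorer trained on rendered faces against
patch-shuffled and noise negatives; its confidence plays the role of a face
detector's score, and an image fails when the confidence drops below a
threshold (default 0.999, with a calibration helper that picks the
threshold from a target false-reject rate on held-out real renders).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._rng import substream
from .faces import LabeledImage
from .nn import MLP, Adam, binary_cross_entropy_logits, save_params, load_params, sigmoid


@dataclass
class ScorerConfig:
    size: int = 64
    channels: int = 1
    hidden: tuple = (64, 32)
    epochs: int = 8
    batch_size: int = 64
    lr: float = 1e-3
    patch: int = 8  # block size for shuffled-patch negatives
    noise_aug_max: float = 0.15  # noise added to both classes during training
    blur_aug_max: float = 1.5  # max Gaussian blur sigma (structure-preserving)
    score_size: int = 16  # images are block-averaged to this size before scoring


def _flatten(images, size, channels):
    arrs = []
    for im in images:
        px = im.pixels if isinstance(im, LabeledImage) else np.asarray(im, dtype=float)
        arrs.append(px.reshape(-1))
    x = np.stack(arrs)
    if x.shape[1] != size * size * channels:
        raise ValueError("input size mismatch for the face scorer")
    return x


def _pool(x: np.ndarray, size: int, channels: int, score_size: int) -> np.ndarray:
    """Block-average flattened images down to the scoring resolution.

    Scoring at a coarse grid makes the detector structural by construction:
    pixel-level texture — where synthetic and generated images differ most —
    is averaged away before the network ever sees it.
    """
    if score_size >= size:
        return x
    f = size // score_size
    im = x.reshape(-1, score_size, f, score_size, f, channels)
    return im.mean(axis=(2, 4)).reshape(len(x), -1)


def shuffle_patches(pixels: np.ndarray, patch: int, rng: np.random.Generator) -> np.ndarray:
    """Permute non-overlapping patch x patch blocks (a face-free negative)."""
    S, _, C = pixels.shape
    k = S // patch
    blocks = pixels[: k * patch, : k * patch].reshape(k, patch, k, patch, C)
    blocks = blocks.transpose(0, 2, 1, 3, 4).reshape(k * k, patch, patch, C)
    perm = rng.permutation(k * k)
    out = blocks[perm].reshape(k, k, patch, patch, C).transpose(0, 2, 1, 3, 4)
    return out.reshape(k * patch, k * patch, C)


class FaceScorer:
    """Binary face-confidence scorer (frozen after training)."""

    def __init__(self, config: ScorerConfig, params: dict):
        self.config = config
        self._net = MLP([config.score_size**2 * config.channels, *config.hidden, 1],
                        name="scorer")
        self._net.params = params
        self.params = params

    def confidence(self, images) -> np.ndarray:
        """Face confidence in [0, 1] per image (deterministic)."""
        single = isinstance(images, (LabeledImage, np.ndarray)) and not (
            isinstance(images, np.ndarray) and images.ndim == 4)
        batch = [images] if single else list(images)
        x = _flatten(batch, self.config.size, self.config.channels)
        x = _pool(x, self.config.size, self.config.channels, self.config.score_size)
        s = sigmoid(self._net(x)[:, 0])
        return s[0] if single else s

    def save(self, path):
        meta = {"kind": "face_scorer", "config": {
            "size": self.config.size, "channels": self.config.channels,
            "hidden": list(self.config.hidden), "epochs": self.config.epochs,
            "batch_size": self.config.batch_size, "lr": self.config.lr,
            "patch": self.config.patch, "noise_aug_max": self.config.noise_aug_max,
            "blur_aug_max": self.config.blur_aug_max,
            "score_size": self.config.score_size}}
        save_params(path, self.params, meta)

    @classmethod
    def load(cls, path):
        params, header = load_params(path)
        if header.get("kind") != "face_scorer":
            raise ValueError("checkpoint is not a face scorer")
        raw = dict(header["config"])
        raw["hidden"] = tuple(raw["hidden"])
        return cls(ScorerConfig(**raw), params)


def train_face_scorer(images, config: ScorerConfig | None = None, seed: int = 0) -> FaceScorer:
    """Train the scorer on rendered faces vs. shuffled-patch/noise negatives."""
    cfg = config or ScorerConfig()
    rng = substream(seed, "scorer-negatives")
    rng_order = substream(seed, "scorer-batches")
    pos = _flatten(images, cfg.size, cfg.channels)
    negs = []
    for im in images:
        px = im.pixels if isinstance(im, LabeledImage) else np.asarray(im, dtype=float)
        negs.append(shuffle_patches(px, cfg.patch, rng).reshape(-1))
    # add pure-noise negatives (uniform) for coverage far from the face manifold
    n_noise = max(len(images) // 4, 1)
    negs += [rng.random(pos.shape[1]) for _ in range(n_noise)]
    x = np.vstack([pos, np.stack(negs)])
    t = np.concatenate([np.ones(len(pos)), np.zeros(len(negs))])
    # structure-preserving degradations applied to BOTH classes, so that
    # neither noise level, blur nor blotchy texture carries label
    # information — only the presence of facial structure does
    from scipy.ndimage import gaussian_filter

    S, C = cfg.size, cfg.channels
    imgs = x.reshape(-1, S, S, C)
    out = np.empty_like(imgs)
    for i in range(len(imgs)):
        im = imgs[i]
        if cfg.blur_aug_max > 0:
            sigma = rng.uniform(0.0, cfg.blur_aug_max)
            if sigma > 0.05:
                im = np.stack([gaussian_filter(im[:, :, c], sigma) for c in range(C)], axis=2)
        if cfg.noise_aug_max > 0:
            amp = rng.uniform(0.0, cfg.noise_aug_max)
            noise = rng.standard_normal(im.shape)
            if rng.random() < 0.5:  # blotchy (spatially correlated) variant
                noise = np.stack([gaussian_filter(noise[:, :, c], 1.5) for c in range(C)],
                                 axis=2) * 4.0
            im = im + amp * noise
        out[i] = im
    x = np.clip(out.reshape(len(x), -1), 0.0, 1.0)
    x = _pool(x, cfg.size, cfg.channels, cfg.score_size)

    net = MLP([cfg.score_size**2 * cfg.channels, *cfg.hidden, 1], name="scorer",
              seed=int(substream(seed, "scorer-init").integers(2**31)))
    opt = Adam(lr=cfg.lr)
    for _ in range(cfg.epochs):
        order = rng_order.permutation(len(x))
        for start in range(0, len(x), cfg.batch_size):
            idx = order[start:start + cfg.batch_size]
            logits, cache = net.forward(x[idx])
            _, dlogits = binary_cross_entropy_logits(logits[:, 0], t[idx])
            _, grads = net.backward(cache, dlogits[:, None])
            opt.step(net.params, grads)
    return FaceScorer(cfg, net.params)


@dataclass
class QCReport:
    """Per-image confidences and the fail partition at threshold tau."""

    scores: pd.DataFrame  # columns: class_id, confidence, fail
    tau: float
    fail_fraction: float
    per_class_fail_fraction: dict

    def passed(self) -> pd.DataFrame:
        return self.scores[~self.scores["fail"]]


def fail_case_filter(images, scorer: FaceScorer, tau: float = 0.999,
                     class_ids=None) -> QCReport:
    """Partition images into pass/fail by the confidence threshold rule.

    An image is a fail-case iff its face confidence is strictly below
    ``tau``.
    """
    if not 0.0 <= tau <= 1.0:
        raise ValueError("tau must lie in [0, 1]")
    images = list(images)
    if class_ids is None:
        class_ids = [im.class_id if isinstance(im, LabeledImage) else -1 for im in images]
    conf = scorer.confidence(images)
    conf = np.atleast_1d(conf)
    df = pd.DataFrame({"class_id": np.asarray(class_ids, dtype=int),
                       "confidence": conf, "fail": conf < tau})
    per_class = {int(c): float(g["fail"].mean()) for c, g in df.groupby("class_id")}
    return QCReport(scores=df, tau=tau, fail_fraction=float(df["fail"].mean()),
                    per_class_fail_fraction=per_class)


def calibrate_tau(scorer: FaceScorer, heldout_images, target_false_reject: float = 0.01) -> float:
    """Pick tau so that at most the target fraction of real renders fails."""
    conf = np.sort(np.atleast_1d(scorer.confidence(list(heldout_images))))
    k = int(np.floor(target_false_reject * len(conf)))
    return float(conf[k])
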