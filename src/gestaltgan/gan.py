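"""Conditional GAN with a classifier-rank auxiliary loss.

The generator never sees pixels directly: a random draw z (standard normal)
is combined with a learned class embedding in a mapping network that
produces an intermediate latent w; the generator renders an image
deterministically from w.  The discriminator is a projection-conditional
network trained with the non-saturating logistic loss plus a gradient
penalty on real images.  The generator additionally pays an auxiliary
penalty whenever a frozen phenotype classifier does not rank the requested
class first:

    L_total = L_D(I) + alpha * GestaltRank(I, d)

The integer rank itself is not differentiable, so the optimized surrogate is
the frozen classifier's cross-entropy against the target class — zero
exactly when the classifier puts probability 1 on the class (rank 0) — while
the true integer rank is logged alongside in the training history.

Model/results split: :class:`GestaltGAN` holds the dataset, judge, sampler
and configuration; :meth:`GestaltGAN.fit` runs the seeded training loop and
returns a :class:`GANFit` with the trained networks, history and summary.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._rng import substream
from .classifier import ClassifierFit, ranked_from_scores, rank_of
from .faces import LabeledImage
from .nn import MLP, Adam, merge_grads, save_params, load_params, sigmoid, softplus
from .nn import softmax as _softmax
from .preprocess import SamplerWeights


@dataclass
class LatentVector:
    """A point in the input latent space Z or the mapped space W."""

    space: str  # "Z" | "W"
    values: np.ndarray
    class_id: int | None = None

    def __post_init__(self):
        if self.space not in ("Z", "W"):
            raise ValueError("space must be 'Z' or 'W'")
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise ValueError("latent values must be a vector")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("latent values must be finite")


@dataclass
class GANConfig:
    dz: int = 32
    dw: int = 32
    class_embed_dim: int = 8
    map_hidden: int = 64
    g_hidden: tuple = (256, 512)
    g_base: int = 64  # generator base resolution; < size enables bilinear upsampling
    d_hidden: tuple = (512, 128)
    alpha: float = 0.1  # weight of the classifier-rank surrogate
    size: int = 64
    channels: int = 1
    n_classes: int = 6
    steps: int = 1000
    batch_size: int = 64
    d_steps: int = 2  # discriminator updates per generator update
    lr_g: float = 1e-3
    lr_d: float = 1e-3
    adam_beta1: float = 0.5
    r1_gamma: float = 1.0
    r1_eps: float = 1e-2
    instance_noise: float = 0.1  # initial s.d., decayed linearly to the floor
    instance_noise_floor: float = 0.02  # keep matching the cohort pixel noise
    g_ema: float = 0.99  # weight EMA decay for the evaluation generator (0 disables)
    lr_decay: float = 1.0  # final learning-rate fraction (linear decay; 1 disables)
    fake_classes: str = "uniform"  # class draw for generated batches: uniform | sampler
    history_interval: int = 50
    rng_seed: int = 0

    def __post_init__(self):
        if self.alpha < 0:
            raise ValueError("alpha must be >= 0")
        if min(self.dz, self.dw) < 8:
            raise ValueError("latent dimensions must be >= 8")

    @property
    def image_dim(self) -> int:
        return self.size * self.size * self.channels


def _bilinear_matrix(n_out: int, n_in: int) -> np.ndarray:
    """1-D bilinear interpolation matrix (pixel-center aligned)."""
    U = np.zeros((n_out, n_in))
    scale = n_in / n_out
    for i in range(n_out):
        src = (i + 0.5) * scale - 0.5
        j0 = int(np.floor(src))
        frac = src - j0
        j0c = np.clip(j0, 0, n_in - 1)
        j1c = np.clip(j0 + 1, 0, n_in - 1)
        U[i, j0c] += 1.0 - frac
        U[i, j1c] += frac
    return U


class _Generator:
    """MLP rendering at a coarse base resolution, bilinearly upsampled.

    The fixed upsampling acts as a smoothness prior: the generator cannot
    express pixel-level speckle, only structure at the base-grid scale.
    """

    def __init__(self, cfg: GANConfig, seed: int):
        if cfg.size % cfg.g_base != 0:
            raise ValueError("g_base must divide the image size")
        self.cfg = cfg
        self.base_dim = cfg.g_base * cfg.g_base * cfg.channels
        self.net = MLP([cfg.dw, *cfg.g_hidden, self.base_dim], out_activation="sigmoid",
                       seed=seed, name="gen")
        self.params = self.net.params
        self._U = _bilinear_matrix(cfg.size, cfg.g_base)

    def _upsample(self, flat_base: np.ndarray) -> np.ndarray:
        cfg = self.cfg
        x = flat_base.reshape(-1, cfg.g_base, cfg.g_base, cfg.channels)
        t = np.einsum("oi,bijc->bojc", self._U, x)
        out = np.einsum("pj,bojc->bopc", self._U, t)
        return out.reshape(-1, cfg.image_dim)

    def _downsample_grad(self, dflat: np.ndarray) -> np.ndarray:
        cfg = self.cfg
        d = dflat.reshape(-1, cfg.size, cfg.size, cfg.channels)
        t = np.einsum("oi,bopc->bipc", self._U, d)
        out = np.einsum("pj,bipc->bijc", self._U, t)
        return out.reshape(-1, self.base_dim)

    def forward(self, w: np.ndarray):
        base, cache = self.net.forward(w)
        return self._upsample(base), cache

    def backward(self, cache, dflat: np.ndarray):
        return self.net.backward(cache, self._downsample_grad(dflat))

    def __call__(self, w: np.ndarray) -> np.ndarray:
        return self.forward(w)[0]


class _Discriminator:
    """Projection-conditional discriminator: logit = <v, h> + b + <e_y, h>."""

    def __init__(self, cfg: GANConfig, seed: int):
        rng = np.random.default_rng(seed)
        self.cfg = cfg
        self.body = MLP([cfg.image_dim, *cfg.d_hidden], out_activation="lrelu",
                        seed=int(rng.integers(2**31)), name="dbody")
        h = cfg.d_hidden[-1]
        self.params = dict(self.body.params)
        self.params["dhead.v"] = rng.normal(0.0, 1.0 / np.sqrt(h), size=h)
        self.params["dhead.b"] = np.zeros(1)
        self.params["dhead.emb"] = rng.normal(0.0, 1.0 / np.sqrt(h), size=(cfg.n_classes, h))
        self.body.params = self.params

    def forward(self, x: np.ndarray, y: np.ndarray):
        h, cache = self.body.forward(2.0 * x - 1.0)  # center pixels for conditioning
        e = self.params["dhead.emb"][y]
        logits = h @ self.params["dhead.v"] + self.params["dhead.b"][0] + (h * e).sum(axis=1)
        return logits, (cache, h, y)

    def backward(self, cache, dlogits: np.ndarray):
        body_cache, h, y = cache
        e = self.params["dhead.emb"][y]
        dh = dlogits[:, None] * (self.params["dhead.v"][None, :] + e)
        grads = {
            "dhead.v": h.T @ dlogits,
            "dhead.b": np.array([dlogits.sum()]),
            "dhead.emb": np.zeros_like(self.params["dhead.emb"]),
        }
        np.add.at(grads["dhead.emb"], y, dlogits[:, None] * h)
        dx, g_body = self.body.backward(body_cache, dh)
        grads.update(g_body)
        return 2.0 * dx, grads  # chain rule through the input centering


class _Mapping:
    """z + class embedding -> w."""

    def __init__(self, cfg: GANConfig, seed: int):
        rng = np.random.default_rng(seed)
        self.cfg = cfg
        self.net = MLP([cfg.dz + cfg.class_embed_dim, cfg.map_hidden, cfg.dw],
                       seed=int(rng.integers(2**31)), name="map")
        self.params = dict(self.net.params)
        self.params["map.cemb"] = rng.normal(
            0.0, 1.0, size=(cfg.n_classes, cfg.class_embed_dim))
        self.net.params = self.params

    def forward(self, z: np.ndarray, y: np.ndarray):
        e = self.params["map.cemb"][y]
        inp = np.concatenate([z, e], axis=1)
        w, cache = self.net.forward(inp)
        return w, (cache, y)

    def backward(self, cache, dw: np.ndarray):
        net_cache, y = cache
        dinp, grads = self.net.backward(net_cache, dw)
        demb = np.zeros_like(self.params["map.cemb"])
        np.add.at(demb, y, dinp[:, self.cfg.dz:])
        grads["map.cemb"] = demb
        return grads


def gestalt_loss(classifier: ClassifierFit, images: np.ndarray, target_classes: np.ndarray,
                 alpha: float):
    """Auxiliary conditioning penalty of the frozen judge.

    Returns ``(surrogate_loss, mean_integer_rank, dpixels)``: the optimized
    surrogate is ``alpha`` times the judge's cross-entropy against the
    target class (exactly 0 when ``alpha == 0``); the integer rank of the
    target in the ranked prediction is reported for monitoring.
    """
    if not classifier.frozen:
        raise ValueError("the judge classifier must be frozen during GAN training")
    x = np.atleast_2d(images.reshape(images.shape[0], -1) if images.ndim > 2 else images)
    y = np.asarray(target_classes, dtype=int)
    ce, dx, logits = classifier.loss_and_input_grad(x, y)
    proba = _softmax(logits)
    ranks = [rank_of(ranked_from_scores(p), t) for p, t in zip(proba, y)]
    if alpha == 0:
        return 0.0, float(np.mean(ranks)), np.zeros_like(x)
    return alpha * ce, float(np.mean(ranks)), alpha * dx


class GestaltGAN:
    """Conditional GAN model bound to a dataset, judge and sampler."""

    def __init__(self, images, labels, sampler: SamplerWeights,
                 config: GANConfig | None = None, classifier: ClassifierFit | None = None):
        self.config = config or GANConfig()
        cfg = self.config
        if isinstance(images, np.ndarray):
            x = images.reshape(images.shape[0], -1).astype(float)
        else:
            x = np.stack([im.pixels.reshape(-1) if isinstance(im, LabeledImage)
                          else np.asarray(im, dtype=float).reshape(-1) for im in images])
        if x.shape[1] != cfg.image_dim:
            raise ValueError("dataset image size does not match the GAN configuration")
        self.x = x
        self.y = np.asarray(labels, dtype=int)
        self.sampler = sampler
        self.classifier = classifier
        if cfg.alpha > 0 and classifier is None:
            raise ValueError("alpha > 0 requires a frozen judge classifier")
        if classifier is not None and not classifier.frozen:
            raise ValueError("the judge classifier must be frozen")
        present = set(np.unique(self.y).tolist())
        covered = set(int(c) for c in sampler.classes)
        if present - covered:
            raise ValueError(f"sampler does not cover classes {sorted(present - covered)}")

    def _draw_fake_classes(self, rng: np.random.Generator, n: int) -> np.ndarray:
        """Class labels for generated batches.

        "uniform" refines every class equally often; "sampler" mirrors the
        (boosted) real-data exposure instead.
        """
        if self.config.fake_classes == "uniform":
            classes = np.asarray(sorted(self.sampler.class_probabilities), dtype=int)
            return classes[rng.integers(0, len(classes), size=n)]
        return self.sampler.draw_classes(rng, n)

    def fit(self, seed: int | None = None) -> "GANFit":
        cfg = self.config
        seed = cfg.rng_seed if seed is None else seed
        rng_sampler = substream(seed, "gan-sampler")
        rng_z = substream(seed, "gan-z")
        rng_init = substream(seed, "gan-init")
        rng_aug = substream(seed, "gan-aug")

        mapping = _Mapping(cfg, int(rng_init.integers(2**31)))
        gen = _Generator(cfg, int(rng_init.integers(2**31)))
        disc = _Discriminator(cfg, int(rng_init.integers(2**31)))

        params_g = {**mapping.params, **gen.params}
        mapping.params = params_g
        mapping.net.params = params_g
        gen.params = params_g
        gen.net.params = params_g
        opt_g = Adam(lr=cfg.lr_g, beta1=cfg.adam_beta1)
        opt_d = Adam(lr=cfg.lr_d, beta1=cfg.adam_beta1)
        ema = {k: v.copy() for k, v in params_g.items()} if cfg.g_ema > 0 else None

        history = []
        B = cfg.batch_size
        for step in range(cfg.steps):
            noise_sd = max(cfg.instance_noise * max(0.0, 1.0 - 2.0 * step / max(cfg.steps, 1)),
                           cfg.instance_noise_floor)
            frac = step / max(cfg.steps - 1, 1)
            decay = 1.0 - (1.0 - cfg.lr_decay) * frac
            opt_g.lr = cfg.lr_g * decay
            opt_d.lr = cfg.lr_d * decay

            # ---- discriminator update(s)
            for _ in range(cfg.d_steps):
                idx = self.sampler.draw(rng_sampler, B)
                x_real = self.x[idx]
                y_real = self.y[idx]
                z = rng_z.standard_normal((B, cfg.dz))
                y_fake = self._draw_fake_classes(rng_sampler, B)
                w, _ = mapping.forward(z, y_fake)
                x_fake, _ = gen.forward(w)
                if noise_sd > 0:
                    x_real = x_real + rng_aug.normal(0.0, noise_sd, x_real.shape)
                    x_fake = x_fake + rng_aug.normal(0.0, noise_sd, x_fake.shape)

                l_real, c_real = disc.forward(x_real, y_real)
                l_fake, c_fake = disc.forward(x_fake, y_fake)
                d_loss = float(np.mean(softplus(-l_real)) + np.mean(softplus(l_fake)))
                dl_real = -sigmoid(-l_real) / B
                dl_fake = sigmoid(l_fake) / B

                grads_d = []
                if cfg.r1_gamma > 0:
                    # finite-difference directional estimate of the R1 penalty
                    u = rng_aug.standard_normal(x_real.shape)
                    l_pert, c_pert = disc.forward(x_real + cfg.r1_eps * u, y_real)
                    diff = (l_pert - l_real) / cfg.r1_eps
                    d_loss += float(0.5 * cfg.r1_gamma * np.mean(diff**2))
                    dl_pert = cfg.r1_gamma * diff / (cfg.r1_eps * B)
                    dl_real = dl_real - dl_pert
                    _, g_pert = disc.backward(c_pert, dl_pert)
                    grads_d.append(g_pert)
                _, g_real = disc.backward(c_real, dl_real)
                _, g_fake = disc.backward(c_fake, dl_fake)
                grads_d += [g_real, g_fake]
                opt_d.step(disc.params, merge_grads(*grads_d))

            # ---- generator update
            z = rng_z.standard_normal((B, cfg.dz))
            y_g = self._draw_fake_classes(rng_sampler, B)
            w, cache_m = mapping.forward(z, y_g)
            x_g, cache_g = gen.forward(w)
            x_g_in = x_g
            if noise_sd > 0:
                x_g_in = x_g + rng_aug.normal(0.0, noise_sd, x_g.shape)
            l_g, c_g = disc.forward(x_g_in, y_g)
            g_adv = float(np.mean(softplus(-l_g)))
            dl_g = -sigmoid(-l_g) / B
            dx_adv, _ = disc.backward(c_g, dl_g)

            if self.classifier is not None:
                surrogate, mean_rank, dx_cls = gestalt_loss(
                    self.classifier, x_g, y_g, cfg.alpha)
                top1 = float(np.mean(
                    np.argmax(self.classifier.logits(x_g.reshape(
                        -1, cfg.size, cfg.size, cfg.channels)), axis=1) == y_g))
            else:
                surrogate, mean_rank, top1 = 0.0, float("nan"), float("nan")
                dx_cls = 0.0
            dx_total = dx_adv + dx_cls
            dw, g_gen = gen.backward(cache_g, dx_total)
            g_map = mapping.backward(cache_m, dw)
            opt_g.step(params_g, merge_grads(g_gen, g_map))
            if cfg.g_ema > 0:
                for k in ema:
                    ema[k] = cfg.g_ema * ema[k] + (1.0 - cfg.g_ema) * params_g[k]

            if not (np.isfinite(d_loss) and np.isfinite(g_adv) and np.isfinite(surrogate)):
                raise RuntimeError(
                    f"non-finite loss at step {step}: d={d_loss} g={g_adv} gestalt={surrogate}")

            if step % cfg.history_interval == 0 or step == cfg.steps - 1:
                history.append({
                    "step": step,
                    "d_loss": d_loss,
                    "g_adv": g_adv,
                    "gestalt_surrogate": surrogate,
                    "mean_rank": mean_rank,
                    "top1_generated": top1,
                })

        return GANFit(config=cfg, params_g=ema if ema is not None else params_g,
                      params_d=disc.params, history=pd.DataFrame(history))


@dataclass
class GANFit:
    """Trained conditional generator (results object)."""

    config: GANConfig
    params_g: dict
    params_d: dict
    history: pd.DataFrame = field(default_factory=pd.DataFrame)

    def __post_init__(self):
        cfg = self.config
        self._mapping = _Mapping(cfg, seed=0)
        self._mapping.params = self.params_g
        self._mapping.net.params = self.params_g
        self._gen = _Generator(cfg, seed=0)
        self._gen.params = self.params_g
        self._gen.net.params = self.params_g
        self._disc = _Discriminator(cfg, seed=0)
        self._disc.params = self.params_d
        self._disc.body.params = self.params_d

    # -- latent plumbing ----------------------------------------------------

    def map_latent(self, z: LatentVector | np.ndarray, class_id: int) -> LatentVector:
        """Map a Z draw plus class label into W (deterministic)."""
        if isinstance(z, LatentVector):
            if z.space != "Z":
                raise ValueError("map_latent expects a Z-space vector")
            zv = z.values
        else:
            zv = np.asarray(z, dtype=float)
        if not 0 <= int(class_id) < self.config.n_classes:
            raise ValueError(f"invalid class id {class_id}")
        w, _ = self._mapping.forward(zv[None, :], np.array([int(class_id)]))
        return LatentVector(space="W", values=w[0], class_id=int(class_id))

    def map_batch(self, z: np.ndarray, class_ids: np.ndarray) -> np.ndarray:
        w, _ = self._mapping.forward(np.asarray(z, dtype=float),
                                     np.asarray(class_ids, dtype=int))
        return w

    def generate(self, w: LatentVector) -> LabeledImage:
        """Deterministically render the image for a W vector."""
        if not isinstance(w, LatentVector) or w.space != "W":
            raise ValueError("generate expects a W-space LatentVector")
        flat = self._gen(w.values[None, :])[0]
        cfg = self.config
        return LabeledImage(
            pixels=flat.reshape(cfg.size, cfg.size, cfg.channels),
            class_id=-1 if w.class_id is None else w.class_id,
            source="generated",
        )

    def generate_batch(self, ws: np.ndarray) -> np.ndarray:
        """Images (n, S, S, C) for an array of W vectors."""
        cfg = self.config
        flat = self._gen(np.asarray(ws, dtype=float))
        return flat.reshape(-1, cfg.size, cfg.size, cfg.channels)

    def generate_class_batch(self, class_id: int, n: int, seed: int) -> np.ndarray:
        """Convenience: n seeded Z draws -> W -> images for one class."""
        rng = substream(seed, f"generate-class-{class_id}")
        z = rng.standard_normal((n, self.config.dz))
        w = self.map_batch(z, np.full(n, int(class_id)))
        return self.generate_batch(w)

    def generator_forward_backward(self, ws: np.ndarray):
        """Forward pass retaining the cache; returns (flat images, backward fn).

        ``backward(dflat)`` gives the gradient with respect to the W batch —
        the hook used by GAN inversion.
        """
        flat, cache = self._gen.forward(np.asarray(ws, dtype=float))

        def backward(dflat):
            dw, _ = self._gen.backward(cache, dflat)
            return dw

        return flat, backward

    # -- reporting / persistence --------------------------------------------

    def summary(self) -> str:
        cfg = self.config
        lines = [
            "Conditional GAN with classifier-rank auxiliary loss",
            "===================================================",
            f"latents          z in R^{cfg.dz} -> w in R^{cfg.dw}",
            f"classes          {cfg.n_classes} (embedding dim {cfg.class_embed_dim})",
            f"image            {cfg.size}x{cfg.size}x{cfg.channels}",
            f"alpha            {cfg.alpha}",
            f"steps            {cfg.steps} (batch {cfg.batch_size})",
        ]
        if len(self.history):
            last = self.history.iloc[-1]
            lines += [
                f"final D loss     {last['d_loss']:.3f}",
                f"final G adv      {last['g_adv']:.3f}",
                f"final mean rank  {last['mean_rank']:.3f}",
                f"final top-1      {last['top1_generated']:.3f}",
            ]
        return "\n".join(lines)

    def save(self, path) -> None:
        cfg = self.config
        meta = {
            "kind": "gestalt_gan",
            "config": {
                "dz": cfg.dz, "dw": cfg.dw, "class_embed_dim": cfg.class_embed_dim,
                "map_hidden": cfg.map_hidden, "g_hidden": list(cfg.g_hidden),
                "g_base": cfg.g_base,
                "d_hidden": list(cfg.d_hidden), "alpha": cfg.alpha, "size": cfg.size, "d_steps": cfg.d_steps,
                "channels": cfg.channels, "n_classes": cfg.n_classes, "steps": cfg.steps,
                "batch_size": cfg.batch_size, "lr_g": cfg.lr_g, "lr_d": cfg.lr_d,
                "adam_beta1": cfg.adam_beta1, "r1_gamma": cfg.r1_gamma,
                "r1_eps": cfg.r1_eps, "instance_noise": cfg.instance_noise,
                "instance_noise_floor": cfg.instance_noise_floor, "g_ema": cfg.g_ema,
                "lr_decay": cfg.lr_decay,
                "fake_classes": cfg.fake_classes,
                "history_interval": cfg.history_interval, "rng_seed": cfg.rng_seed,
            },
        }
        params = {f"G::{k}": v for k, v in self.params_g.items()}
        params.update({f"D::{k}": v for k, v in self.params_d.items()})
        save_params(path, params, meta)
        hist_path = str(path).replace(".npz", "") + "_history.csv"
        self.history.to_csv(hist_path, index=False)

    @classmethod
    def load(cls, path) -> "GANFit":
        params, header = load_params(path)
        if header.get("kind") != "gestalt_gan":
            raise ValueError("checkpoint is not a GAN fit")
        raw = dict(header["config"])
        raw["g_hidden"] = tuple(raw["g_hidden"])
        raw["d_hidden"] = tuple(raw["d_hidden"])
        cfg = GANConfig(**raw)
        pg = {k[3:]: v for k, v in params.items() if k.startswith("G::")}
        pd_ = {k[3:]: v for k, v in params.items() if k.startswith("D::")}
        import os
        hist_path = str(path).replace(".npz", "") + "_history.csv"
        hist = pd.read_csv(hist_path) if os.path.exists(hist_path) else pd.DataFrame()
        return cls(config=cfg, params_g=pg, params_d=pd_, history=hist)
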