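"""Latent-space averaging and feature-loss GAN inversion.

The latent-average portrait of a class is the image generated from the
component-wise mean of many class-conditional W vectors — a sharp
alternative to the blurry pixel-space average face.  For cohorts outside
the trained classes, every portrait is first inverted into W (gradient
descent on a frozen-classifier feature loss anchored by a pixel term) and
the inverted vectors are averaged instead.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from ._rng import substream
from .classifier import ClassifierFit
from .faces import LabeledImage
from .gan import GANFit, LatentVector


def sample_latents(fit: GANFit, class_id: int, n: int, seed: int) -> list[LatentVector]:
    """n seeded Z draws mapped through the class-conditional mapping network."""
    if n < 1:
        raise ValueError("n must be >= 1")
    if not 0 <= int(class_id) < fit.config.n_classes:
        raise ValueError(f"invalid class id {class_id}")
    rng = substream(seed, f"latents-class-{class_id}")
    z = rng.standard_normal((n, fit.config.dz))
    w = fit.map_batch(z, np.full(n, int(class_id)))
    return [LatentVector(space="W", values=row, class_id=int(class_id)) for row in w]


def latent_average(ws: list[LatentVector]) -> LatentVector:
    """Component-wise arithmetic mean of W vectors of one class."""
    if not ws:
        raise ValueError("cannot average an empty latent list")
    spaces = {w.space for w in ws}
    dims = {w.values.shape for w in ws}
    classes = {w.class_id for w in ws}
    if spaces != {"W"} or len(dims) != 1:
        raise ValueError("latent vectors must all be W-space with equal dimension")
    if len(classes) != 1:
        raise ValueError("cannot average latents of mixed classes")
    mean = np.mean(np.stack([w.values for w in ws]), axis=0)
    return LatentVector(space="W", values=mean, class_id=ws[0].class_id)


def image_average(images: list[LabeledImage]) -> LabeledImage:
    """Pixel-wise arithmetic mean of aligned same-size images."""
    if not images:
        raise ValueError("cannot average an empty image list")
    shapes = {im.pixels.shape for im in images}
    if len(shapes) != 1:
        raise ValueError("images must share the same size to be averaged")
    mean = np.mean(np.stack([im.pixels for im in images]), axis=0)
    classes = {im.class_id for im in images}
    return LabeledImage(pixels=mean, class_id=classes.pop() if len(classes) == 1 else -1,
                        source=images[0].source)


def average_portrait(fit: GANFit, class_id: int, n: int = 10_000, seed: int = 0) -> LabeledImage:
    """Latent-average portrait: generate from the mean of n class W draws."""
    ws = sample_latents(fit, class_id, n, seed)
    return fit.generate(latent_average(ws))


def sharpness(image: LabeledImage | np.ndarray) -> float:
    """Mean gradient magnitude of the luminance — higher is sharper."""
    gray = image.gray() if isinstance(image, LabeledImage) else np.asarray(image, dtype=float)
    if gray.ndim == 3:
        gray = gray.mean(axis=2)
    gy = ndimage.sobel(gray, axis=0)
    gx = ndimage.sobel(gray, axis=1)
    return float(np.mean(np.hypot(gx, gy)))


# ---------------------------------------------------------------------------
# inversion


@dataclass
class InversionConfig:
    iterations: int = 600
    step_size: float = 0.1
    lambda_pix: float = 0.1  # weight of the pixel MSE anchor
    init: str = "class_mean"  # or "supplied"
    init_samples: int = 1000  # W draws used to form the class-mean start
    rng_seed: int = 0
    tol: float = 1e-10  # stop when the loss improvement falls below this

    def __post_init__(self):
        if self.iterations < 1:
            raise ValueError("iterations must be >= 1")
        if self.lambda_pix < 0:
            raise ValueError("lambda_pix must be >= 0")


@dataclass
class InversionResult:
    w: LatentVector  # best iterate
    losses: np.ndarray  # loss trace (per iteration, evaluated loss)
    best_losses: np.ndarray  # running minimum (non-increasing by construction)
    final_loss: float
    reconstruction_mse: float
    converged: bool


def invert(
    fit: GANFit,
    classifier: ClassifierFit,
    target: LabeledImage,
    class_id: int,
    config: InversionConfig | None = None,
    w0: LatentVector | None = None,
) -> InversionResult:
    """Find w* minimizing cosine feature distance + pixel anchor to ``target``.

    Seeded Adam descent in W starting from the class-conditional mean (or a
    supplied w).  The best iterate (not the last) is returned, so the
    reported best-loss trace is non-increasing.
    """
    cfg = config or InversionConfig()
    if not classifier.frozen:
        raise ValueError("inversion requires the frozen judge classifier")
    t_flat = target.pixels.reshape(1, -1)
    t_emb = classifier.embed_batch(t_flat)[0]
    t_norm = np.linalg.norm(t_emb)
    if t_norm == 0:
        raise ValueError("target embedding is zero; feature loss undefined")

    if cfg.init == "supplied":
        if w0 is None:
            raise ValueError("init='supplied' requires w0")
        w = w0.values.copy()
    else:
        ws = sample_latents(fit, class_id, cfg.init_samples, cfg.rng_seed)
        w = latent_average(ws).values.copy()

    # Adam state on the single latent vector
    m = np.zeros_like(w)
    v = np.zeros_like(w)
    b1, b2, eps = 0.9, 0.999, 1e-8

    losses = []
    best_losses = []
    best_loss = np.inf
    best_w = w.copy()
    prev = np.inf
    converged = False
    for t in range(1, cfg.iterations + 1):
        img_flat, g_backward = fit.generator_forward_backward(w[None, :])
        emb, e_backward = classifier.embed_and_input_grad_fn(img_flat)
        f = emb[0]
        f_norm = np.linalg.norm(f)
        cos = float(f @ t_emb / (f_norm * t_norm + 1e-30))
        mse = float(np.mean((img_flat[0] - t_flat[0]) ** 2))
        loss = (1.0 - cos) + cfg.lambda_pix * mse
        if not np.isfinite(loss):
            raise RuntimeError(f"non-finite inversion loss at iteration {t}: trace={losses}")
        losses.append(loss)
        if loss < best_loss:
            best_loss, best_w = loss, w.copy()
        best_losses.append(best_loss)

        # gradients: d(1-cos)/df, then back through judge and generator
        dcos_df = t_emb / (f_norm * t_norm + 1e-30) - cos * f / (f_norm**2 + 1e-30)
        d_emb = -dcos_df[None, :]
        dx = e_backward(d_emb)
        dx = dx + cfg.lambda_pix * 2.0 * (img_flat - t_flat) / t_flat.size
        dw = g_backward(dx)[0]

        m = b1 * m + (1 - b1) * dw
        v = b2 * v + (1 - b2) * dw * dw
        w = w - cfg.step_size * (m / (1 - b1**t)) / (np.sqrt(v / (1 - b2**t)) + eps)

        if abs(prev - loss) < cfg.tol:
            converged = True
            break
        prev = loss

    img_best = fit.generator_forward_backward(best_w[None, :])[0][0]
    rec_mse = float(np.mean((img_best - t_flat[0]) ** 2))
    return InversionResult(
        w=LatentVector(space="W", values=best_w, class_id=int(class_id)),
        losses=np.asarray(losses),
        best_losses=np.asarray(best_losses),
        final_loss=best_loss,
        reconstruction_mse=rec_mse,
        converged=converged,
    )


@dataclass
class CohortAverageResult:
    image: LabeledImage
    w: LatentVector
    inversions: list
    n_skipped: int


def cohort_latent_average(
    fit: GANFit,
    classifier: ClassifierFit,
    images: list[LabeledImage],
    class_id: int,
    config: InversionConfig | None = None,
) -> CohortAverageResult:
    """Latent average for an arbitrary cohort via per-image GAN inversion.

    The conditioning class for the inversions must be supplied explicitly —
    for a cohort outside the trained classes it names the trained class used
    as the starting point.  Images whose inversion fails are skipped and
    counted in the result metadata.
    """
    if not images:
        raise ValueError("cohort must contain at least one image")
    results = []
    n_skipped = 0
    for im in images:
        try:
            results.append(invert(fit, classifier, im, class_id, config))
        except RuntimeError:
            n_skipped += 1
    if not results:
        raise RuntimeError("all cohort inversions failed")
    w_mean = latent_average([r.w for r in results])
    img = fit.generate(w_mean)
    img.class_id = images[0].class_id
    return CohortAverageResult(image=img, w=w_mean, inversions=results, n_skipped=n_skipped)
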