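"""Synthetic labeled cohorts of parametric faces.

Each "disorder" class is a mean-offset vector on the interpretable facial
geometry; one large reference class sits at the population mean and plays
the role of unaffected individuals.  Per-image parameter noise is truncated
Gaussian, pixel noise is added after rasterization, and optional grayscale /
downsampling degradations emulate historical low-quality clinical
photographs.  Ground-truth parameters and landmarks are recorded in the
manifest so that downstream stages can be scored against them.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from PIL import Image

from ._rng import substream
from .faces import (
    N_PARAMS,
    POPULATION_MEAN,
    DegenerateGeometryError,
    LabeledImage,
    LandmarkSet,
    PhenotypeSpec,
    render_face,
    _check_geometry,
    _layout,
)

#: reference class-offset matrix (K=5 affected classes x 8 parameters)
REFERENCE_OFFSETS = np.array([
    # iod   eye_h  f_w   f_h   nose  phil  mouth brow
    [+5.0,  0.0,  0.0,  0.0,  0.0,  0.0, -4.0,  0.0],  # class 0
    [-5.0,  0.0,  0.0,  0.0, +4.0,  0.0,  0.0,  0.0],  # class 1
    [ 0.0,  0.0, +5.0, +4.0,  0.0,  0.0,  0.0,  0.0],  # class 2
    [ 0.0, +4.0,  0.0,  0.0,  0.0, +4.0,  0.0,  0.0],  # class 3
    [ 0.0,  0.0,  0.0,  0.0, -4.0,  0.0, +5.0,  0.0],  # class 4
])

#: reference per-parameter noise s.d. (px); thin features get less spread
REFERENCE_PARAM_SD = np.array([1.0, 0.8, 1.0, 1.0, 0.8, 0.6, 1.0, 0.25])

MANIFEST_COLUMNS = (
    ["path", "class_id", "age_scale"]
    + [f"p{i}" for i in range(N_PARAMS)]
    + [c for i in range(5) for c in (f"lx{i}", f"ly{i}")]
    + ["source"]
)


@dataclass
class CohortConfig:
    """Study conditions for a synthetic cohort.

    The defaults are the reference configuration: 5 affected classes with
    geometry offsets of 4-5 px, 200 images per class, 2000 unaffected images
    at the population mean, 64x64 grayscale frames, parameter noise of about
    1 px and pixel noise of 0.02.
    """

    n_classes: int = 5
    class_offsets: np.ndarray = field(default_factory=lambda: REFERENCE_OFFSETS.copy())
    population_mean: np.ndarray = field(default_factory=lambda: POPULATION_MEAN.copy())
    param_sd: np.ndarray = field(default_factory=lambda: REFERENCE_PARAM_SD.copy())
    n_images: int = 200
    n_unaffected: int = 2000
    size: int = 64
    channels: int = 1
    pixel_noise_sd: float = 0.02
    grayscale_fraction: float = 0.0
    downsample_fraction: float = 0.0
    downsample_factor: int = 2
    age_scale_sd: float = 0.0
    rng_seed: int = 0

    def __post_init__(self):
        self.class_offsets = np.atleast_2d(np.asarray(self.class_offsets, dtype=float))
        self.population_mean = np.asarray(self.population_mean, dtype=float)
        self.param_sd = np.asarray(self.param_sd, dtype=float)
        if self.class_offsets.shape != (self.n_classes, N_PARAMS):
            raise ValueError("class_offsets must be (n_classes, P)")
        if self.population_mean.shape != (N_PARAMS,) or self.param_sd.shape != (N_PARAMS,):
            raise ValueError(f"population_mean and param_sd must have length {N_PARAMS}")
        if self.n_images < 0 or self.n_unaffected < 0:
            raise ValueError("image counts must be >= 0")
        if self.size < 32:
            raise ValueError("image size must be >= 32")
        for name in ("grayscale_fraction", "downsample_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.channels not in (1, 3):
            raise ValueError("channels must be 1 or 3")

    @property
    def unaffected_class(self) -> int:
        """Class id reserved for the unaffected reference class."""
        return self.n_classes

    def class_mean(self, class_id: int) -> np.ndarray:
        """True mean parameter vector of a class (unaffected = population mean)."""
        if class_id == self.unaffected_class:
            return self.population_mean.copy()
        return self.population_mean + self.class_offsets[class_id]

    @classmethod
    def from_yaml(cls, path) -> "CohortConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        for key in ("class_offsets", "population_mean", "param_sd"):
            if key in raw:
                raw[key] = np.asarray(raw[key], dtype=float)
        return cls(**raw)

    def to_yaml(self, path) -> None:
        raw = {
            "n_classes": self.n_classes,
            "class_offsets": self.class_offsets.tolist(),
            "population_mean": self.population_mean.tolist(),
            "param_sd": self.param_sd.tolist(),
            "n_images": self.n_images,
            "n_unaffected": self.n_unaffected,
            "size": self.size,
            "channels": self.channels,
            "pixel_noise_sd": self.pixel_noise_sd,
            "grayscale_fraction": self.grayscale_fraction,
            "downsample_fraction": self.downsample_fraction,
            "downsample_factor": self.downsample_factor,
            "age_scale_sd": self.age_scale_sd,
            "rng_seed": self.rng_seed,
        }
        with open(path, "w") as fh:
            yaml.safe_dump(raw, fh, sort_keys=False)


def _truncated_normal(rng: np.random.Generator, sd: np.ndarray, max_sd: float = 3.0) -> np.ndarray:
    """Independent Gaussian draw truncated at +/- max_sd standard deviations."""
    draw = rng.normal(0.0, sd)
    while np.any(np.abs(draw) > max_sd * sd):
        bad = np.abs(draw) > max_sd * sd
        draw[bad] = rng.normal(0.0, sd[bad])
    return draw


def sample_spec(config: CohortConfig, class_id: int, rng: np.random.Generator) -> PhenotypeSpec:
    """Draw one phenotype: class mean + truncated parameter noise.

    Resamples the noise if any parameter would become non-positive.
    """
    mean = config.class_mean(class_id)
    for _ in range(100):
        params = mean + _truncated_normal(rng, config.param_sd)
        if not np.all(params > 0):
            continue
        try:
            _check_geometry(_layout(params, 1.0, config.size), config.size)
        except DegenerateGeometryError:
            continue  # truncate the noise to geometrically valid faces
        break
    else:
        raise RuntimeError("could not draw a valid phenotype; check config geometry")
    age = 1.0
    if config.age_scale_sd > 0:
        age = float(np.exp(rng.normal(0.0, config.age_scale_sd)))
    return PhenotypeSpec(class_id=class_id, params=params, age_scale=age)


def degrade(image: LabeledImage, mode: str, factor: int = 2) -> LabeledImage:
    """Return a degraded copy: channel-collapsed grayscale or block-averaged
    downsample (re-upsampled to the original size).  Labels, truth and
    landmarks are passed through unchanged."""
    S = image.size
    if mode == "grayscale":
        pixels = image.gray()[:, :, None]
    elif mode == "downsample":
        if factor < 2:
            raise ValueError("downsample factor must be >= 2")
        if S % factor != 0:
            raise ValueError(f"factor {factor} does not divide image size {S}")
        px = image.pixels
        small = px.reshape(S // factor, factor, S // factor, factor, px.shape[2]).mean(axis=(1, 3))
        pixels = np.repeat(np.repeat(small, factor, axis=0), factor, axis=1)
    else:
        raise ValueError(f"unknown degradation mode {mode!r}")
    return LabeledImage(
        pixels=pixels,
        class_id=image.class_id,
        landmarks=image.landmarks,
        truth=image.truth,
        source=image.source,
    )


def _manifest_row(path: str, img: LabeledImage) -> dict:
    spec = img.truth
    row = {"path": path, "class_id": img.class_id, "age_scale": spec.age_scale if spec else 1.0}
    for i in range(N_PARAMS):
        row[f"p{i}"] = spec.params[i] if spec else np.nan
    pts = img.landmarks.points if img.landmarks is not None else np.full((5, 2), np.nan)
    for i in range(5):
        row[f"lx{i}"], row[f"ly{i}"] = pts[i]
    row["source"] = img.source
    return row


def sample_cohort(config: CohortConfig) -> tuple[list[LabeledImage], pd.DataFrame]:
    """Generate the full cohort and its manifest, reproducibly from the seed.

    Returns exactly ``n_images`` per affected class followed by
    ``n_unaffected`` unaffected images (class id = n_classes).
    """
    rng_params = substream(config.rng_seed, "cohort-params")
    rng_pixels = substream(config.rng_seed, "cohort-pixel-noise")
    rng_degrade = substream(config.rng_seed, "cohort-degrade")

    images: list[LabeledImage] = []
    rows: list[dict] = []
    counts = [config.n_images] * config.n_classes + [config.n_unaffected]
    for class_id, n in enumerate(counts):
        for i in range(n):
            spec = sample_spec(config, class_id, rng_params)
            img = render_face(
                spec,
                size=config.size,
                rng_seed=int(rng_pixels.integers(2**31)),
                channels=config.channels,
                pixel_noise_sd=config.pixel_noise_sd,
            )
            if config.grayscale_fraction > 0 and rng_degrade.random() < config.grayscale_fraction:
                img = degrade(img, "grayscale")
            if config.downsample_fraction > 0 and rng_degrade.random() < config.downsample_fraction:
                img = degrade(img, "downsample", config.downsample_factor)
            path = f"class{class_id}/img{i:05d}.png"
            images.append(img)
            rows.append(_manifest_row(path, img))
    manifest = pd.DataFrame(rows, columns=MANIFEST_COLUMNS)
    return images, manifest


# ---------------------------------------------------------------------------
# disk IO


def _to_uint8(pixels: np.ndarray) -> np.ndarray:
    return np.clip(np.round(pixels * 255.0), 0, 255).astype(np.uint8)


def save_image(img: LabeledImage, path) -> None:
    arr = _to_uint8(img.pixels)
    pil = Image.fromarray(arr[:, :, 0], mode="L") if arr.shape[2] == 1 else Image.fromarray(arr, mode="RGB")
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    # write via a buffer so the file content is a pure function of the pixels
    buf = io.BytesIO()
    pil.save(buf, format="PNG")
    Path(path).write_bytes(buf.getvalue())


def save_cohort(images: list[LabeledImage], manifest: pd.DataFrame, outdir) -> Path:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for img, path in zip(images, manifest["path"]):
        save_image(img, outdir / path)
    manifest_path = outdir / "manifest.csv"
    manifest.to_csv(manifest_path, index=False, float_format="%.6f")
    return manifest_path


def load_cohort(manifest_path) -> tuple[list[LabeledImage], pd.DataFrame]:
    """Load a cohort written by :func:`save_cohort` (or any directory of
    images with a manifest in the same schema)."""
    manifest_path = Path(manifest_path)
    root = manifest_path.parent
    manifest = pd.read_csv(manifest_path)
    images = []
    for _, row in manifest.iterrows():
        arr = np.asarray(Image.open(root / row["path"]), dtype=float) / 255.0
        pts = np.array([[row[f"lx{i}"], row[f"ly{i}"]] for i in range(5)])
        lm = LandmarkSet(pts) if np.all(np.isfinite(pts)) else None
        truth = None
        params = np.array([row[f"p{i}"] for i in range(N_PARAMS)])
        if np.all(np.isfinite(params)):
            truth = PhenotypeSpec(int(row["class_id"]), params, float(row["age_scale"]))
        images.append(LabeledImage(
            pixels=arr if arr.ndim == 3 else arr[:, :, None],
            class_id=int(row["class_id"]),
            landmarks=lm,
            truth=truth,
            source=str(row["source"]),
        ))
    return images, manifest
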