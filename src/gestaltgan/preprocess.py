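"""Face alignment and class-balanced sampling.

Alignment maps the five detected/ground-truth landmarks onto a canonical,
left-right symmetric template with a least-squares similarity transform
(rotation + isotropic scale + translation, no reflection), then resamples
the image bilinearly with edge replication.  The sampler draws training
images with replacement so that every class receives equal exposure, with a
configurable boost factor for the reference (unaffected) class.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from skimage.transform import SimilarityTransform, warp

from .faces import POPULATION_MEAN, LabeledImage, LandmarkSet, PhenotypeSpec, landmarks_for


@dataclass
class AlignmentTemplate:
    """Canonical landmark positions in an S x S output frame."""

    landmarks: LandmarkSet
    size: int

    def __post_init__(self):
        pts = self.landmarks.points
        mid = (self.size - 1) / 2.0
        # left-right symmetric pairs: eyes, mouth corners; nose on the midline
        pairs = [(0, 1), (3, 4)]
        for i, j in pairs:
            if not (abs((pts[i, 0] - mid) + (pts[j, 0] - mid)) < 1e-6
                    and abs(pts[i, 1] - pts[j, 1]) < 1e-6):
                raise ValueError("template landmarks must be symmetric about the vertical midline")
        if abs(pts[2, 0] - mid) > 1e-6:
            raise ValueError("template nose tip must lie on the vertical midline")


def default_template(size: int = 64) -> AlignmentTemplate:
    """Template at the population-mean geometry for the given frame size."""
    spec = PhenotypeSpec(class_id=0, params=POPULATION_MEAN * (size / 64.0))
    return AlignmentTemplate(landmarks=landmarks_for(spec, size), size=size)


@dataclass
class SimilarityFit:
    """Least-squares similarity transform and its landmark residual."""

    rotation: float  # radians, counter-clockwise in (x right, y down) coords
    scale: float
    translation: np.ndarray  # (2,)
    residual: float  # RMS landmark distance after transform
    matrix: np.ndarray  # 3x3 homogeneous

    def apply(self, points: np.ndarray) -> np.ndarray:
        pts = np.asarray(points, dtype=float)
        h = np.column_stack([pts, np.ones(len(pts))])
        return (h @ self.matrix.T)[:, :2]


def estimate_similarity(src: LandmarkSet, dst: AlignmentTemplate | LandmarkSet) -> SimilarityFit:
    """Closed-form (Umeyama) similarity fit from source landmarks to the template."""
    dst_lm = dst.landmarks if isinstance(dst, AlignmentTemplate) else dst
    s, d = src.points, dst_lm.points
    # degenerate when the source points are (near-)collinear
    centered = s - s.mean(axis=0)
    svals = np.linalg.svd(centered, compute_uv=False)
    if svals[-1] < 1e-8 * max(svals[0], 1.0):
        raise ValueError("source landmarks are collinear; similarity fit is degenerate")
    if hasattr(SimilarityTransform, "from_estimate"):
        tf = SimilarityTransform.from_estimate(s, d)
        if not tf:
            raise ValueError("similarity estimation failed")
    else:  # scikit-image < 0.26
        tf = SimilarityTransform()
        if not tf.estimate(s, d):
            raise ValueError("similarity estimation failed")
    res = float(np.sqrt(np.mean(np.sum((tf(s) - d) ** 2, axis=1))))
    return SimilarityFit(
        rotation=float(tf.rotation),
        scale=float(tf.scale),
        translation=np.asarray(tf.translation, dtype=float),
        residual=res,
        matrix=np.asarray(tf.params, dtype=float),
    )


def align_face(image: LabeledImage, template: AlignmentTemplate) -> LabeledImage:
    """Warp ``image`` so its landmarks match the template (bilinear, edge fill)."""
    if image.landmarks is None:
        raise ValueError(
            "image has no landmarks; supply a landmark sidecar for external images"
        )
    fit = estimate_similarity(image.landmarks, template)
    tf = SimilarityTransform(matrix=fit.matrix)
    out = np.stack(
        [
            warp(image.pixels[:, :, c], tf.inverse, output_shape=(template.size, template.size),
                 order=1, mode="edge", preserve_range=True)
            for c in range(image.channels)
        ],
        axis=2,
    )
    new_lm = LandmarkSet(fit.apply(image.landmarks.points))
    return LabeledImage(
        pixels=np.clip(out, 0.0, 1.0),
        class_id=image.class_id,
        landmarks=new_lm,
        truth=image.truth,
        source=image.source,
    )


@dataclass
class SamplerWeights:
    """Per-image sampling probabilities with equal class representation.

    Every non-boosted class has the same total probability; the boosted
    class (by default the unaffected reference class) receives
    ``boost_factor`` times that amount.  Within a class, images are
    equiprobable.
    """

    probabilities: np.ndarray  # (N,) per-image, sums to 1
    labels: np.ndarray  # (N,) class id per image
    class_probabilities: dict
    boost_class: int | None
    boost_factor: float

    def __post_init__(self):
        if abs(self.probabilities.sum() - 1.0) > 1e-9:
            raise ValueError("sampler probabilities must sum to 1")

    @property
    def classes(self) -> np.ndarray:
        return np.unique(self.labels)

    def draw(self, rng: np.random.Generator, n: int) -> np.ndarray:
        """Draw n image indices with replacement."""
        return rng.choice(len(self.probabilities), size=n, replace=True, p=self.probabilities)

    def draw_classes(self, rng: np.random.Generator, n: int) -> np.ndarray:
        """Draw n class labels from the class-level distribution."""
        classes = sorted(self.class_probabilities)
        p = np.array([self.class_probabilities[c] for c in classes])
        return np.asarray(classes)[rng.choice(len(classes), size=n, replace=True, p=p)]


def make_sampler(
    labels: np.ndarray | pd.Series,
    boost_class: int | None = None,
    boost_factor: float = 20.0,
) -> SamplerWeights:
    """Build oversampling weights: equal exposure per class, boosted reference.

    ``labels`` is the per-image class id column of a manifest.  With K
    non-boosted classes of total weight 1 each and a boosted class of weight
    ``boost_factor``, the boosted class is drawn ``boost_factor`` times as
    often as any single other class.
    """
    labels = np.asarray(labels, dtype=int)
    if labels.size == 0:
        raise ValueError("empty manifest")
    if boost_factor < 1.0:
        raise ValueError("boost_factor must be >= 1")
    classes, counts = np.unique(labels, return_counts=True)
    if boost_class is not None and boost_class not in classes:
        raise ValueError(f"boost class {boost_class} not present in the manifest")
    weights = {}
    for c, n in zip(classes, counts):
        if n == 0:
            raise ValueError(f"class {c} has no images")
        weights[int(c)] = boost_factor if c == boost_class else 1.0
    total = sum(weights.values())
    class_p = {c: w / total for c, w in weights.items()}
    probs = np.zeros(labels.size)
    for c, n in zip(classes, counts):
        probs[labels == c] = class_p[int(c)] / n
    return SamplerWeights(
        probabilities=probs,
        labels=labels,
        class_probabilities=class_p,
        boost_class=boost_class,
        boost_factor=boost_factor,
    )
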