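"""Parametric face model: rendering and geometry measurement.

A face is described by eight interpretable geometry parameters, all in pixel
units of the target frame:

======  ==================  =========================================
index   name                meaning
======  ==================  =========================================
0       interocular         distance between the two eye centers
1       eye_height          height of the eye line above face center
2       face_halfwidth      semi-axis of the face ellipse (x)
3       face_halfheight     semi-axis of the face ellipse (y)
4       nose_length         length of the vertical nose segment
5       philtrum            nose tip to mouth-line distance
6       mouth_width         distance between the mouth corners
7       brow_thickness      vertical thickness of the eyebrow bars
======  ==================  =========================================

Faces are rasterized with anti-aliased signed-distance coverage so that the
geometry can be measured back from the pixels to sub-pixel accuracy, either
directly (connected dark components and coverage integrals, for clean
renders) or by model-based registration (for arbitrary, e.g. generated,
images).  The five canonical landmarks (eye centers, nose tip, mouth
corners) follow deterministically from the parameters.

Coordinates are (x right, y down), 0-based, with real-valued sub-pixel
positions; pixel (i, j) is centered at x = j, y = i.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize
from skimage.measure import label, regionprops
from skimage.segmentation import expand_labels

PARAM_NAMES = (
    "interocular",
    "eye_height",
    "face_halfwidth",
    "face_halfheight",
    "nose_length",
    "philtrum",
    "mouth_width",
    "brow_thickness",
)
N_PARAMS = len(PARAM_NAMES)

#: population mean geometry for the reference 64x64 frame
POPULATION_MEAN = np.array([18.0, 5.0, 21.0, 24.0, 9.0, 5.0, 14.0, 2.0])

# fixed proportions, multiplied by age_scale
EYE_RADIUS = 2.4
NOSE_RADIUS = 0.9
MOUTH_RADIUS = 1.1
BROW_HALFLEN = 2.8
BROW_OFFSET = 5.5  # brow line above eye line
NOSE_TOP_OFFSET = 2.0  # nose starts this far above face center

# shades (grayscale); RGB variants share the same luminance ordering
GRAY_BG = 0.93
GRAY_SKIN = 0.72
GRAY_FEATURE = 0.12
RGB_BG = (0.93, 0.93, 0.95)
RGB_SKIN = (0.85, 0.70, 0.55)
RGB_FEATURE = (0.13, 0.10, 0.09)
_LUM = np.array([0.299, 0.587, 0.114])


class DegenerateGeometryError(ValueError):
    """A facial feature falls outside the face ellipse or the frame."""


class MeasurementError(RuntimeError):
    """Direct geometry measurement could not identify the facial features."""


@dataclass
class LandmarkSet:
    """Five canonical landmarks: eyes, nose tip, mouth corners (x, y)."""

    points: np.ndarray  # (5, 2), rows: left eye, right eye, nose tip, left mouth, right mouth

    def __post_init__(self):
        self.points = np.asarray(self.points, dtype=float)
        if self.points.shape != (5, 2):
            raise ValueError("landmarks must be a (5, 2) array")
        if not self.points[0, 0] < self.points[1, 0]:
            raise ValueError("left eye must be left of right eye (viewer coordinates)")

    @property
    def left_eye(self):
        return self.points[0]

    @property
    def right_eye(self):
        return self.points[1]

    @property
    def nose_tip(self):
        return self.points[2]

    @property
    def mouth_left(self):
        return self.points[3]

    @property
    def mouth_right(self):
        return self.points[4]

    def check_in_bounds(self, size: int) -> None:
        if np.any(self.points < -0.5) or np.any(self.points > size - 0.5):
            raise ValueError("landmark outside image bounds")


@dataclass
class PhenotypeSpec:
    """Class label plus ground-truth facial geometry."""

    class_id: int
    params: np.ndarray
    age_scale: float = 1.0

    def __post_init__(self):
        self.params = np.asarray(self.params, dtype=float)
        if self.params.shape != (N_PARAMS,):
            raise ValueError(f"params must have length {N_PARAMS}")
        if not np.all(self.params > 0):
            bad = PARAM_NAMES[int(np.argmin(self.params))]
            raise ValueError(f"geometry parameter {bad!r} must be strictly positive")
        if not self.age_scale > 0:
            raise ValueError("age_scale must be positive")
        self.class_id = int(self.class_id)


@dataclass
class LabeledImage:
    """Pixel array in [0, 1] plus label, landmarks and provenance."""

    pixels: np.ndarray  # (S, S, C), C in {1, 3}
    class_id: int
    landmarks: LandmarkSet | None = None
    truth: PhenotypeSpec | None = None
    source: str = "synthetic"  # synthetic | generated | external

    def __post_init__(self):
        self.pixels = np.asarray(self.pixels, dtype=float)
        if self.pixels.ndim == 2:
            self.pixels = self.pixels[:, :, None]
        if self.pixels.ndim != 3 or self.pixels.shape[2] not in (1, 3):
            raise ValueError("pixels must be (S, S, C) with C in {1, 3}")
        if self.pixels.min() < -1e-9 or self.pixels.max() > 1 + 1e-9:
            raise ValueError("pixel values must lie in [0, 1]")
        if self.source not in ("synthetic", "generated", "external"):
            raise ValueError(f"unknown source {self.source!r}")

    @property
    def size(self) -> int:
        return self.pixels.shape[0]

    @property
    def channels(self) -> int:
        return self.pixels.shape[2]

    def gray(self) -> np.ndarray:
        """Luminance image (S, S)."""
        if self.channels == 1:
            return self.pixels[:, :, 0]
        return self.pixels @ _LUM


# ---------------------------------------------------------------------------
# geometry layout


def _layout(params: np.ndarray, age_scale: float, size: int) -> dict:
    """Continuous feature geometry for a parameter vector (no validity checks)."""
    q = np.asarray(params, dtype=float) * age_scale
    cx = cy = (size - 1) / 2.0
    ey = cy - q[1]
    exl, exr = cx - q[0] / 2.0, cx + q[0] / 2.0
    nose_top = cy - NOSE_TOP_OFFSET * age_scale
    nose_tip = nose_top + q[4]
    mouth_y = nose_tip + q[5]
    return {
        "cx": cx,
        "cy": cy,
        "a": q[2],
        "b": q[3],
        "eye_l": (exl, ey),
        "eye_r": (exr, ey),
        "eye_r_px": EYE_RADIUS * age_scale,
        "brow_halflen": BROW_HALFLEN * age_scale,
        "brow_y": ey - BROW_OFFSET * age_scale,
        "brow_r": q[7] / 2.0,
        "nose_top": (cx, nose_top),
        "nose_tip": (cx, nose_tip),
        "nose_r": NOSE_RADIUS * age_scale,
        "mouth_l": (cx - q[6] / 2.0, mouth_y),
        "mouth_r": (cx + q[6] / 2.0, mouth_y),
        "mouth_r_px": MOUTH_RADIUS * age_scale,
    }


def landmarks_for(spec: PhenotypeSpec, size: int) -> LandmarkSet:
    g = _layout(spec.params, spec.age_scale, size)
    return LandmarkSet(np.array([g["eye_l"], g["eye_r"], g["nose_tip"], g["mouth_l"], g["mouth_r"]]))


def _check_geometry(g: dict, size: int) -> None:
    """Raise DegenerateGeometryError naming the offending parameter."""
    if g["a"] > size / 2.0 - 1.0:
        raise DegenerateGeometryError("face_halfwidth: face ellipse exceeds the frame")
    if g["b"] > size / 2.0 - 1.0:
        raise DegenerateGeometryError("face_halfheight: face ellipse exceeds the frame")

    def inside(x, y, margin, name):
        # scaled ellipse coordinate; > 1 means outside
        f = np.hypot((x - g["cx"]) / g["a"], (y - g["cy"]) / g["b"])
        # convert margin (px) to the local scaled units conservatively
        if f > 1.0 - margin / min(g["a"], g["b"]):
            raise DegenerateGeometryError(f"{name}: feature outside the face ellipse")

    r = g["eye_r_px"]
    for (ex, ey) in (g["eye_l"], g["eye_r"]):
        inside(ex + np.sign(ex - g["cx"]) * r, ey, 0.5, "interocular")
        inside(ex, ey - r, 0.5, "eye_height")
        bx = ex + np.sign(ex - g["cx"]) * (g["brow_halflen"] + g["brow_r"])
        inside(bx, g["brow_y"] - g["brow_r"], 0.5, "brow_thickness")
    inside(g["nose_tip"][0], g["nose_tip"][1] + g["nose_r"], 0.5, "nose_length")
    for (mx, my) in (g["mouth_l"], g["mouth_r"]):
        inside(mx + np.sign(mx - g["cx"]) * g["mouth_r_px"], my, 0.5, "mouth_width")
        inside(mx, my + g["mouth_r_px"], 0.5, "philtrum")


# ---------------------------------------------------------------------------
# signed distances and rasterization


def _grid(size: int):
    ys, xs = np.mgrid[0:size, 0:size].astype(float)
    return xs, ys


def _sdf_circle(xs, ys, cx, cy, r):
    return np.hypot(xs - cx, ys - cy) - r


def _sdf_capsule(xs, ys, ax, ay, bx, by, r):
    px, py = xs - ax, ys - ay
    vx, vy = bx - ax, by - ay
    vv = vx * vx + vy * vy
    t = 0.0 if vv == 0 else np.clip((px * vx + py * vy) / vv, 0.0, 1.0)
    return np.hypot(px - t * vx, py - t * vy) - r


def _sdf_ellipse(xs, ys, cx, cy, a, b):
    dx, dy = xs - cx, ys - cy
    f = np.hypot(dx / a, dy / b)
    # first-order distance estimate: (f - 1) / |grad f|
    gf = np.hypot(dx / a**2, dy / b**2)
    with np.errstate(invalid="ignore", divide="ignore"):
        d = np.where(gf > 0, (f - 1.0) * f / np.maximum(gf, 1e-12), -min(a, b))
    return d


def _coverage(sdf, aa=1.0):
    return np.clip(0.5 - sdf / aa, 0.0, 1.0)


def _render_raw(params, age_scale, size, channels=1, antialias=1.0, offset=(0.0, 0.0)):
    """Rasterize without validity checks; returns (S, S, C) floats in [0, 1]."""
    g = _layout(params, age_scale, size)
    ox, oy = offset
    xs, ys = _grid(size)
    xs = xs - ox
    ys = ys - oy

    face = _coverage(_sdf_ellipse(xs, ys, g["cx"], g["cy"], g["a"], g["b"]), antialias)
    feats = [
        _sdf_circle(xs, ys, *g["eye_l"], g["eye_r_px"]),
        _sdf_circle(xs, ys, *g["eye_r"], g["eye_r_px"]),
        _sdf_capsule(xs, ys, g["eye_l"][0] - g["brow_halflen"], g["brow_y"],
                     g["eye_l"][0] + g["brow_halflen"], g["brow_y"], g["brow_r"]),
        _sdf_capsule(xs, ys, g["eye_r"][0] - g["brow_halflen"], g["brow_y"],
                     g["eye_r"][0] + g["brow_halflen"], g["brow_y"], g["brow_r"]),
        _sdf_capsule(xs, ys, *g["nose_top"], *g["nose_tip"], g["nose_r"]),
        _sdf_capsule(xs, ys, *g["mouth_l"], *g["mouth_r"], g["mouth_r_px"]),
    ]
    feat_cov = np.zeros_like(face)
    for s in feats:
        c = _coverage(s, antialias)
        feat_cov = feat_cov + c - feat_cov * c  # union

    if channels == 1:
        img = GRAY_BG * (1 - face) + GRAY_SKIN * face
        img = img * (1 - feat_cov) + GRAY_FEATURE * feat_cov
        return img[:, :, None]
    bg, skin, feat = (np.array(c) for c in (RGB_BG, RGB_SKIN, RGB_FEATURE))
    img = bg[None, None, :] * (1 - face[:, :, None]) + skin[None, None, :] * face[:, :, None]
    img = img * (1 - feat_cov[:, :, None]) + feat[None, None, :] * feat_cov[:, :, None]
    return img


def render_face(
    spec: PhenotypeSpec,
    size: int = 64,
    rng_seed: int = 0,
    channels: int = 1,
    pixel_noise_sd: float = 0.0,
    antialias: float = 1.0,
) -> LabeledImage:
    """Render an anti-aliased face for ``spec``; deterministic given the seed.

    Pixel noise (emulating lighting/sensor variation) is i.i.d. Gaussian
    added after rasterization and clipped to [0, 1].
    """
    if size < 32:
        raise ValueError("image size must be >= 32")
    if channels not in (1, 3):
        raise ValueError("channels must be 1 or 3")
    g = _layout(spec.params, spec.age_scale, size)
    _check_geometry(g, size)
    img = _render_raw(spec.params, spec.age_scale, size, channels, antialias)
    if pixel_noise_sd > 0:
        rng = np.random.default_rng(rng_seed)
        img = img + rng.normal(0.0, pixel_noise_sd, size=img.shape)
    img = np.clip(img, 0.0, 1.0)
    lm = landmarks_for(spec, size)
    lm.check_in_bounds(size)
    return LabeledImage(pixels=img, class_id=spec.class_id, landmarks=lm, truth=spec, source="synthetic")


# ---------------------------------------------------------------------------
# measurement


def _capsule_len_from_area(area: float, r: float) -> float:
    """Segment length of a capsule (radius r) with the given covered area."""
    return max((area - np.pi * r * r) / (2.0 * r), 0.0)


def measure_geometry_direct(image: LabeledImage | np.ndarray, age_scale: float = 1.0) -> np.ndarray:
    """Measure the eight geometry parameters from a clean rendered face.

    Uses anti-aliased coverage integrals: feature positions are
    coverage-weighted centroids; widths/lengths are recovered from covered
    areas of the known capsule shapes; the face semi-axes come from second
    moments of the face mask (for a uniform ellipse, a = 2*sigma_x).
    Raises :class:`MeasurementError` when the six dark components cannot be
    identified (e.g. heavily blurred or degraded input).
    """
    if isinstance(image, LabeledImage):
        gray = image.gray()
    else:
        arr = np.asarray(image, dtype=float)
        gray = arr if arr.ndim == 2 else (arr[:, :, 0] if arr.shape[2] == 1 else arr @ _LUM)
    size = gray.shape[0]
    cx = cy = (size - 1) / 2.0

    # feature coverage relative to skin
    cov = np.clip((GRAY_SKIN - gray) / (GRAY_SKIN - GRAY_FEATURE), 0.0, 1.0)
    cov[cov < 0.15] = 0.0  # suppress rectified pixel-noise coverage
    lab = label(cov > 0.5)
    props = [p for p in regionprops(lab) if p.area >= 3]
    if len(props) < 6:
        raise MeasurementError(f"expected 6 dark facial components, found {len(props)}")
    props = sorted(props, key=lambda p: p.area, reverse=True)[:6]

    # claim the anti-aliasing ramp around each component without double-counting
    lab_x = expand_labels(lab, distance=2.0)
    comps = []
    xs, ys = _grid(size)
    for p in props:
        m = lab_x == p.label
        w = cov * m
        a = w.sum()
        comps.append({
            "x": (w * xs).sum() / a,
            "y": (w * ys).sum() / a,
            "area": a,
        })

    central = sorted((c for c in comps if abs(c["x"] - cx) < 3.0), key=lambda c: c["y"])
    lateral = [c for c in comps if abs(c["x"] - cx) >= 3.0]
    if len(central) != 2 or len(lateral) != 4:
        raise MeasurementError("could not separate nose/mouth from eyes/brows")
    nose, mouth = central
    left = sorted((c for c in lateral if c["x"] < cx), key=lambda c: c["y"])
    right = sorted((c for c in lateral if c["x"] > cx), key=lambda c: c["y"])
    if len(left) != 2 or len(right) != 2:
        raise MeasurementError("could not pair brows and eyes")
    (brow_l, eye_l), (brow_r, eye_r) = left, right

    interocular = eye_r["x"] - eye_l["x"]
    eye_height = cy - 0.5 * (eye_l["y"] + eye_r["y"])

    nose_len = _capsule_len_from_area(nose["area"], NOSE_RADIUS * age_scale)
    nose_tip_y = nose["y"] + nose_len / 2.0
    mouth_w = _capsule_len_from_area(mouth["area"], MOUTH_RADIUS * age_scale)
    philtrum = mouth["y"] - nose_tip_y

    # brow: horizontal capsule, length 2*halflen known, solve area for thickness
    L = 2.0 * BROW_HALFLEN * age_scale
    area_b = 0.5 * (brow_l["area"] + brow_r["area"])
    # area = L*t + (pi/4)*t^2
    t = (-L + np.sqrt(L * L + np.pi * area_b)) / (np.pi / 2.0)
    brow_thickness = t

    # face ellipse from second moments of the face mask (features count as face)
    face_cov = np.clip((GRAY_BG - gray) / (GRAY_BG - GRAY_SKIN), 0.0, 1.0)
    face_cov = np.maximum(face_cov, cov)
    face_cov[face_cov < 0.3] = 0.0  # suppress rectified background pixel noise
    tot = face_cov.sum()
    fx = (face_cov * xs).sum() / tot
    fy = (face_cov * ys).sum() / tot
    var_x = (face_cov * (xs - fx) ** 2).sum() / tot
    var_y = (face_cov * (ys - fy) ** 2).sum() / tot
    a_half = 2.0 * np.sqrt(var_x)
    b_half = 2.0 * np.sqrt(var_y)

    return np.array([
        interocular, eye_height, a_half, b_half, nose_len, philtrum, mouth_w, brow_thickness,
    ]) / age_scale


def measure_geometry(
    image: LabeledImage | np.ndarray,
    init: np.ndarray | None = None,
    refine: bool = True,
    fit_photometry: bool = True,
    maxiter: int = 6,
) -> np.ndarray:
    """Measure geometry by model-based registration.

    Fits the eight parameters (plus a small translational nuisance offset) by
    minimizing the mean squared difference between a clean re-render and the
    luminance of ``image`` (Powell search).  With ``fit_photometry`` the
    model is affinely matched in intensity first, making the measurement
    robust to global brightness/contrast shifts in generated images.  A fast
    direct measurement seeds the search when it succeeds; otherwise several
    starts (population mean plus short-nose and long-nose variants) guard
    against the nose/mouth registration local minimum, and the start with
    the lowest residual wins.
    """
    if isinstance(image, LabeledImage):
        gray = image.gray()
    else:
        arr = np.asarray(image, dtype=float)
        gray = arr if arr.ndim == 2 else (arr[:, :, 0] if arr.shape[2] == 1 else arr @ _LUM)
    size = gray.shape[0]

    inits = []
    if init is not None:
        inits.append(np.asarray(init, dtype=float))
    else:
        try:
            inits.append(measure_geometry_direct(gray))
        except MeasurementError:
            pass
        # multi-start guards: the vertical nose/mouth arrangement admits a
        # local minimum where a long nose swallows a high mouth line
        short_nose = POPULATION_MEAN.copy()
        short_nose[4] -= 4.0
        short_nose[5] -= 1.0
        long_nose = POPULATION_MEAN.copy()
        long_nose[4] += 4.0
        inits += [POPULATION_MEAN.copy(), short_nose, long_nose]
    if not refine:
        return inits[0]

    lo = np.maximum(POPULATION_MEAN - np.array([10, 6, 9, 9, 7, 4, 9, 1.6]), 0.3)
    hi = POPULATION_MEAN + np.array([10, 7, 8, 7, 8, 6, 10, 2.5])
    bounds = list(zip(lo, hi)) + [(-3.0, 3.0), (-3.0, 3.0)]

    def objective(x):
        model = _render_raw(x[:8], 1.0, size, channels=1, offset=(x[8], x[9]))[:, :, 0]
        if fit_photometry:
            m = model.ravel()
            t = gray.ravel()
            mc = m - m.mean()
            denom = (mc * mc).sum()
            a = ((t - t.mean()) * mc).sum() / denom if denom > 0 else 1.0
            b = t.mean() - a * m.mean()
            model = a * model + b
        return float(np.mean((model - gray) ** 2))

    best = None
    for start in inits:
        x0 = np.concatenate([np.clip(start, lo, hi), [0.0, 0.0]])
        res = minimize(objective, x0, method="Powell", bounds=bounds,
                       options={"maxiter": maxiter, "xtol": 1e-3, "ftol": 1e-7})
        if best is None or res.fun < best.fun:
            best = res
    return np.asarray(best.x[:8], dtype=float)
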