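"""Alignment and sampler tests."""

import numpy as np
import pytest

from gestaltgan import (
    LandmarkSet,
    PhenotypeSpec,
    POPULATION_MEAN,
    align_face,
    default_template,
    estimate_similarity,
    make_sampler,
    render_face,
)
from gestaltgan._rng import substream
from gestaltgan.faces import LabeledImage


def _rotate_points(points, angle, center):
    c, s = np.cos(angle), np.sin(angle)
    R = np.array([[c, -s], [s, c]])
    return (points - center) @ R.T + center


def test_template_is_symmetric():
    t = default_template(64)
    pts = t.landmarks.points
    mid = (64 - 1) / 2
    assert abs((pts[0, 0] - mid) + (pts[1, 0] - mid)) < 1e-9
    assert abs(pts[2, 0] - mid) < 1e-9


def test_identity_fit():
    t = default_template(64)
    fit = estimate_similarity(t.landmarks, t)
    assert abs(fit.rotation) < 1e-9
    assert abs(fit.scale - 1) < 1e-9
    assert fit.residual < 1e-9


def test_rotation_recovered_exactly():
    t = default_template(64)
    center = np.array([31.5, 31.5])
    rotated = _rotate_points(t.landmarks.points, np.deg2rad(10), center)
    fit = estimate_similarity(LandmarkSet(rotated), t)
    assert abs(fit.rotation - np.deg2rad(-10)) < 1e-6
    assert abs(fit.scale - 1) < 1e-6


def test_similarity_recovery_under_jitter():
    """Monte-Carlo: random similarity + 0.5 px landmark jitter is recovered."""
    t = default_template(64)
    rng = substream(3, "jitter")
    rot_err, scale_err = [], []
    for _ in range(100):
        angle = rng.uniform(-0.3, 0.3)
        scale = rng.uniform(0.8, 1.2)
        shift = rng.uniform(-4, 4, size=2)
        pts = scale * _rotate_points(t.landmarks.points, angle, np.array([31.5, 31.5]))
        pts = pts + shift + rng.normal(0, 0.5, size=pts.shape)
        fit = estimate_similarity(LandmarkSet(pts), t)
        rot_err.append(fit.rotation + angle)  # inverse transform rotates back
        scale_err.append(fit.scale * scale - 1.0)
    assert np.abs(np.mean(rot_err)) < 3 * np.std(rot_err) / 10 + 0.01
    assert np.abs(np.mean(scale_err)) < 3 * np.std(scale_err) / 10 + 0.01
    assert np.std(rot_err) < 0.1 and np.std(scale_err) < 0.1


def test_collinear_landmarks_rejected():
    t = default_template(64)
    pts = np.column_stack([np.linspace(10, 50, 5), np.linspace(10, 50, 5) * 0 + 20])
    with pytest.raises(ValueError, match="collinear"):
        estimate_similarity(LandmarkSet(pts), t)


def test_align_already_aligned_is_identity():
    img = render_face(PhenotypeSpec(0, POPULATION_MEAN), 64)
    t = default_template(64)
    # template equals this face's own landmarks
    from gestaltgan import AlignmentTemplate
    t_self = AlignmentTemplate(landmarks=img.landmarks, size=64)
    out = align_face(img, t_self)
    assert np.max(np.abs(out.pixels - img.pixels)) < 1e-6


def test_align_undoes_known_shift():
    img = render_face(PhenotypeSpec(0, POPULATION_MEAN), 64)
    shifted_pixels = np.roll(img.pixels, 3, axis=1)  # shift right by 3 px
    shifted = LabeledImage(
        pixels=shifted_pixels, class_id=0,
        landmarks=LandmarkSet(img.landmarks.points + np.array([3.0, 0.0])),
        truth=img.truth)
    from gestaltgan import AlignmentTemplate
    t_self = AlignmentTemplate(landmarks=img.landmarks, size=64)
    out = align_face(shifted, t_self)
    core = (slice(8, 56), slice(8, 56))
    assert np.max(np.abs(out.pixels[core] - img.pixels[core])) < 0.05


def test_alignment_levels_the_eyes():
    """After alignment both eye centers share the same height."""
    img = render_face(PhenotypeSpec(0, POPULATION_MEAN), 64)
    angle = np.deg2rad(8)
    rotated_lm = _rotate_points(img.landmarks.points, angle, np.array([31.5, 31.5]))
    from skimage.transform import rotate
    rot_pixels = np.clip(rotate(img.pixels[:, :, 0], np.rad2deg(angle), order=1,
                                mode="edge"), 0, 1)[:, :, None]
    rotated = LabeledImage(pixels=rot_pixels, class_id=0, landmarks=LandmarkSet(rotated_lm))
    out = align_face(rotated, default_template(64))
    assert abs(out.landmarks.left_eye[1] - out.landmarks.right_eye[1]) < 1.0


def test_align_requires_landmarks():
    img = LabeledImage(pixels=np.full((64, 64, 1), 0.5), class_id=0)
    with pytest.raises(ValueError, match="landmark"):
        align_face(img, default_template(64))


def test_alignment_is_idempotent():
    img = render_face(PhenotypeSpec(1, POPULATION_MEAN + 1.0), 64)
    t = default_template(64)
    once = align_face(img, t)
    fit = estimate_similarity(once.landmarks, t)
    assert abs(fit.rotation) < 1e-6
    assert abs(fit.scale - 1) < 1e-3
    assert np.all(np.abs(fit.translation) < 0.1)


# ---------------------------------------------------------------------------
# sampler


def test_equal_representation_two_classes():
    labels = np.array([0] * 10 + [1] * 90)
    s = make_sampler(labels)
    assert abs(s.class_probabilities[0] - 0.5) < 1e-12
    assert abs(s.class_probabilities[1] - 0.5) < 1e-12
    np.testing.assert_allclose(np.unique(s.probabilities[labels == 0]), 0.05)
    np.testing.assert_allclose(np.unique(s.probabilities[labels == 1]), 0.5 / 90)


def test_boosted_reference_class_probability():
    """20 disorder classes + a 20x boosted unaffected class: the reference
    class receives half of all draws."""
    labels = np.concatenate([np.full(5, c) for c in range(21)])
    s = make_sampler(labels, boost_class=20, boost_factor=20.0)
    assert abs(s.class_probabilities[20] - 0.5) < 1e-12
    assert abs(s.class_probabilities[0] - 0.025) < 1e-12
    assert abs(s.probabilities.sum() - 1.0) < 1e-9


def test_empirical_frequencies_match_targets():
    labels = np.array([0] * 10 + [1] * 40 + [2] * 50)
    s = make_sampler(labels, boost_class=2, boost_factor=3.0)
    rng = substream(0, "sampler-mc")
    draws = s.labels[s.draw(rng, 100_000)]
    for c, p in s.class_probabilities.items():
        freq = np.mean(draws == c)
        se = np.sqrt(p * (1 - p) / 100_000)
        assert abs(freq - p) < 3 * se + 1e-4


def test_sampler_invariant_to_duplication():
    labels = np.array([0] * 10 + [1] * 20)
    dup = np.array([0] * 20 + [1] * 20)  # class 0 duplicated
    a = make_sampler(labels)
    b = make_sampler(dup)
    assert a.class_probabilities == b.class_probabilities


def test_sampler_errors():
    with pytest.raises(ValueError, match="empty"):
        make_sampler(np.array([]))
    with pytest.raises(ValueError, match="not present"):
        make_sampler(np.array([0, 0, 1, 1]), boost_class=9)
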