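"""Latent/image averaging oracles and inversion mechanics."""

import numpy as np
import pytest

from gestaltgan import (
    InversionConfig,
    LabeledImage,
    LatentVector,
    average_portrait,
    cohort_latent_average,
    image_average,
    invert,
    latent_average,
    sample_latents,
    sharpness,
)


def _w(values, class_id=0):
    return LatentVector(space="W", values=np.asarray(values, dtype=float),
                        class_id=class_id)


def test_latent_average_identities(rng):
    w = rng.normal(size=8)
    avg = latent_average([_w(w)] * 5)
    np.testing.assert_allclose(avg.values, w, atol=1e-15)
    sym = latent_average([_w(w), _w(-w)])
    np.testing.assert_allclose(sym.values, 0.0, atol=1e-15)


def test_latent_average_matches_component_loop(rng):
    """Oracle equivalence on 100 random stacks."""
    for _ in range(100):
        n, d = int(rng.integers(1, 12)), int(rng.integers(2, 10))
        vecs = rng.normal(size=(n, d))
        avg = latent_average([_w(v) for v in vecs])
        brute = np.array([sum(vecs[i][j] for i in range(n)) / n for j in range(d)])
        np.testing.assert_allclose(avg.values, brute, atol=1e-12)


def test_latent_average_validation(rng):
    with pytest.raises(ValueError):
        latent_average([])
    with pytest.raises(ValueError, match="mixed"):
        latent_average([_w(np.ones(4), 0), _w(np.ones(4), 1)])
    with pytest.raises(ValueError):
        latent_average([_w(np.ones(4)), _w(np.ones(5))])
    with pytest.raises(ValueError):
        latent_average([LatentVector(space="Z", values=np.ones(4))])


def test_image_average_identities():
    a = LabeledImage(pixels=np.zeros((8, 8, 1)), class_id=0)
    b = LabeledImage(pixels=np.ones((8, 8, 1)), class_id=0)
    avg = image_average([a, b])
    np.testing.assert_allclose(avg.pixels, 0.5)
    same = image_average([b, b, b])
    np.testing.assert_allclose(same.pixels, 1.0)


def test_image_average_matches_pixel_loop(rng):
    imgs = [LabeledImage(pixels=rng.random((6, 6, 1)), class_id=0) for _ in range(7)]
    avg = image_average(imgs)
    brute = np.zeros((6, 6, 1))
    for im in imgs:
        brute += im.pixels
    brute /= len(imgs)
    np.testing.assert_allclose(avg.pixels, brute, atol=1e-12)
    with pytest.raises(ValueError, match="size"):
        image_average(imgs + [LabeledImage(pixels=np.zeros((5, 5, 1)), class_id=0)])
    with pytest.raises(ValueError):
        image_average([])


def test_sample_latents_seeded_and_counted(tiny_fit):
    a = sample_latents(tiny_fit, 0, 5, seed=3)
    b = sample_latents(tiny_fit, 0, 5, seed=3)
    assert len(a) == 5
    for wa, wb in zip(a, b):
        np.testing.assert_array_equal(wa.values, wb.values)
    c = sample_latents(tiny_fit, 0, 5, seed=4)
    assert any(not np.array_equal(wa.values, wc.values) for wa, wc in zip(a, c))
    with pytest.raises(ValueError):
        sample_latents(tiny_fit, 0, 0, seed=1)
    with pytest.raises(ValueError):
        sample_latents(tiny_fit, 9, 1, seed=1)


def test_average_portrait_of_one_is_that_image(tiny_fit):
    (w,) = sample_latents(tiny_fit, 1, 1, seed=5)
    port = average_portrait(tiny_fit, 1, n=1, seed=5)
    np.testing.assert_array_equal(port.pixels, tiny_fit.generate(w).pixels)


def test_average_portrait_permutation_invariant(tiny_fit):
    ws = sample_latents(tiny_fit, 0, 20, seed=8)
    a = tiny_fit.generate(latent_average(ws))
    b = tiny_fit.generate(latent_average(ws[::-1]))
    np.testing.assert_allclose(a.pixels, b.pixels, atol=1e-12)


def test_sharpness_orders_blur():
    rng = np.random.default_rng(0)
    sharp = np.zeros((32, 32))
    sharp[8:24, 8:24] = 1.0
    from scipy.ndimage import gaussian_filter
    blurred = gaussian_filter(sharp, 3.0)
    assert sharpness(sharp) > sharpness(blurred)


def test_inversion_initialized_at_optimum_stays_there(tiny_fit, tiny_setup):
    clf = tiny_setup[-1]
    w0 = tiny_fit.map_latent(np.full(8, 0.4), 0)
    target = tiny_fit.generate(w0)
    res = invert(tiny_fit, clf, target, 0,
                 InversionConfig(iterations=5, init="supplied"), w0=w0)
    assert res.reconstruction_mse < 1e-12


def test_inversion_beats_class_mean_initialization(tiny_fit, tiny_setup):
    clf = tiny_setup[-1]
    w0 = tiny_fit.map_latent(np.full(8, 1.2), 0)
    target = tiny_fit.generate(w0)
    cfg = InversionConfig(iterations=150, init="class_mean", init_samples=100,
                          rng_seed=0)
    mean_w = latent_average(sample_latents(tiny_fit, 0, 100, seed=0))
    mse_init = float(np.mean((tiny_fit.generate(mean_w).pixels - target.pixels) ** 2))
    res = invert(tiny_fit, clf, target, 0, cfg)
    assert res.reconstruction_mse < mse_init
    # best-so-far trace is non-increasing by construction
    assert np.all(np.diff(res.best_losses) <= 1e-15)


def test_inversion_requires_frozen_judge(tiny_fit, tiny_setup):
    clf = tiny_setup[-1]
    target = tiny_fit.generate(tiny_fit.map_latent(np.zeros(8), 0))
    clf.frozen = False
    try:
        with pytest.raises(ValueError, match="frozen"):
            invert(tiny_fit, clf, target, 0)
    finally:
        clf.frozen = True


def test_cohort_latent_average_single_image(tiny_fit, tiny_setup):
    clf = tiny_setup[-1]
    w0 = tiny_fit.map_latent(np.full(8, -0.7), 1)
    target = tiny_fit.generate(w0)
    res = cohort_latent_average(tiny_fit, clf, [target], 1,
                                InversionConfig(iterations=150, rng_seed=1))
    assert res.n_skipped == 0
    mse = float(np.mean((res.image.pixels - target.pixels) ** 2))
    assert mse < 5e-3


def test_cohort_latent_average_linearity(tiny_fit, tiny_setup):
    """Two self-generated targets: the cohort average is close to the image
    generated from the mean of the two recovered latents."""
    clf = tiny_setup[-1]
    w1 = tiny_fit.map_latent(np.full(8, 0.5), 1)
    w2 = tiny_fit.map_latent(np.full(8, -0.5), 1)
    targets = [tiny_fit.generate(w) for w in (w1, w2)]
    res = cohort_latent_average(tiny_fit, clf, targets, 1,
                                InversionConfig(iterations=200, rng_seed=2))
    ref = tiny_fit.generate(latent_average([w1, w2]))
    mse = float(np.mean((res.image.pixels - ref.pixels) ** 2))
    assert mse < 5e-3
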