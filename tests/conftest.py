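import numpy as np
import pytest

from gestaltgan import (
    ClassifierConfig,
    CohortConfig,
    GANConfig,
    GestaltGAN,
    PhenotypeClassifier,
    POPULATION_MEAN,
    REFERENCE_OFFSETS,
    REFERENCE_PARAM_SD,
    make_sampler,
    sample_cohort,
)


@pytest.fixture(scope="session")
def small_cohort():
    """A fast, reduced cohort for API-level tests (not accuracy claims)."""
    cfg = CohortConfig(n_images=30, n_unaffected=60, rng_seed=7)
    images, manifest = sample_cohort(cfg)
    return cfg, images, manifest


@pytest.fixture(scope="session")
def reference_cohort():
    """The reference study cohort: K=5 classes x 200 images + 2000 unaffected."""
    cfg = CohortConfig(rng_seed=0)
    images, manifest = sample_cohort(cfg)
    return cfg, images, manifest


@pytest.fixture(scope="session")
def judge(reference_cohort):
    """Frozen phenotype classifier trained on the reference cohort."""
    cfg, images, manifest = reference_cohort
    labels = manifest["class_id"].to_numpy()
    fit = PhenotypeClassifier(images, labels, ClassifierConfig(seed=0)).fit(seed=0)
    return fit


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20_24)


@pytest.fixture(scope="session")
def tiny_setup():
    """Tiny 32x32 two-class cohort + judge + GAN config for unit tests."""
    cfg = CohortConfig(
        n_classes=2,
        class_offsets=REFERENCE_OFFSETS[:2],
        n_images=15,
        n_unaffected=15,
        rng_seed=3,
    )
    images, manifest = sample_cohort(cfg)
    labels = manifest["class_id"].to_numpy()
    x = np.stack([im.pixels for im in images])
    clf = PhenotypeClassifier(
        x, labels,
        ClassifierConfig(size=64, n_classes=3, hidden=(16, 8), epochs=3)).fit(seed=0)
    sampler = make_sampler(labels, boost_class=2, boost_factor=4.0)
    gan_cfg = GANConfig(size=64, g_base=32, dz=8, dw=8, class_embed_dim=4,
                        map_hidden=16, g_hidden=(32, 64), d_hidden=(64, 32),
                        n_classes=3, steps=40, batch_size=8, history_interval=10)
    return x, labels, sampler, gan_cfg, clf


@pytest.fixture(scope="session")
def tiny_fit(tiny_setup):
    x, labels, sampler, gan_cfg, clf = tiny_setup
    return GestaltGAN(x, labels, sampler, gan_cfg, classifier=clf).fit(seed=5)
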