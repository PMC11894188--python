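# Methods

This note documents the models, algorithms and numerical choices behind
`gestaltgan`: a desk-scale, CPU-only toolkit that reproduces the complete
workflow of class-conditional portrait synthesis for facial dysmorphology —
cohort preparation, boosted oversampling, conditional GAN training with a
classifier-rank auxiliary loss, latent-average portraits, feature-loss GAN
inversion, fail-case quality control, and the survey evaluation statistics —
on a fully synthetic cohort whose ground truth is known.

## The synthetic cohort

Real dysmorphology databases cannot be shipped with a toolkit, so the unit
of study here is a *parametric face*: an anti-aliased rendering controlled
by eight interpretable geometry parameters in pixel units (inter-ocular
distance, eye height, face half-width and half-height, nose length,
philtrum length, mouth width, brow thickness). A "disorder" class is a mean
offset vector on these parameters — the synthetic analogue of a facial
gestalt — and the unaffected reference class sits at the population mean.

The reference configuration uses K = 5 disorder classes with offsets of
4–5 px on one or two parameters each (comfortably above the ~1 px noise
floor, mirroring the clinical situation where a gestalt is a subtle but
consistent shift), 200 images per class, 2000 unaffected images, and a
64×64 grayscale frame. Monochrome rendering reflects the large historical
black-and-white fraction of clinical photo archives and keeps single-CPU
training budgets realistic; RGB rendering and grayscale/downsampling
degradations are available for emulating mixed-quality archives.

Per-image parameter noise is independent Gaussian (s.d. ≈ 1 px; thin
features less), truncated at ±3 s.d. and resampled whenever a draw would
produce non-positive parameters or geometrically invalid faces (a feature
escaping the face ellipse) — i.e. the phenotype distribution is the
truncation of the Gaussian to renderable faces. Rejection rates at the
reference configuration are ≤ ~2 % per class, so class means are shifted
by well under 0.05 px. Pixel noise (s.d. 0.02, clipped to [0, 1]) is added
after rasterization as a stand-in for lighting and sensor variation.

What the generator deliberately does *not* emulate: pose, illumination
models, texture, hair, age progression, occlusion, or any photorealism.
Passing tests therefore demonstrate that the *pipeline machinery* —
conditioning, rank loss, averaging, inversion, statistics — behaves as
designed on a controlled morphometric family; they say nothing about
photorealistic face synthesis per se.

### Geometry measurement

Two routines recover parameters from pixels:

- **Direct measurement** (`measure_geometry_direct`): thresholds the dark
  features, claims each component's anti-aliasing ramp by nearest-label
  expansion, and converts coverage-weighted centroids and areas back to
  positions and capsule lengths; the face semi-axes come from second
  moments of the face mask (for a uniform ellipse a = 2σₓ). Sub-0.2 px
  bias on clean renders; raises a `MeasurementError` on images it cannot
  parse (heavy blur, merged features).
- **Model-based registration** (`measure_geometry`): Powell minimization of
  the mean squared difference between a clean re-render and the target
  luminance, with two translational nuisance parameters and an inner
  closed-form affine photometric match (robust to the brightness/contrast
  shifts of generated images). The search is multi-start — the direct
  estimate when available, plus population-mean, short-nose and long-nose
  starts — because the vertical nose/philtrum/mouth arrangement admits a
  local minimum in which a long nose swallows a high mouth line; the start
  with the lowest residual wins. Accuracy on clean renders is < 0.1 px.

## Preprocessing

Alignment maps the five canonical landmarks (eye centers, nose tip, mouth
corners) onto a left-right symmetric template with the closed-form
least-squares similarity transform (rotation + isotropic scale +
translation, no reflection; Umeyama solution via scikit-image), followed by
bilinear warping with edge replication. Synthetic images carry ground-truth
landmarks; external images require a landmark sidecar — no face detector is
bundled.

The training sampler draws images with replacement so that every class has
equal expected exposure, with the unaffected reference class boosted by a
configurable factor (default 20×). Within a class, images are equiprobable;
per-image probabilities sum to one by construction.

## The phenotype classifier (frozen judge)

A fully-connected network (4096 → 128 → 64 → K+1, leaky-ReLU, softmax
cross-entropy, Adam, 12 epochs) stands in for a large pre-trained
dysmorphology ensemble. Training uses random-erasing augmentation (a 16 px
square at a random position is filled with the skin shade, probability 0.5
per image): hiding a patch means no single facial cue suffices to identify
a class, so the judge's evidence — and hence the gradient of the rank loss
it later provides — is distributed over *all* of a class's geometry
rather than its single most discriminative feature. Its three downstream roles: ranked class
predictions (ties broken by ascending class id, making the ranking — and
hence the rank of any target class — deterministic), a 64-dimensional
penultimate embedding used as the inversion feature space, and top-k
accuracy for evaluating generated images. After `fit()` the classifier is
frozen; the GAN trainer refuses a judge whose `frozen` flag is cleared.

All networks in the toolkit are built on a compact numpy layer stack with
explicit forward/backward passes (`gestaltgan.nn`), gradient-checked
against finite differences in the test suite. Fully-connected nets are a
deliberate choice for 64×64 single-channel geometric faces: they train in
minutes on one CPU and meet every behavioural contract; translation
equivariance buys nothing on pre-aligned, centered renders.

## Conditional GAN

Structure follows the style-GAN convention: z ∈ R³² drawn from a standard
normal is concatenated with a learned 8-dimensional class embedding and
mapped by a 2-layer perceptron to the intermediate latent w ∈ R³²; the
generator renders an image deterministically from w (256 → 512 hidden
units, sigmoid output in [0, 1]). The discriminator is a
projection-conditional MLP (512 → 128) on centered pixels: its logit is
v·h + b + e_y·h with a per-class embedding e_y; it takes two update steps
per generator step, which at the boosted exposure roughly doubles how often
it sees each rare disorder class.

The total generator objective is

    L_total = L_D(I) + α · GestaltRank(I, d)

where L_D is the non-saturating logistic adversarial loss and the rank term
penalizes the frozen judge not putting the requested class d first. The
integer rank is a step function, so the optimized surrogate is the judge's
cross-entropy against d — zero exactly when the judge assigns probability 1
to d (rank 0) — scaled by α (default 0.1); the true integer rank is logged
alongside in the training history at every reporting interval. The rank
term touches only the generator update and only generated images; the
discriminator's own update is purely adversarial.

Stabilization, each of which proved necessary at this scale:

- **R1 penalty, finite-difference form.** The gradient penalty on real
  images is estimated as E_u[((D(x+εu) − D(x))/ε)²] with u standard normal
  and ε = 10⁻², an unbiased directional estimator of ‖∇ₓD‖² whose weight
  gradient needs only ordinary backprop through two evaluations (γ = 1).
- **Instance noise with a floor.** Real and generated images receive the
  same Gaussian noise, decaying from 0.1 to a permanent floor of 0.02 — the
  cohort's own pixel-noise scale. Without the floor the discriminator
  learns to detect the *absence* of sensor noise in generator output, and
  the deterministic generator responds with high-contrast speckle.
- **Generator weight EMA** (decay 0.99): the returned evaluation generator
  is the exponential moving average of the generator weights, which
  suppresses the oscillation inherent in adversarial optimization.
- **Uniform class draws for generated batches.** Real-image exposure keeps
  the boosted oversampling; the conditioning labels of *generated* batches
  are drawn uniformly so that every disorder class receives equal generator
  refinement. With boosted fake draws the reference class consumed ~80 % of
  generator updates and the disorder classes stayed visibly under-trained
  at desk budgets.

All randomness flows from a single run seed through named substreams
(sampler, z draws, initialization, augmentation), so training is exactly
reproducible; with α = 0 the trained weights are bit-identical to a build
with the rank term deleted. The default desk budget is 1000 generator
steps at batch 64 (≈ 10–12 minutes on one CPU core), Adam with β₁ = 0.5 and
learning rate 10⁻³ for both networks.

## Latent averages and inversion

The latent-average portrait of a class is G(mean of n class-conditional w
draws). The full-scale convention is n = 10 000 (the library default);
tests and the acceptance pipeline use n = 1000, which is equivalent for the
quantity being computed — the sample mean of w concentrates as O(1/√n), so
the portrait is already visually and metrically stable at n = 1000.
Pixel-space averages of aligned cohort images are computed for comparison;
sharpness is quantified as the mean Sobel gradient magnitude of the
luminance.

Inversion minimizes (1 − cos(f(G(w)), f(target))) + λ_pix·MSE(G(w), target)
over w by seeded Adam (600 iterations, step 0.1), where f is the frozen
judge's embedding. The pure feature loss is ill-posed for backgrounds and
global placement, hence the pixel anchor (λ_pix = 0.1, config-exposed).
Initialization is the mean of 1000 class-conditional w draws (or a supplied
w); the best iterate, not the last, is returned, which guarantees a
non-increasing best-loss trace. For cohorts outside the trained classes the
conditioning class used for initialization is a required, explicit argument
— which trained class to anchor on is a modelling judgement the caller must
make.

## Quality control and survey statistics

The fail-case detector is a small binary scorer trained on real renders
against patch-shuffled renders and uniform noise; a generated image fails
when its confidence falls below τ. To keep the decision structural rather
than textural, inputs are block-averaged to a 16×16 grid before scoring and
training applies structure-preserving degradations (blur, i.i.d. and
blotchy noise) identically to both classes, so texture statistics carry no
label information. The interface default τ = 0.999 mirrors the convention
of thresholding a face detector's confidence at 99.9 %, but because this
scorer is *not* a large pre-trained detector, `calibrate_tau` picks τ from
a target false-reject rate on held-out real renders (default 1 %), and the
reproduction pipeline uses the calibrated value. One caveat is inherent to
a narrowly-trained surrogate: generated images are slightly
out-of-distribution, so at the strict calibrated τ a large fraction can be
flagged even when faces are plainly present (confidences 0.9–0.99); the
pipeline therefore reports both the threshold-rule fail rate and the
fraction of generated images whose face confidence exceeds 0.5.

Survey answers (three categories: spotting the original among generated
portraits, re-identifying the training individual, diagnosing the disorder)
are filtered — skipped and timed-out answers removed, with exact count
conservation — then tested: the two above-chance questions with a one-sided
exact binomial test against the chance level 1/n_options (the hypotheses
are directional; the two-sided variant, summing all outcomes no more likely
than the observed one, is available), and diagnostic accuracy on real vs.
generated portraits with Pearson's chi-square on the 2×2 table, df = 1, no
continuity correction by default (switchable).

## Known limitations

- The adversarial game at desk scale leaves residual rendered noise in the
  disorder-class outputs; the unaffected class, with 20× exposure, is
  visibly cleaner. Latent averages of disorder classes recover controlled
  geometry to ≲ 1 px at the default configuration (verified over several
  training seeds), with the vertically-stretched class (raised eyes plus
  lengthened philtrum) the most sensitive to the training budget.
- The unaffected class's latent average renders the facial features
  faithfully but washes out the low-contrast skin ellipse, so its face
  half-axes are not reliably measurable; geometry-recovery claims are made
  for the disorder classes.
- The judge is a surrogate trained on the same synthetic family it later
  evaluates; its absolute accuracies do not transfer to any real ensemble.
- The survey statistics operate on answer records; the toolkit does not
  model per-participant effects or re-run any human study.
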