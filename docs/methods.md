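# Methods

This note documents the models, the numerical choices, and what the
synthetic phantoms do and do not show about real histology data.

## Problem setting

Given spatially registered pairs of an RGB H&E tile `x` and a single-channel
IF tile `y` for a marker with a morphological signature (e.g. panCK labeling
tumor epithelium), the translator learns `G(x) ≈ y`. Generalization across
patients depends on how representative the training samples are of the
cohort, so the package also implements the feature-guided selection of
training samples, and the SSIM-based protocol for comparing models on
held-out samples.

## Tissue phantoms (synthetic_data)

A phantom pair is rendered from a `PhantomSpec`:

- **Stroma**: pink eosin field (default RGB (0.91, 0.72, 0.83)) with a
  smooth Gaussian texture (σ = 3 px, amplitude 0.04).
- **Nuclei**: dark-violet disks (default RGB (0.36, 0.22, 0.54)), radius
  jittered ±30 % around `nucleus_radius`, centers Poisson-sampled at
  `nucleus_density` per px²; inside marker regions the density is
  multiplied by `marker_density_boost` (default 3), emulating the higher
  cellularity of tumor epithelium. A 0.6-px Gaussian antialiases edges.
- **Marker regions**: disks carrying IF signal. The IF channel is the
  region indicator smoothed with a σ = 2 px Gaussian (continuous boundaries,
  as in real staining) plus optional additive Gaussian noise (`noise_sd`,
  default 0.02), clipped to [0, 1].
- **Chromatic marker signature**: marker-region cytoplasm is tinted by
  `marker_tint` (default (−0.06, −0.04, +0.03)), the basophilic shift of
  epithelial cytoplasm relative to collagenous stroma. This matters for a
  structural reason: nucleus placement is stochastic, so density alone makes
  the marker region only a noisy correlate of the H&E appearance. With the
  deterministic tint, the noise-free H&E → IF mapping is a pure function of
  the H&E content — a property the translator tests rely on, since it
  guarantees a learnable target exists.
- **DAPI channel**: the same nuclei rendered as a smoothed indicator; this
  is the channel registration anchors on (hematoxylin ↔ DAPI), matching how
  paired H&E/IF data is registered in practice.

Cohorts assign samples to texture clusters (`TextureParams` per cluster) and
derive per-tile seeds from the cohort seed via `SeedSequence`, so any tile is
reproducible in isolation. `perturb_alignment` resamples the IF/DAPI members
through a planted forward affine (bilinear, zero fill) and records it, giving
registration tests an exact ground truth.

What the phantoms do **not** model: autofluorescence beyond additive noise,
tissue folds/tears, out-of-focus regions, stain batch variation beyond
global color casts, and the full texture richness of real PDAC tissue.
A translator that performs well here has demonstrated that the pipeline's
mechanics (training, adaptive weighting, evaluation) work; it says nothing
about the strength of morphology–marker association in any real dataset.

## Preprocessing

- `downscale`: block averaging (anti-aliased), floor dimensions.
- `nuclei_mask`: ITU-R 601 grayscale, Otsu threshold on a 256-bin histogram;
  H&E is complemented (nuclei dark), DAPI is not. Constant images raise a
  degenerate-input error.
- `register_pair`: SIFT keypoints/descriptors on the two nuclei masks
  (lightly smoothed, σ = 1, so the binary edges have gradients), capped at
  min(10 000, detected); cross-checked matching with a 0.8 Lowe ratio;
  affine fit by RANSAC (3 px inlier threshold, 2000 trials, seeded). The
  contract is the recovered transform, not the detector: the acceptance
  check is < 1 px median corner error over 20 random affines with up to
  20 px translation, 5° rotation and 3 % scale.
- `median_filter_if`: disk structuring element (default radius 5),
  reflect-padded edges.
- `normalize_if`: affine map to pre-clip mean 0.25 / std 0.125, clipped to
  [0, 1]. Idempotent only when nothing clips.
- `normalize_he`: Reinhard-style color transfer — each LAB channel affinely
  mapped to reference means/stds (pluggable `target_stats`). Chosen over
  stain-matrix deconvolution for robustness on arbitrary RGB inputs
  (including grayscale-as-RGB) while satisfying the fixed-point and
  color-cast-convergence contracts; a deconvolution-based normalizer can be
  slotted in through the same interface.
- `tile_pair`: 0-based, row-major, half-open windows; partial edge tiles
  dropped. Background pixel ⇔ all three 8-bit channels > 180 (strict);
  a tile is dropped together with its IF mate iff its H&E background
  fraction is strictly greater than 0.5 — the exactly-50 % tile is kept.
  IF content never triggers removal.

## VAE features (representation)

Encoder: three stride-2 3×3 conv blocks (8 → 16 → 32 filters, leaky ReLU)
and a dense head emitting (μ, log σ²) of the 16-dimensional diagonal
Gaussian posterior; decoder mirrors it with nearest-neighbor upsampling and
a sigmoid output. Loss = Gaussian negative log-likelihood with fixed unit
variance (½‖x − x̂‖² plus its (D/2)·ln 2π normalizer) + closed-form
KL(q ‖ N(0, I)), Adam (lr 1e-3), log-variances clipped to ±8 for stability.
Features are posterior means — deterministic, standard for downstream use.
Latent size 16 is the default; any of {2, 4, 8, 16, 32} is supported.

## Representative-sample selection

Signed features map to the simplex by row softmax (order-preserving,
strictly positive; a min-shift normalizer is available as `method="shift"`).
KL uses natural log; the base only rescales scores and never reorders the
selection. Subset distributions are arithmetic means of member rows. The
subset score is (|X|/|S|) · KL(P(A|S) ‖ P(A|X)): at equal divergence a
larger subset scores lower, so minimization prefers subsets contributing
many tiles. The greedy sequence adds, at each step, the sample whose union
with the current selection minimizes the score; ties break on the smaller
sample id. Each greedy step is verified against exhaustive enumeration over
that step's candidates in the tests (the greedy prefix is not guaranteed
globally optimal over all subsets of a given size).

## Translator

Generator: U-net with a full-resolution encoder block, three stride-2
levels (f, 2f, 4f, 8f filters), skip connections by concatenation, and a
linear 1-channel output head. The head is linear rather than sigmoid for an
optimization reason: with an L1 objective and mostly-dark IF targets, the
constant-magnitude sign gradient pushes background logits toward −∞ until a
sigmoid head saturates and training stalls; a linear head converges to the
conditional median, and inference clips into [0, 1].

Discriminator (adversarial mode): patch classifier on the concatenated
(H&E, IF) pair — three stride-2 conv blocks and a 1-channel logit map, one
logit per receptive patch. Internally both networks train on logits with
numerically stable BCE; the generator uses the non-saturating adversarial
term (maximize log D(x, G(x))). The `cgan_objective` helper reports the
textbook minimax objective on probabilities.

The L1 weight is adapted per batch: λ = base_λ · (fraction of batch pixels
strictly above the source-WSI mean IF intensity), base_λ = 100. Each tile
carries its own source-WSI mean (`wsi_means`); by default the mean over the
training IF tiles stands in, and batches mixing sources average their means.
Note a corner case that is correct by construction: a constant IF channel
has zero pixels strictly above its own mean, hence λ = 0 — the
stain-prevalence rule sees no stain.

Profiles: the full profile keeps lr 0.002, 500 epochs, batch 64, first
layer 128 filters. The desk preset (used throughout the test suite) is
64×64 tiles, batch 8, first layer 8 filters, ≤ 1200 optimization steps —
sized so that training completes in minutes on one CPU while the held-out
behaviour (loss decrease, SSIM above the shuffled-pair baseline) is
unambiguous. Mode comparisons match optimization steps, not epochs.

Augmentation applies geometric ops (flips, rotation ≤ 10°, scale ± 5 %,
translation ≤ 3 px) with identical parameters to both members of a pair;
blur and Gaussian/Poisson noise per image; hue/saturation jitter to the H&E
member only.

## Evaluation

SSIM: both images prefiltered with a σ = 3 Gaussian (suppresses
registration/instrumentation noise a translator cannot reproduce), then
stride-1 uniform 11×11 windows fully interior to the image, population
moments, stabilizers c1 = (0.01 L)², c2 = (0.03 L)² with data range L = 1.
The windowed implementation is held equal (1e-10) to a brute-force
sliding-window oracle in the tests. Gaussian-weighted windows are available
behind a flag.

Model comparison: scores pivot to a paired tiles × models matrix per
held-out sample subset. Two models → Wilcoxon signed-rank (all-zero
differences report p = 1); three or more → Friedman; on rejection at
α = 0.05, Nemenyi post-hoc: mean-rank differences scaled by
√(k(k+1)/(6n)) referred to the studentized range distribution (infinite
df). Shapiro–Wilk is reported per model but does not gate the nonparametric
route. Null calibration of the Friedman test (rejection rate ≈ α over 1000
exchangeable replicates) is asserted in the suite.

## Orchestration

`run_experiment` derives per-stage seeds by hashing the stage name with the
global seed, trains one translator per training-set composition, evaluates
each only on samples outside its composition, and runs the statistics
battery on subsets held out by every model. A composition covering all
samples is rejected (nothing would be held out). Runs write the resolved
config, the score table, and the comparison report.

## Known limitations

- The NumPy training core is single-process; the full-scale profile
  (256-px tiles, 128 filters, 500 epochs) is impractical on CPU and is
  provided as configuration, not as a tested path.
- Reinhard color transfer normalizes global color statistics only; it does
  not separate stain concentrations.
- The adversarial mode is exercised as a smoke-tested training path
  (discriminator neither collapses nor saturates; the weighted L1 component
  decreases); phantom-scale runs are too short for the adversarial term to
  demonstrably sharpen outputs.
- SSIM is sensitive to residual misregistration and noise; the σ = 3
  prefilter mitigates but does not remove this.
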