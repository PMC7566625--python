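# shiftlab

Virtual immunofluorescence (IF) staining from H&E histology. Routine
hematoxylin-and-eosin sections are cheap and ubiquitous; antibody-based IF
imaging of tumor markers such as pan-cytokeratin (panCK) is informative but
slow and expensive. When a marker's spatial distribution has a morphological
signature in H&E, an image-to-image translation model can estimate the IF
channel from the H&E image alone. `shiftlab` implements that pipeline
end-to-end for researchers in computational pathology:

- **Paired preprocessing** — nuclei-mask affine registration of H&E and IF
  whole-slide images (hematoxylin vs. DAPI, keypoint matching + RANSAC),
  disk median filtering, intensity normalization (IF rescaled to mean 0.25,
  std 0.125, clipped to [0, 1]), and background-filtered 256-px tiling
  (a tile is dropped when more than 50 % of its pixels have all three 8-bit
  RGB values above 180).
- **Representation** — a convolutional variational autoencoder maps each
  H&E tile to a 16-dimensional latent feature vector (posterior mean),
  giving a tiles × features table.
- **Representative-sample selection** — feature rows are softmax-normalized
  into distributions P(A|x_i) over the feature domain; a candidate subset S
  of the tile set X is scored by the size-weighted Kullback–Leibler
  divergence

      score(S) = (|X| / |S|) · KL( P(A|S) ‖ P(A|X) ),   P(A|S) = mean of member rows,

  and a greedy search builds the sample sequence X̂₁ ⊂ X̂₂ ⊂ … that keeps
  the training set maximally representative of the cohort.
- **Translation** — a conditional adversarial translator (U-net generator
  G, patch discriminator D) with objective

      G* = arg min_G max_D  L_cGAN(G, D) + λ · L_L1(G),

  where the L1 weight is adapted per batch to IF stain prevalence:
  λ = 100 · (fraction of batch pixels strictly above the source-WSI mean
  intensity). An `l1_only` mode drops the discriminator (the supervised
  pixel-loss baseline), plus paired augmentation, model ensembling
  (pixel-wise output averaging), and tile stitching.
- **Evaluation** — SSIM over 11-px sliding windows after a σ = 3 Gaussian
  prefilter of both images, Pearson r, and a paired model-comparison
  battery (Shapiro–Wilk reported; Wilcoxon signed-rank for two models;
  Friedman plus Nemenyi post-hoc for three or more; α = 0.05).

No patient data is required anywhere: `shiftlab.synthetic_data` generates
seeded H&E/IF tissue phantoms whose marker channel is a deterministic
function of the rendered morphology, multi-sample cohorts with planted
cluster structure, known affine misalignments, and feature tables with known
representativeness ordering. Networks run on a compact NumPy training core
(`shiftlab.nn`), so everything works on one CPU.

## Worked example

```python
import numpy as np
from shiftlab import synthetic_data as sd, translation as tr, evaluation as ev

# a cohort of paired 64-px H&E/IF phantom tiles from one sample
cohort = sd.CohortSpec(samples=[sd.SampleSpec("A", 240, "c")],
                       clusters={"c": sd.TextureParams()},
                       tile_size=64, seed=11)
tiles = dict(sd.generate_cohort(cohort))["A"]
train, test = tiles[:200], tiles[200:]

# supervised (L1-only) translator at the desk preset
cfg = tr.desk_config("l1_only", seed=0, max_steps=1200)
model = tr.train_translator([(p.he, p.if_chan) for p in train], cfg)
print(f"L1 {np.mean(model.history['l1'][:50]):.4f} -> "
      f"{np.mean(model.history['l1'][-50:]):.4f}")

scores = [ev.ssim(tr.translate_tile(model, p.he), p.if_chan) for p in test]
print(f"median held-out SSIM {np.median(scores):.3f}")
```

Output:

```
L1 0.2025 -> 0.0199
median held-out SSIM 0.979
```

The training L1 falls by an order of magnitude, and the virtual IF tiles of
held-out phantoms agree closely with the true marker channel (SSIM is 1.0
for identical images; ~0.98 here reflects residual blur at marker-region
boundaries).

A command-line interface covers the same workflow
(`shiftlab simulate | preprocess | featurize | select | train | infer |
evaluate | compare | run`); see `shiftlab --help`.

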