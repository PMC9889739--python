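# Methods

## The model

`orbitvae` detects enlarged extraocular muscles in per-orbit coronal CT
volumes by unsupervised anomaly detection.  A three-dimensional
variational autoencoder (VAE) is trained on *normal* orbits only.  The
encoder maps a volume x to a diagonal Gaussian posterior
q_θ(z|x) = N(μ(x), diag(σ²(x))) over an 8-dimensional latent code; a
code is drawn with the reparameterization trick z = μ + σ ⊙ ε,
ε ~ N(0, I), and the decoder p_φ(x|z) reconstructs the volume.  The
training objective, minimized per mini-batch, is the mean over volumes
of

    L(x) = Σ_voxels (x − x̂)²  +  KLD(q_θ(z|x) ‖ N(0, I)),

with the KLD in closed form, −½ Σ_j (1 + log σ_j² − μ_j² − σ_j²).
Both terms are **sums**, not means: the per-volume total L(x) is the
anomaly score, and a fixed cutoff on that score only makes sense if the
scale does not depend on batch or latent sizes.  A volume whose
anatomy the model never learned — an enlarged inferior rectus, for
instance — reconstructs poorly and receives a high score.

Scores are turned into a classifier by ROC analysis with the abnormal
class positive: the operating cutoff maximizes Youden's J = TPR − FPR
("score > cutoff" → abnormal; ties at the cutoff count as normal; equal
J prefers the lower cutoff).

At evaluation time the decoder receives the posterior mean (ε = 0) by
default, so scores are deterministic and duplicate volumes score
identically; sampled scoring under an explicit seed is available via
`score_dataset(..., sample=True)`.

## Architecture

Encoder: four modules of [3×3×3 conv (stride 1, pad 1) → batch norm →
ReLU → dropout → 2×2×2 max pool], with channel widths 16/32/64/128 and
dropout rates 0.19, 0.19, 0.20, 0.23; each module halves the spatial
edge (64³ → 4³ at the default input size).  Two dense layers then
produce μ and log σ² (length 8).  Decoder: dense re-expansion, three
modules of [transposed conv (kernel 4, stride 2, pad 1) → batch norm →
leaky ReLU, negative slope 0.6], then a final module consisting of a
3×3×3 convolution to one channel, a sigmoid (inputs live in [0, 1]),
and trilinear ×2 upsampling.  Ending with interpolation rather than a
transposed convolution suppresses checkerboard artifacts at the output
margin.  Latent dimension, dropout rates and the leaky slope are the
tuned values; channel widths, kernel sizes and the dense width (512)
are this package's own defaults and are configurable.

The network is implemented in NumPy (`orbitvae.nn`): convolutions are
im2col GEMMs with the transposed convolution evaluated as eight
phase-wise 2×2×2 convolutions, and every backward pass is hand-derived
and verified against central finite differences in the test suite.
Training uses Adam (lr 1e-3 by default), shuffled mini-batches of 32,
a fixed number of epochs (100 by default; no early stopping), and
records per-epoch mean total loss for the training set and both
validation groups.  Validation volumes never contribute gradients; a
guard refuses bit-identical volumes across the split.

## Preprocessing

In order: (1) Hounsfield-unit windowing at center 40 / width 400 — the
clamped window maps to [0, 1], which *is* the min–max normalization
(per-volume and global normalization coincide under a fixed window);
(2) optional in-plane rotation by a configured angle (default 0) as the
skew-handling step — no automatic estimation; (3) per-slice orbit crop
of 136×136 centered on configured coordinates, the in-plane midpoint,
or an intensity centroid; (4) left orbits mirrored to right-orbit
shape; (5) a piecewise-linear muscle-emphasis transfer; (6) trilinear
resampling to a cube (64³ by default).

The transfer exists because a windowed orbit is dominated by bright
bone and, in volume, by the globe: the autoencoder would spend its
capacity on those instead of the thin muscles.  The default knots on
windowed intensity are (0→0, 0.46→0, 0.50→1, 0.60→1, 0.70→0, 1→0):
everything below +24 HU (fat, air, vitreous ≈ +10 HU) is zeroed, the
muscle band +40..+80 HU maps to 1, and intensities above +120 HU —
bone onset and the saturated top of the window — return to 0.  Keeping
the lower knee *above* the globe's attenuation matters; with a lower
knee the globe outshines the muscles it dwarfs in volume and its
anatomical variability dominates the reconstruction error.  Band edges
are configurable for other windows or contrast protocols.

Coordinate convention: 0-based (slice, row, column) with coronal slices
along axis 0, anterior first; rows increase downward, so the inferior
rectus sits at large row indices.

## The synthetic phantom

Clinical orbital CT cannot be redistributed, so the package ships a
phantom generator that emulates the geometry the detector must be
sensitive to: a per-orbit crop (default 64 slices of 136×136) holding a
high-attenuation bony shell (+700 HU) funnelling toward the posterior
apex, a spherical globe (+10 HU) in the anterior third, four rectus
muscles (+55 HU) as straight tapered cylinders along the
anterior–posterior axis at the inferior/superior/medial/lateral clock
positions (radius 2.5 voxels, tapering to half toward the apex), all on
orbital fat (−80 HU) with additive Gaussian noise (σ = 10 HU).
Positions, radii and the realized HU palette are jittered by ±10 % per
volume.  "Abnormal" phantoms multiply the radius of selected muscles
(default: the inferior rectus, where enlargement typically begins in
thyroid eye disease) by an enlargement factor (default 2.0), leaving
attenuation unchanged — enlargement is a size effect.  Per-volume seeds
are a splitmix-style hash of (cohort seed, index), so cohorts extend
without reshuffling.

What the phantom does **not** model: real orbital anatomy (curved
muscle paths, oblique muscles, optic nerve, lacrimal gland), scanner
physics (beam hardening, partial-volume blur, anisotropic voxels), and
contrast enhancement.  A pass on phantoms therefore demonstrates that
the pipeline is wired correctly and sensitive to the intended effect
size, not that clinical performance is reproduced.

## The reference experiment

`orbitvae.study.run_phantom_study` trains on 150 normal phantoms and
scores 30 held-out normal + 30 abnormal phantoms (enlargement 2.0).
Problem sizes are desk-scale by design — volumes resampled to 32³,
half-width channels (8/16/32/64, dense width 256), 30 epochs — so the
study runs in a few minutes on one CPU while exercising every stage at
full fidelity.  Expected behaviour, asserted by the acceptance tests:
training loss and normal-validation loss fall together (no overfitting
signal), the abnormal-validation curve separates upward during
training, the abnormal group's mean total loss exceeds the normal
group's, and AUROC ≥ 0.85 on the held-out phantoms.

## Numerical and design notes

- Windowing is monotone and, composed with a unit window, idempotent;
  the pipeline is deterministic and side-effect free.
- Resampling is trilinear (order 1) everywhere: it preserves constants,
  cannot overshoot the input range, and avoids ringing.
- Ties: max-pool gradients are split evenly among tied voxels; the ROC
  cutoff prefers the lower threshold at equal J; a score exactly at the
  cutoff is classified normal.
- Batch normalization uses running statistics (momentum 0.1, ε = 1e-5)
  in eval mode, making eval forward passes fully deterministic.
- The reconstruction expectation is approximated with a single latent
  sample during training (standard practice).
- Group metrics keep the reporting convention in which "sensitivity" is
  the accuracy of the *normal* group (TN/(TN+FP)) and "specificity" the
  accuracy of the *abnormal* group (TP/(TP+FN)); the fields are named
  `normal_group_accuracy` / `abnormal_group_accuracy` to avoid the
  ambiguity, and F1 takes abnormal as positive.  Rates with a zero
  denominator are returned as NaN and flagged, never silently zeroed.
- The loss keeps both terms at weight 1; no β-weighting of the KLD.

## Known limitations

- Pure-NumPy training is CPU-bound; the defaults are sized for
  hundreds, not tens of thousands, of volumes.
- Orbit localization is configuration-driven (coordinates or intensity
  centroid); there is no anatomical landmark detection.
- The difference map is a visualization, not a segmentation; no
  thresholded masks are derived from it.
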