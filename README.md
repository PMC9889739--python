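# orbitvae

Unsupervised detection of enlarged extraocular muscles in orbital CT
with a three-dimensional variational autoencoder (VAE).

Thyroid eye disease enlarges the extraocular muscles — typically
starting at the inferior rectus — but the muscles are thin, long and
hard to annotate, so supervised learning is impractical on the small
datasets a single center can collect.  `orbitvae` takes the anomaly
detection route instead: a 3D VAE is trained on **normal** orbits only,
and the per-volume total loss

&nbsp;&nbsp;&nbsp;&nbsp; L(x) = Σ<sub>voxels</sub> (x − x̂)² + KLD( q<sub>θ</sub>(z|x) ‖ N(0, I) )

serves as an anomaly score: orbits whose anatomy the model never
learned reconstruct poorly and score high.  ROC analysis on scored
validation volumes yields an operating cutoff (maximum Youden J), and
voxel-wise squared-difference heat maps show *where* a reconstruction
failed.  The package covers the full pipeline — CT preprocessing
(HU windowing, orbit crop, left→right flip, muscle-emphasis intensity
transfer, resampling to 64³), the VAE (implemented in NumPy, no deep
learning framework required), training, scoring, evaluation, and
visualization — plus a synthetic orbital-phantom generator so that
everything is testable without clinical data.

It is aimed at medical-image-analysis researchers who want a
self-contained, inspectable reference implementation of
reconstruction-error anomaly detection on volumetric CT.

## Worked example

Train on synthetic normal orbits and evaluate held-out normal/abnormal
phantoms (abnormal = inferior rectus radius ×2), at a small size that
runs in under a minute:

```python
from orbitvae import ExtraocularAnomalyVAE, ModelConfig, TrainConfig, PhantomSpec

spec = PhantomSpec(grid_shape=(32, 64, 64), muscle_radius_vox=2.0)
model = ExtraocularAnomalyVAE.from_phantoms(
    n_train=40, n_val_normal=10, n_val_abnormal=10,
    spec=spec, seed=0, edge=16,
    model_config=ModelConfig(input_edge=16, encoder_channels=(4, 8, 16, 32),
                             fc_hidden=64),
    train_config=TrainConfig(epochs=10, batch_size=8, seed=0))
results = model.fit()
print(results.summary())
```

```text
3D VAE anomaly detector (orbitvae 0.1.0)
======================================================
input edge            : 16
encoder channels      : (4, 8, 16, 32)
latent dimensions     : 8
dropout rates         : (0.19, 0.19, 0.2, 0.23)
leaky-ReLU slope      : 0.6
parameters            : 67,441
epochs / batch size   : 10 / 8
optimizer / lr        : adam / 0.001
training volumes      : 40
------------------------------------------------------
final train loss      : 225.9
final val loss (norm) : 262.3
final val loss (abn)  : 285.0
AUROC                 : 0.980
best cutoff (Youden J): 266.2
normal-group accuracy : 90.0%
abnormal-group acc.   : 100.0%
overall accuracy      : 95.0%
F1 (abnormal positive): 0.952
======================================================
```

Reading the table: the abnormal validation group's mean total loss
(285.0) sits above the normal group's (262.3), AUROC 0.980 says the
score ranks abnormal above normal orbits almost perfectly, and the
cutoff 266.2 is the score threshold (maximum Youden J) that the
classifier "score > cutoff → abnormal" uses; the four rates below it
describe the resulting confusion matrix.  `results.plot_loss_curves()`
shows the two validation curves separating during training, and
`results.plot_triptych(volume, slice_index)` renders
input / reconstruction / difference-map panels with reconstruction
failures in red.

The same pipeline is scriptable from the shell:

```sh
orbitvae generate --n-normal 150 --n-abnormal 0 --seed 1 --out-dir raw/
orbitvae preprocess --in-dir raw/ --out-dir pre/ --out-edge 64
orbitvae train --train-dir pre/ --out-dir run/ --epochs 100
orbitvae score --checkpoint run/checkpoint.npz --in-dir val_pre/ --out scores.csv
orbitvae evaluate --scores scores.csv --out metrics.json
orbitvae diffmap --checkpoint run/checkpoint.npz --volume pre/phantom_0000.nii.gz \
    --slice 32 --out map.png
```

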