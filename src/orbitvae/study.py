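"""The end-to-end phantom study: the package's reference experiment.

Because the clinical CT volumes behind the original anomaly-detection
results are not public, the system is validated end to end on the
synthetic phantoms: train the VAE on 150 normal phantoms, then score a
held-out set of 30 normal and 30 abnormal phantoms (inferior-rectus
radius enlarged by factor 2.0) and check that abnormal volumes carry
higher total loss and are separable by ROC analysis.

Problem sizes are deliberately desk-scale so the study runs in a few
minutes on one CPU: volumes are resampled to a 32^3 cube, the network
uses half-width channels (8, 16, 32, 64, dense width 256), and training
runs 30 epochs.  Dropout rates, latent dimension 8, leaky slope 0.6,
batch size 32 and the Adam learning rate 1e-3 are the full-scale
settings.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .evaluate import (RocResult, ScoreSet, classify, group_metrics,
                       roc_analysis)
from .model import ModelConfig
from .phantom import PhantomSpec, make_cohort, mix_seed
from .preprocess import PreprocessConfig, preprocess_pipeline
from .train import TrainConfig, TrainingTrace, score_dataset, train_model

STUDY_EDGE = 32
N_TRAIN = 150
N_VAL_NORMAL = 30
N_VAL_ABNORMAL = 30
STUDY_EPOCHS = 30


def study_model_config(edge: int = STUDY_EDGE) -> ModelConfig:
    return ModelConfig(input_edge=edge, encoder_channels=(8, 16, 32, 64),
                       fc_hidden=256)


def study_train_config(seed: int) -> TrainConfig:
    return TrainConfig(epochs=STUDY_EPOCHS, batch_size=32, learning_rate=1e-3,
                       seed=seed)


def preprocessed_cohort(n_normal: int, n_abnormal: int, seed: int,
                        spec: PhantomSpec = PhantomSpec(),
                        edge: int = STUDY_EDGE):
    """Generate phantoms and push them through the full preprocessing chain."""
    crop = min(136, spec.grid_shape[1], spec.grid_shape[2])
    cfg = PreprocessConfig(out_edge=edge, crop_edge=crop)
    cohort = make_cohort(n_normal, n_abnormal, spec, seed)
    vols = np.stack([preprocess_pipeline(v, cfg) for v, _ in cohort])
    labels = np.array([lab for _, lab in cohort])
    return vols, labels


@dataclass
class StudyResult:
    trace: TrainingTrace
    scores: np.ndarray
    labels: np.ndarray
    roc: RocResult
    mean_loss_normal: float
    mean_loss_abnormal: float
    metrics: "object"
    model: "object"


def run_phantom_study(seed: int = 1, spec: PhantomSpec = PhantomSpec(),
                      n_train: int = N_TRAIN,
                      n_val_normal: int = N_VAL_NORMAL,
                      n_val_abnormal: int = N_VAL_ABNORMAL,
                      epochs: int = STUDY_EPOCHS,
                      edge: int = STUDY_EDGE) -> StudyResult:
    """Train on normal phantoms, score held-out phantoms, run ROC analysis."""
    train_vols, _ = preprocessed_cohort(n_train, 0, mix_seed(seed, 101),
                                        spec, edge)
    val_vols, val_labels = preprocessed_cohort(
        n_val_normal, n_val_abnormal, mix_seed(seed, 202), spec, edge)

    tcfg = study_train_config(seed)
    model, trace = train_model(
        train_vols, val_vols[val_labels == 0], val_vols[val_labels == 1],
        cfg=tcfg, model_cfg=study_model_config(edge))

    scores = score_dataset(model, val_vols, seed=mix_seed(seed, 303))
    roc = roc_analysis(ScoreSet(scores=scores, labels=val_labels))
    preds = classify(scores, roc.best_cutoff)
    return StudyResult(
        trace=trace, scores=scores, labels=val_labels, roc=roc,
        mean_loss_normal=float(scores[val_labels == 0].mean()),
        mean_loss_abnormal=float(scores[val_labels == 1].mean()),
        metrics=group_metrics(val_labels, preds), model=model)
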