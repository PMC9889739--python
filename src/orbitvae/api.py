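"""Model/Results front end.

:class:`ExtraocularAnomalyVAE` is built from preprocessed volumes (or
straight from phantoms); ``fit()`` trains the autoencoder and returns an
:class:`AnomalyVAEResults` carrying the trained parameters, the
training trace, anomaly scores, ROC diagnostics and a ``summary()``
table, in the spirit of statsmodels' Model/Results split.
"""

from __future__ import annotations

import numpy as np

from . import __version__
from .diffmap import squared_difference, triptych
from .evaluate import (GroupMetrics, RocResult, ScoreSet, classify,
                       group_metrics, roc_analysis)
from .model import ModelConfig, VAE3D
from .phantom import PhantomSpec, mix_seed

from .study import preprocessed_cohort
from .train import (TrainConfig, TrainingTrace, reconstruct, score_dataset,
                    train_model)


class ExtraocularAnomalyVAE:
    """A 3D VAE anomaly detector for per-orbit CT volumes.

    Parameters
    ----------
    train_volumes : array-like, shape (n, e, e, e)
        Preprocessed normal volumes in [0, 1] (see
        :func:`orbitvae.preprocess.preprocess_pipeline`).
    val_normal, val_abnormal : array-like, optional
        Held-out volumes scored every epoch; never used for gradients.
    model_config, train_config : optional
        Architecture and optimisation settings; defaults follow the
        tuned hyperparameters (latent dim 8, dropout
        0.19/0.19/0.20/0.23, leaky slope 0.6, batches of 32).
    """

    def __init__(self, train_volumes, val_normal=None, val_abnormal=None,
                 model_config: ModelConfig | None = None,
                 train_config: TrainConfig | None = None):
        self.train_volumes = np.asarray(train_volumes, dtype=np.float32)
        self.val_normal = (np.asarray(val_normal, dtype=np.float32)
                           if val_normal is not None else np.empty((0,)))
        self.val_abnormal = (np.asarray(val_abnormal, dtype=np.float32)
                             if val_abnormal is not None else np.empty((0,)))
        edge = self.train_volumes.shape[-1]
        self.model_config = model_config or ModelConfig(input_edge=edge)
        self.train_config = train_config or TrainConfig()

    @classmethod
    def from_phantoms(cls, n_train=150, n_val_normal=30, n_val_abnormal=30,
                      spec: PhantomSpec = PhantomSpec(), seed: int = 0,
                      edge: int = 64, model_config=None, train_config=None):
        """Build the model from freshly generated, preprocessed phantoms."""
        train_vols, _ = preprocessed_cohort(n_train, 0, mix_seed(seed, 101),
                                            spec, edge)
        val, lab = preprocessed_cohort(n_val_normal, n_val_abnormal,
                                       mix_seed(seed, 202), spec, edge)
        tc = train_config or TrainConfig(seed=seed)
        return cls(train_vols, val[lab == 0], val[lab == 1],
                   model_config=model_config, train_config=tc)

    def fit(self) -> "AnomalyVAEResults":
        model, trace = train_model(self.train_volumes, self.val_normal,
                                   self.val_abnormal, cfg=self.train_config,
                                   model_cfg=self.model_config)
        return AnomalyVAEResults(self, model, trace)


class AnomalyVAEResults:
    """Trained parameters plus diagnostics; returned by ``fit()``."""

    def __init__(self, model_spec: ExtraocularAnomalyVAE, network: VAE3D,
                 trace: TrainingTrace):
        self.model = model_spec
        self.network = network
        self.trace = trace
        self._roc: RocResult | None = None

    # -- scoring ------------------------------------------------------------

    def score(self, volumes, seed: int = 0) -> np.ndarray:
        """Per-volume total loss (anomaly score)."""
        return score_dataset(self.network, volumes, seed=seed)

    def validation_scores(self, seed: int = 0):
        vols = np.concatenate([self.model.val_normal, self.model.val_abnormal])
        labels = np.concatenate([
            np.zeros(len(self.model.val_normal), int),
            np.ones(len(self.model.val_abnormal), int)])
        return self.score(vols, seed=seed), labels

    def roc(self, seed: int = 0) -> RocResult:
        if self._roc is None:
            scores, labels = self.validation_scores(seed=seed)
            self._roc = roc_analysis(ScoreSet(scores=scores, labels=labels))
        return self._roc

    def evaluate(self, seed: int = 0) -> GroupMetrics:
        scores, labels = self.validation_scores(seed=seed)
        preds = classify(scores, self.roc(seed=seed).best_cutoff)
        return group_metrics(labels, preds)

    # -- visual diagnostics -------------------------------------------------

    def diffmap(self, volume, seed: int = 0):
        xhat, _, _ = reconstruct(self.network, np.asarray(volume)[None],
                                 seed=seed)
        return squared_difference(np.asarray(volume), xhat[0])

    def plot_triptych(self, volume, slice_index, path=None, seed: int = 0):
        xhat, _, _ = reconstruct(self.network, np.asarray(volume)[None],
                                 seed=seed)
        return triptych(np.asarray(volume), xhat[0], slice_index, path)

    def plot_loss_curves(self, path=None):
        """Total-loss-versus-epoch curves for train and validation groups."""
        import matplotlib.pyplot as plt

        df = self.trace.to_frame()
        fig, ax = plt.subplots(figsize=(6, 4))
        ax.plot(df["epoch"], df["train_loss"], color="tab:blue",
                label="normal training")
        if np.isfinite(df["val_normal_loss"]).any():
            ax.plot(df["epoch"], df["val_normal_loss"], color="tab:green",
                    label="normal validation")
        if np.isfinite(df["val_abnormal_loss"]).any():
            ax.plot(df["epoch"], df["val_abnormal_loss"], color="tab:red",
                    label="abnormal validation")
        ax.set_xlabel("epoch")
        ax.set_ylabel("mean total loss")
        ax.legend()
        fig.tight_layout()
        if path is not None:
            fig.savefig(str(path), dpi=120)
            plt.close(fig)
            return None
        return fig

    # -- reporting ----------------------------------------------------------

    def summary(self) -> str:
        cfg, tc = self.model.model_config, self.model.train_config
        lines = [
            "3D VAE anomaly detector (orbitvae %s)" % __version__,
            "=" * 54,
            f"input edge            : {cfg.input_edge}",
            f"encoder channels      : {cfg.encoder_channels}",
            f"latent dimensions     : {cfg.latent_dim}",
            f"dropout rates         : {cfg.dropout_rates}",
            f"leaky-ReLU slope      : {cfg.leaky_slope}",
            f"parameters            : {self.network.n_parameters():,}",
            f"epochs / batch size   : {tc.epochs} / {tc.batch_size}",
            f"optimizer / lr        : {tc.optimizer} / {tc.learning_rate}",
            f"training volumes      : {len(self.model.train_volumes)}",
            "-" * 54,
            f"final train loss      : {self.trace.train_loss[-1]:.1f}",
        ]
        if len(self.model.val_normal) and len(self.model.val_abnormal):
            r = self.roc()
            m = self.evaluate()
            lines += [
                f"final val loss (norm) : {self.trace.val_normal_loss[-1]:.1f}",
                f"final val loss (abn)  : {self.trace.val_abnormal_loss[-1]:.1f}",
                f"AUROC                 : {r.auc:.3f}",
                f"best cutoff (Youden J): {r.best_cutoff:.1f}",
                f"normal-group accuracy : {m.normal_group_accuracy:.1%}",
                f"abnormal-group acc.   : {m.abnormal_group_accuracy:.1%}",
                f"overall accuracy      : {m.overall_accuracy:.1%}",
                f"F1 (abnormal positive): {m.f1:.3f}",
            ]
        lines.append("=" * 54)
        return "\n".join(lines)
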