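"""Training loop: normals only, shuffled mini-batches, per-epoch trace.

The autoencoder sees only normal volumes; both validation groups are
scored every epoch in eval mode but never contribute gradients.  "32
per training epoch" is read as shuffled mini-batches of 32 (reshuffled
every epoch so the input order carries no bias); the alternative
reading — a 32-sample cap per epoch — is available via
``samples_per_epoch``.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import objective
from .model import VAE3D, ModelConfig, build_model
from .phantom import mix_seed


class TrainingError(ValueError):
    pass


@dataclass(frozen=True)
class TrainConfig:
    epochs: int = 100
    batch_size: int = 32
    learning_rate: float = 1e-3
    seed: int = 0
    optimizer: str = "adam"
    samples_per_epoch: int | None = None  # optional cap (alternative reading)

    def __post_init__(self):
        if self.epochs < 1:
            raise TrainingError(f"epochs must be >= 1, got {self.epochs}")
        if self.batch_size < 1:
            raise TrainingError(f"batch_size must be >= 1, got {self.batch_size}")
        if self.optimizer != "adam":
            raise TrainingError(f"unsupported optimizer {self.optimizer!r}")


@dataclass
class TrainingTrace:
    """Per-epoch mean total losses for train and both validation groups."""

    train_loss: list[float] = field(default_factory=list)
    val_normal_loss: list[float] = field(default_factory=list)
    val_abnormal_loss: list[float] = field(default_factory=list)

    def __len__(self):
        return len(self.train_loss)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "epoch": np.arange(1, len(self) + 1),
            "train_loss": self.train_loss,
            "val_normal_loss": self.val_normal_loss,
            "val_abnormal_loss": self.val_abnormal_loss,
        })


def _as_stack(volumes) -> np.ndarray:
    arr = np.asarray(volumes, dtype=np.float32)
    if arr.ndim == 3:
        arr = arr[None]
    if arr.ndim != 4:
        raise TrainingError(
            f"expected a list of rank-3 volumes, got array of shape {arr.shape}")
    return arr


def _digest(vol: np.ndarray) -> str:
    return hashlib.sha1(np.ascontiguousarray(vol, dtype=np.float32).tobytes()
                        ).hexdigest()


def _forward_batched(model: VAE3D, volumes: np.ndarray, rng, batch_size=16,
                     train=False, sample=False):
    xh, mus, lvs = [], [], []
    for s in range(0, len(volumes), batch_size):
        xb = volumes[s:s + batch_size]
        xhat, d, _ = model.forward(xb, rng=rng, train=train, sample=sample)
        xh.append(xhat)
        mus.append(d.mu)
        lvs.append(d.logvar)
    return np.concatenate(xh), np.concatenate(mus), np.concatenate(lvs)


def score_dataset(model: VAE3D, volumes, seed: int = 0,
                  batch_size: int = 16, sample: bool = False) -> np.ndarray:
    """Per-volume total losses (anomaly scores) in eval mode.

    By default the posterior mean is decoded (no reparameterization
    noise), so scores are deterministic and identical volumes get
    identical scores; ``sample=True`` draws one latent sample under
    ``seed`` instead.
    """
    vols = _as_stack(volumes)
    rng = np.random.default_rng(seed)
    xhat, mu, logvar = _forward_batched(model, vols, rng, batch_size,
                                        train=False, sample=sample)
    return objective.batch_losses(vols, xhat, mu, logvar)


def reconstruct(model: VAE3D, volumes, seed: int = 0, batch_size: int = 16,
                sample: bool = False):
    """Eval-mode reconstructions plus latent parameters (for diff maps/tests)."""
    vols = _as_stack(volumes)
    rng = np.random.default_rng(seed)
    return _forward_batched(model, vols, rng, batch_size, train=False,
                            sample=sample)


def train_model(train_normals, val_normals, val_abnormals,
                cfg: TrainConfig = TrainConfig(),
                model_cfg: ModelConfig | None = None,
                model: VAE3D | None = None):
    """Fit the VAE on normal volumes; returns (model, TrainingTrace).

    Validation volumes are scored each epoch (eval mode, seeded
    reparameterization) and never contribute gradients.  Raises if any
    validation volume is bit-identical to a training volume (leakage
    guard).
    """
    from .nn import Adam

    x_train = _as_stack(train_normals)
    x_vn = _as_stack(val_normals) if len(val_normals) else np.empty((0,) + x_train.shape[1:], np.float32)
    x_va = _as_stack(val_abnormals) if len(val_abnormals) else np.empty((0,) + x_train.shape[1:], np.float32)
    if x_train.shape[0] == 0:
        raise TrainingError("training set is empty")

    train_digests = {_digest(v) for v in x_train}
    for name, group in (("normal", x_vn), ("abnormal", x_va)):
        for v in group:
            if _digest(v) in train_digests:
                raise TrainingError(
                    f"leakage: a {name}-validation volume is identical to a "
                    "training volume")

    if model is None:
        edge = x_train.shape[1]
        if model_cfg is None:
            model_cfg = ModelConfig(input_edge=edge)
        model = build_model(model_cfg, seed=mix_seed(cfg.seed, 0))
    opt = Adam(model._groups, lr=cfg.learning_rate)
    shuffle_rng = np.random.default_rng(mix_seed(cfg.seed, 1))
    noise_rng = np.random.default_rng(mix_seed(cfg.seed, 2))
    model.set_dropout_rng(np.random.default_rng(mix_seed(cfg.seed, 3)))

    trace = TrainingTrace()
    n = x_train.shape[0]
    for epoch in range(cfg.epochs):
        order = shuffle_rng.permutation(n)
        if cfg.samples_per_epoch is not None:
            order = order[:cfg.samples_per_epoch]
        epoch_losses = []
        for s in range(0, len(order), cfg.batch_size):
            xb = x_train[order[s:s + cfg.batch_size]]
            opt.zero_grads()
            xhat, d, _ = model.forward(xb, rng=noise_rng, train=True)
            model.backward(xb, xhat)
            opt.step()
            epoch_losses.append(
                objective.batch_losses(xb, xhat, d.mu, d.logvar))
        trace.train_loss.append(float(np.mean(np.concatenate(epoch_losses))))

        val_seed = mix_seed(cfg.seed, 1000 + epoch)
        vn = score_dataset(model, x_vn, seed=val_seed) if len(x_vn) else np.array([np.nan])
        va = score_dataset(model, x_va, seed=val_seed) if len(x_va) else np.array([np.nan])
        trace.val_normal_loss.append(float(np.mean(vn)))
        trace.val_abnormal_loss.append(float(np.mean(va)))
    return model, trace
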