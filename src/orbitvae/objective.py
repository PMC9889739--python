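"""Loss function: per-volume anomaly score = reconstruction loss + KLD.

The reconstruction term is the plain sum of squared differences over
all voxels (not averaged), and the KLD term is the closed-form
divergence of the encoder's diagonal Gaussian q(z|x) = N(mu, diag(sigma^2))
from the standard-normal prior p(z) = N(0, I),

    KLD = -1/2 * sum_j (1 + logvar_j - mu_j^2 - exp(logvar_j)),

summed (not averaged) over latent dimensions.  Keeping both terms as
sums makes the per-volume total directly comparable with a fixed
anomaly cutoff.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .model import LatentDistribution


@dataclass(frozen=True)
class LossBreakdown:
    recon: float
    kld: float

    @property
    def total(self) -> float:
        return self.recon + self.kld


def reconstruction_loss(x: np.ndarray, xhat: np.ndarray) -> float:
    """Sum of squared voxel-wise differences between input and output."""
    x = np.asarray(x, dtype=np.float64)
    xhat = np.asarray(xhat, dtype=np.float64)
    if x.shape != xhat.shape:
        raise ValueError(f"shape mismatch: {x.shape} vs {xhat.shape}")
    d = x - xhat
    return float(np.sum(d * d))


def kld_loss(d: LatentDistribution) -> float:
    """Closed-form KL(q(z|x) || N(0, I)), summed over latent dimensions."""
    mu = np.asarray(d.mu, dtype=np.float64)
    logvar = np.asarray(d.logvar, dtype=np.float64)
    if not (np.all(np.isfinite(mu)) and np.all(np.isfinite(logvar))):
        raise ValueError("mu and logvar must be finite")
    return float(-0.5 * np.sum(1.0 + logvar - mu ** 2 - np.exp(logvar)))


def total_loss(x: np.ndarray, xhat: np.ndarray, d: LatentDistribution) -> LossBreakdown:
    """Per-volume loss breakdown; ``total`` is the anomaly score."""
    return LossBreakdown(recon=reconstruction_loss(x, xhat), kld=kld_loss(d))


def batch_losses(x: np.ndarray, xhat: np.ndarray,
                 mu: np.ndarray, logvar: np.ndarray) -> np.ndarray:
    """Vectorized per-volume totals for a batch (axis 0 indexes volumes)."""
    x = np.asarray(x, dtype=np.float64)
    xhat = np.asarray(xhat, dtype=np.float64)
    d = (x - xhat).reshape(x.shape[0], -1)
    recon = np.einsum("ij,ij->i", d, d)
    mu = np.asarray(mu, dtype=np.float64)
    logvar = np.asarray(logvar, dtype=np.float64)
    kld = -0.5 * np.sum(1.0 + logvar - mu ** 2 - np.exp(logvar), axis=1)
    return recon + kld
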