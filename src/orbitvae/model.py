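"""The 3D variational autoencoder.

Encoder: four modules of [conv3x3x3 -> batch norm -> ReLU -> dropout ->
2x2x2 max pool], each halving the spatial edge (64 -> 32 -> 16 -> 8 -> 4
at the default input size), followed by two dense layers producing the
latent mean vector mu and log-variance vector (length 8 by default).
A latent code is drawn with the reparameterization trick,
z = mu + exp(logvar / 2) * eps, eps ~ N(0, I).

Decoder: dense re-expansion, three modules of [transposed conv (kernel
4, stride 2) -> batch norm -> leaky ReLU], and a final module that uses
trilinear upsampling followed by an ordinary convolution and a sigmoid —
ending with interpolation rather than another transposed convolution
suppresses checkerboard artifacts at the output margin and keeps the
reconstruction in [0, 1].
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np

from . import nn

CHECKPOINT_FORMAT_VERSION = 1


class ConfigError(ValueError):
    """An invalid model or run configuration."""


@dataclass(frozen=True)
class ModelConfig:
    """Architecture hyperparameters.

    Dropout rates, latent dimensionality and the leaky-ReLU negative
    slope follow the tuned values (0.19 for the first two encoder
    modules, 0.20 for the third, 0.23 for the fourth; 8 latent
    dimensions; slope 0.6).  Channel widths and dense sizes are this
    package's own defaults, sized to the 4-down/4-up structure.
    """

    input_edge: int = 64
    encoder_channels: tuple[int, int, int, int] = (16, 32, 64, 128)
    latent_dim: int = 8
    dropout_rates: tuple[float, float, float, float] = (0.19, 0.19, 0.20, 0.23)
    leaky_slope: float = 0.6
    fc_hidden: int = 512

    def __post_init__(self):
        if self.latent_dim < 1:
            raise ConfigError(f"latent_dim must be >= 1, got {self.latent_dim}")
        if self.input_edge % 16 != 0 or self.input_edge < 16:
            raise ConfigError(
                f"input_edge must be a positive multiple of 2^4, got {self.input_edge}")
        if len(self.encoder_channels) != 4 or any(c < 1 for c in self.encoder_channels):
            raise ConfigError("encoder_channels must be 4 positive counts")
        if len(self.dropout_rates) != 4 or not all(0 <= r < 1 for r in self.dropout_rates):
            raise ConfigError("dropout_rates must be 4 values in [0, 1)")
        if self.leaky_slope <= 0:
            raise ConfigError(f"leaky_slope must be > 0, got {self.leaky_slope}")

    @property
    def bottleneck_edge(self) -> int:
        return self.input_edge // 16

    @property
    def flat_dim(self) -> int:
        return self.encoder_channels[3] * self.bottleneck_edge ** 3


@dataclass
class LatentDistribution:
    """Per-volume diagonal Gaussian over latent codes."""

    mu: np.ndarray
    logvar: np.ndarray

    def __post_init__(self):
        self.mu = np.asarray(self.mu)
        self.logvar = np.asarray(self.logvar)
        if self.mu.shape != self.logvar.shape:
            raise ValueError("mu and logvar must have equal shape")
        if not (np.all(np.isfinite(self.mu)) and np.all(np.isfinite(self.logvar))):
            raise ValueError("latent distribution parameters must be finite")


def reparameterize(d: LatentDistribution, seed=None,
                   rng: np.random.Generator | None = None) -> np.ndarray:
    """Draw z = mu + exp(logvar/2) * eps with eps ~ N(0, I)."""
    if rng is None:
        rng = np.random.default_rng(seed)
    eps = rng.standard_normal(d.mu.shape).astype(d.mu.dtype, copy=False)
    return d.mu + np.exp(0.5 * d.logvar) * eps


class VAE3D:
    """The network, its parameters, and hand-rolled forward/backward."""

    def __init__(self, cfg: ModelConfig, seed: int = 0, dtype=nn.DTYPE):
        self.cfg = cfg
        self.seed = seed
        self.dtype = dtype
        rng = np.random.default_rng(seed)
        ch = cfg.encoder_channels
        mk = lambda cin, cout, first=False: nn.Conv3d(
            cin, cout, 3, 1, rng=rng, dtype=dtype, first_layer=first)

        self.encoder = nn.Sequential([
            lay
            for i, (cin, cout) in enumerate(zip((1,) + ch[:3], ch))
            for lay in (mk(cin, cout, first=(i == 0)),
                        nn.BatchNorm3d(cout, dtype=dtype), nn.ReLU(),
                        nn.Dropout(cfg.dropout_rates[i]), nn.MaxPool3d())
        ])
        self.enc_fc = nn.Sequential([
            nn.Linear(cfg.flat_dim, cfg.fc_hidden, rng=rng, dtype=dtype), nn.ReLU()])
        self.fc_mu = nn.Linear(cfg.fc_hidden, cfg.latent_dim, rng=rng, dtype=dtype)
        self.fc_logvar = nn.Linear(cfg.fc_hidden, cfg.latent_dim, rng=rng, dtype=dtype)

        self.dec_fc = nn.Sequential([
            nn.Linear(cfg.latent_dim, cfg.fc_hidden, rng=rng, dtype=dtype), nn.ReLU(),
            nn.Linear(cfg.fc_hidden, cfg.flat_dim, rng=rng, dtype=dtype), nn.ReLU()])
        slope = cfg.leaky_slope
        self.decoder = nn.Sequential([
            nn.ConvTranspose3d(ch[3], ch[2], rng=rng, dtype=dtype),
            nn.BatchNorm3d(ch[2], dtype=dtype), nn.LeakyReLU(slope),
            nn.ConvTranspose3d(ch[2], ch[1], rng=rng, dtype=dtype),
            nn.BatchNorm3d(ch[1], dtype=dtype), nn.LeakyReLU(slope),
            nn.ConvTranspose3d(ch[1], ch[0], rng=rng, dtype=dtype),
            nn.BatchNorm3d(ch[0], dtype=dtype), nn.LeakyReLU(slope),
            # final module ends in upsampling instead of a transposed
            # convolution (avoids margin checkerboard artifacts)
            mk(ch[0], 1), nn.Sigmoid(), nn.Upsample2(),
        ])
        self._groups = [self.encoder, self.enc_fc, self.fc_mu, self.fc_logvar,
                        self.dec_fc, self.decoder]

    # -- plumbing -----------------------------------------------------------

    def set_dropout_rng(self, rng: np.random.Generator):
        for lay in self.encoder.layers:
            if isinstance(lay, nn.Dropout):
                lay.rng = rng

    def zero_grads(self):
        for g in self._groups:
            g.zero_grads()

    def parameter_slots(self):
        return list(nn.iter_params(self._groups))

    def n_parameters(self) -> int:
        return sum(lay.params[name].size for lay, name in self.parameter_slots())

    # -- forward pieces -----------------------------------------------------

    def _check_input(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x)
        e = self.cfg.input_edge
        if x.ndim == 3:
            x = x[None]
        if x.ndim == 4:
            x = x[:, None]
        if x.ndim != 5 or x.shape[1] != 1 or x.shape[2:] != (e, e, e):
            raise ValueError(
                f"expected input volumes of shape ({e}, {e}, {e}); got {x.shape}")
        return x.astype(self.dtype, copy=False)

    def encode(self, x, train: bool = False) -> LatentDistribution:
        x = self._check_input(x)
        h = self.encoder.forward(x, train=train)
        self._enc_shape = h.shape
        h = h.reshape(h.shape[0], -1)
        h = self.enc_fc.forward(h, train=train)
        mu = self.fc_mu.forward(h, train=train)
        logvar = self.fc_logvar.forward(h, train=train)
        return LatentDistribution(mu, logvar)

    def decode(self, z: np.ndarray, train: bool = False) -> np.ndarray:
        z = np.asarray(z, dtype=self.dtype)
        if z.ndim == 1:
            z = z[None]
        if z.shape[1] != self.cfg.latent_dim:
            raise ValueError(
                f"latent vectors must have length {self.cfg.latent_dim}, got {z.shape[1]}")
        h = self.dec_fc.forward(z, train=train)
        e = self.cfg.bottleneck_edge
        h = h.reshape(z.shape[0], self.cfg.encoder_channels[3], e, e, e)
        self._dec_shape = h.shape
        return self.decoder.forward(h, train=train)[:, 0]

    def forward(self, x, seed=None, rng=None, train: bool = False,
                sample: bool = True):
        """encode -> reparameterize -> decode; returns (xhat, dist, eps).

        With ``sample=False`` the posterior mean is decoded (eps = 0),
        which makes eval-mode scoring fully deterministic.
        """
        d = self.encode(x, train=train)
        if sample:
            if rng is None:
                rng = np.random.default_rng(seed)
            eps = rng.standard_normal(d.mu.shape).astype(self.dtype)
        else:
            eps = np.zeros_like(d.mu)
        z = d.mu + np.exp(0.5 * d.logvar) * eps
        xhat = self.decode(z, train=train)
        self._fwd_cache = (d, eps, z)
        return xhat, d, eps

    # -- backward -----------------------------------------------------------

    def backward(self, x, xhat):
        """Accumulate gradients of mean-per-volume [recon + KLD] loss.

        Must follow a ``forward(..., train=True)`` call on the same batch.
        """
        d, eps, _z = self._fwd_cache
        x = self._check_input(x)[:, 0]
        n = x.shape[0]
        dxhat = (2.0 / n) * (xhat - x)
        dh = self.decoder.backward(dxhat[:, None])
        dz = self.dec_fc.backward(dh.reshape(n, -1))
        # z = mu + exp(logvar/2) * eps
        dmu = dz.copy()
        dlogvar = dz * eps * 0.5 * np.exp(0.5 * d.logvar)
        # KLD = -1/2 sum(1 + logvar - mu^2 - exp(logvar)) per volume
        dmu += d.mu / n
        dlogvar += 0.5 * (np.exp(d.logvar) - 1.0) / n
        dhid = self.fc_mu.backward(dmu) + self.fc_logvar.backward(dlogvar)
        dflat = self.enc_fc.backward(dhid)
        self.encoder.backward(dflat.reshape(self._enc_shape))

    # -- checkpointing ------------------------------------------------------

    def save(self, path):
        path = Path(path)
        arrays, meta = {}, []
        for i, (lay, name) in enumerate(self.parameter_slots()):
            arrays[f"p{i}"] = lay.params[name]
            meta.append(name)
        for j, lay in enumerate(self._bn_layers()):
            arrays[f"bn{j}_mean"] = lay.running_mean
            arrays[f"bn{j}_var"] = lay.running_var
        arrays["__meta__"] = np.frombuffer(json.dumps({
            "format_version": CHECKPOINT_FORMAT_VERSION,
            "config": asdict(self.cfg),
            "seed": self.seed,
            "param_names": meta,
        }).encode(), dtype=np.uint8)
        with open(path, "wb") as fh:
            np.savez(fh, **arrays)

    def _bn_layers(self):
        out = []
        for g in self._groups:
            if isinstance(g, nn.Sequential):
                out += [l for l in g.layers if isinstance(l, nn.BatchNorm3d)]
        return out

    @classmethod
    def load(cls, path) -> "VAE3D":
        with np.load(Path(path)) as data:
            meta = json.loads(bytes(data["__meta__"]).decode())
            if meta["format_version"] != CHECKPOINT_FORMAT_VERSION:
                raise ValueError(
                    f"unsupported checkpoint format {meta['format_version']}")
            cfg = meta["config"]
            cfg["encoder_channels"] = tuple(cfg["encoder_channels"])
            cfg["dropout_rates"] = tuple(cfg["dropout_rates"])
            model = cls(ModelConfig(**cfg), seed=meta["seed"])
            for i, (lay, name) in enumerate(model.parameter_slots()):
                lay.params[name] = data[f"p{i}"].copy()
            for j, lay in enumerate(model._bn_layers()):
                lay.running_mean = data[f"bn{j}_mean"].copy()
                lay.running_var = data[f"bn{j}_var"].copy()
        model.zero_grads()
        return model


def build_model(cfg: ModelConfig, seed: int = 0) -> VAE3D:
    """Construct a VAE with deterministic initialization under ``seed``."""
    return VAE3D(cfg, seed=seed)
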