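"""Difference maps: voxel-wise squared input/reconstruction discrepancy.

The map's sum is exactly the reconstruction loss, so the heat map is a
spatial decomposition of the anomaly score: large values (rendered red)
mark structures the autoencoder failed to reconstruct — enlarged
muscles in true positives, but sometimes extraorbital clutter as well.
"""

from __future__ import annotations

from dataclasses import dataclass

import matplotlib
matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np


@dataclass(frozen=True)
class DifferenceMap:
    values: np.ndarray

    def __post_init__(self):
        v = np.asarray(self.values, dtype=np.float64)
        object.__setattr__(self, "values", v)
        if v.ndim != 3:
            raise ValueError("difference map must be rank-3")
        if v.size and v.min() < 0:
            raise ValueError("difference map must be non-negative")

    @property
    def total(self) -> float:
        return float(self.values.sum())


def squared_difference(x: np.ndarray, xhat: np.ndarray) -> DifferenceMap:
    """Element-wise (x - xhat)^2."""
    x = np.asarray(x, dtype=np.float64)
    xhat = np.asarray(xhat, dtype=np.float64)
    if x.shape != xhat.shape:
        raise ValueError(f"shape mismatch: {x.shape} vs {xhat.shape}")
    return DifferenceMap(values=(x - xhat) ** 2)


def render_heatmap(d: DifferenceMap, slice_index: int,
                   vmax: float | None = None, cmap: str = "coolwarm") -> np.ndarray:
    """One coronal slice as an RGB uint8 image, blue (small) to red (large).

    ``vmax`` defaults to the per-volume maximum so renderings are
    invariant to positive rescaling of the map; pass a fixed value for
    cross-volume comparability.
    """
    if not 0 <= slice_index < d.values.shape[0]:
        raise IndexError(
            f"slice {slice_index} out of range [0, {d.values.shape[0]})")
    if vmax is None:
        vmax = float(d.values.max())
    sl = d.values[slice_index]
    norm = np.zeros_like(sl) if vmax == 0 else np.clip(sl / vmax, 0.0, 1.0)
    rgba = matplotlib.colormaps[cmap](norm)
    return (rgba[..., :3] * 255).round().astype(np.uint8)


def save_heatmap(d: DifferenceMap, slice_index: int, path,
                 vmax: float | None = None, cmap: str = "coolwarm") -> None:
    plt.imsave(str(path), render_heatmap(d, slice_index, vmax, cmap))


def triptych(x: np.ndarray, xhat: np.ndarray, slice_index: int, path=None,
             cmap: str = "coolwarm"):
    """Input / reconstruction / difference-map panel for one slice."""
    d = squared_difference(x, xhat)
    fig, axes = plt.subplots(1, 3, figsize=(9, 3))
    axes[0].imshow(x[slice_index], cmap="gray", vmin=0, vmax=1)
    axes[0].set_title("input")
    axes[1].imshow(xhat[slice_index], cmap="gray", vmin=0, vmax=1)
    axes[1].set_title("reconstruction")
    axes[2].imshow(render_heatmap(d, slice_index, cmap=cmap))
    axes[2].set_title("difference map")
    for ax in axes:
        ax.axis("off")
    fig.tight_layout()
    if path is not None:
        fig.savefig(str(path), dpi=120)
        plt.close(fig)
        return None
    return fig
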