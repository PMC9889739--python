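"""CT preprocessing chain feeding the autoencoder.

Stages, in order: Hounsfield-unit windowing (center 40, width 400 by
default — the clamped window is itself the min-max normalization to
[0, 1]), optional in-plane rotation (skew handling), per-slice orbit
crop (136 x 136 by default), left-to-right flip so every orbit matches
the right-orbit shape, a piecewise-linear intensity transfer that
emphasizes the extraocular-muscle band while sending saturated bone to
zero, and trilinear resampling to a cube (64^3 by default).

The muscle-emphasis transfer exists because bone dominates a windowed
orbit image: muscle sits around +35..+70 HU while cortical bone clamps
to the top of the window, so without the transfer the autoencoder
spends its capacity reconstructing bone contours instead of muscles.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.transform import resize as _sk_resize

from .phantom import HUVolume


class PreprocessConfigError(ValueError):
    pass


class PipelineStageError(RuntimeError):
    """Failure inside a named pipeline stage."""

    def __init__(self, stage: str, original: Exception):
        super().__init__(f"preprocessing stage {stage!r} failed: {original}")
        self.stage = stage
        self.original = original


@dataclass(frozen=True)
class WindowSettings:
    """CT display window: orbit defaults center 40 HU, width 400 HU."""

    center: float = 40.0
    width: float = 400.0

    def __post_init__(self):
        if self.width <= 0:
            raise PreprocessConfigError(f"window width must be > 0, got {self.width}")

    @property
    def lo(self) -> float:
        return self.center - self.width / 2.0

    @property
    def hi(self) -> float:
        return self.center + self.width / 2.0


@dataclass(frozen=True)
class TransferFunction:
    """Piecewise-linear map on [0, 1] windowed intensities.

    ``points`` are (x, y) control points with strictly increasing x,
    x[0] = 0 and x[-1] = 1, all values in [0, 1].  Segments may descend,
    which is how intensities above the bone-onset knot are sent to 0.
    """

    points: tuple[tuple[float, float], ...]

    def __post_init__(self):
        pts = tuple((float(x), float(y)) for x, y in self.points)
        object.__setattr__(self, "points", pts)
        xs = [p[0] for p in pts]
        ys = [p[1] for p in pts]
        if len(pts) < 2:
            raise PreprocessConfigError("transfer needs at least 2 control points")
        if any(x1 <= x0 for x0, x1 in zip(xs, xs[1:])):
            raise PreprocessConfigError(
                "transfer domain knots must be strictly increasing")
        if xs[0] != 0.0 or xs[-1] != 1.0:
            raise PreprocessConfigError("transfer domain must span [0, 1]")
        if min(ys) < 0 or max(ys) > 1 or min(xs) < 0 or max(xs) > 1:
            raise PreprocessConfigError("transfer points must lie in [0, 1]^2")

    def __call__(self, grid: np.ndarray) -> np.ndarray:
        xs = np.array([p[0] for p in self.points])
        ys = np.array([p[1] for p in self.points])
        return np.interp(grid, xs, ys).astype(np.asarray(grid).dtype, copy=False)


def identity_transfer() -> TransferFunction:
    return TransferFunction(((0.0, 0.0), (1.0, 1.0)))


def default_muscle_transfer() -> TransferFunction:
    """Default muscle-emphasis map on windowed (center 40 / width 400) values.

    The plateau tracks the extraocular-muscle attenuation band: values
    below +24 HU (w < 0.46) — air, fat, vitreous/globe around +10 HU —
    map to 0, the band +40..+80 HU (w in [0.50, 0.60]) maps to 1, and
    intensities ramp back to 0 by +120 HU (w = 0.70) so contrast-bright
    and bony structures, including the saturated top of the window, are
    suppressed.  Keeping the lower knee above the globe's HU matters:
    otherwise the globe outshines the muscles it dwarfs in volume.
    """
    return TransferFunction(((0.0, 0.0), (0.46, 0.0), (0.50, 1.0),
                             (0.60, 1.0), (0.70, 0.0), (1.0, 0.0)))


def window_hu(vol, w: WindowSettings = WindowSettings()) -> np.ndarray:
    """Clamp HU into the window and rescale to [0, 1] (min-max normalize)."""
    values = vol.values if isinstance(vol, HUVolume) else np.asarray(vol)
    out = (values.astype(np.float64) - w.lo) / w.width
    return np.clip(out, 0.0, 1.0).astype(np.float32)


def emphasize_muscle(grid: np.ndarray, t: TransferFunction | None = None) -> np.ndarray:
    """Apply the intensity transfer element-wise to a [0, 1] grid."""
    grid = np.asarray(grid)
    if grid.size and (grid.min() < 0 or grid.max() > 1):
        raise ValueError("emphasize_muscle expects values in [0, 1]")
    t = t or default_muscle_transfer()
    return t(grid)


def extract_orbit(vol: HUVolume, side: str | None = None, crop_edge: int = 136,
                  center: tuple[float, float] | str | None = None) -> HUVolume:
    """Per-slice centered crop of ``crop_edge`` x ``crop_edge``.

    ``center`` is an (row, col) coordinate, the string ``"centroid"``
    for an intensity-centroid estimate (on windowed values), or None
    for the in-plane midpoint.  ``side`` sets the output laterality
    metadata when given.
    """
    ns, nr, nc = vol.values.shape
    if crop_edge > nr or crop_edge > nc:
        raise ValueError(
            f"crop of {crop_edge}x{crop_edge} exceeds in-plane extent {nr}x{nc}")
    if center is None:
        cy, cx = nr / 2.0, nc / 2.0
    elif center == "centroid":
        w = window_hu(vol).sum(axis=0)
        tot = w.sum()
        if tot == 0:
            cy, cx = nr / 2.0, nc / 2.0
        else:
            cy = float((w.sum(axis=1) * np.arange(nr)).sum() / tot)
            cx = float((w.sum(axis=0) * np.arange(nc)).sum() / tot)
    else:
        cy, cx = center
    r0 = int(round(cy - crop_edge / 2.0))
    c0 = int(round(cx - crop_edge / 2.0))
    r0 = min(max(r0, 0), nr - crop_edge)
    c0 = min(max(c0, 0), nc - crop_edge)
    lat = side if side is not None else vol.laterality
    return HUVolume(values=vol.values[:, r0:r0 + crop_edge, c0:c0 + crop_edge].copy(),
                    spacing=vol.spacing, laterality=lat)


def flip_lr(vol: HUVolume) -> HUVolume:
    """Mirror along the in-plane left-right (column) axis."""
    lat = {"left": "right", "right": "left"}.get(vol.laterality, "unknown")
    return HUVolume(values=np.ascontiguousarray(vol.values[:, :, ::-1]),
                    spacing=vol.spacing, laterality=lat)


def resize_to_cube(grid: np.ndarray, edge: int = 64) -> np.ndarray:
    """Trilinear resample to ``edge``^3; output range stays within input range."""
    grid = np.asarray(grid, dtype=np.float64)
    if grid.size == 0:
        raise ValueError("cannot resize an empty grid")
    if grid.shape == (edge, edge, edge):
        return grid.astype(np.float32)
    out = _sk_resize(grid, (edge, edge, edge), order=1, mode="edge",
                     anti_aliasing=False, preserve_range=True)
    return out.astype(np.float32)


@dataclass(frozen=True)
class PreprocessConfig:
    """Everything the deterministic pipeline needs."""

    window: WindowSettings = WindowSettings()
    transfer: TransferFunction = field(default_factory=default_muscle_transfer)
    crop_edge: int = 136
    crop_center: tuple[float, float] | str | None = None
    rotation_deg: float = 0.0
    out_edge: int = 64


def preprocess_pipeline(vol: HUVolume, config: PreprocessConfig = PreprocessConfig()
                        ) -> np.ndarray:
    """window -> rotate -> crop -> flip-if-left -> emphasize -> resize.

    Returns a float32 cube of shape (out_edge,)*3 with values in [0, 1].
    Raises :class:`PipelineStageError` naming the failing stage.
    """
    def stage(name, fn, *a, **kw):
        try:
            return fn(*a, **kw)
        except PipelineStageError:
            raise
        except Exception as exc:
            raise PipelineStageError(name, exc) from exc

    grid = stage("window", window_hu, vol, config.window)
    if config.rotation_deg != 0.0:
        grid = stage("rotate", ndimage.rotate, grid, config.rotation_deg,
                     axes=(1, 2), reshape=False, order=1, mode="nearest")
        grid = np.clip(grid, 0.0, 1.0)
    work = HUVolume(values=grid, spacing=vol.spacing, laterality=vol.laterality)
    work = stage("crop", extract_orbit, work, None, config.crop_edge,
                 config.crop_center)
    if work.laterality == "left":
        work = stage("flip", flip_lr, work)
    grid = stage("emphasize", emphasize_muscle, work.values, config.transfer)
    return stage("resize", resize_to_cube, grid, config.out_edge)
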