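"""Synthetic orbital-CT phantoms with known muscle geometry.

Each phantom emulates a single-orbit coronal CT crop: a high-attenuation
bony shell that funnels toward the posterior apex, a spherical globe,
and four rectus muscles modelled as straight tapered cylinders running
along the anterior-posterior (slice) axis at the inferior, superior,
medial and lateral clock positions.  "Abnormal" phantoms enlarge the
cross-section of selected muscles (the inferior rectus by default,
where enlargement typically begins in thyroid eye disease) by a radius
factor, leaving attenuation values unchanged — enlargement is a size
effect, not a density effect.

Values are in Hounsfield units: orbital fat around -80 HU, globe ~+10,
muscle ~+55, cortical bone ~+700, plus optional additive Gaussian noise.
Geometry is deliberately schematic — it exercises the pipeline, it is
not a claim about real orbital anatomy.

Axis convention: arrays are indexed (slice, row, column) with coronal
slices stacked along axis 0, anterior at slice 0; rows increase
downward, so the inferior muscle sits at larger row indices.
"""

from __future__ import annotations

from dataclasses import dataclass


import numpy as np
import pandas as pd

MUSCLES = ("inferior", "superior", "medial", "lateral")

# per-volume seeds: splitmix-style multiplicative mix of the cohort seed
# with the volume index, truncated to 31 bits
_MIX = 0x9E3779B9


def mix_seed(seed: int, index: int) -> int:
    return (int(seed) ^ (_MIX * (index + 1))) & 0x7FFFFFFF


class PhantomConfigError(ValueError):
    """Invalid phantom specification."""


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry and intensity parameters of the synthetic orbit."""

    grid_shape: tuple[int, int, int] = (64, 136, 136)  # (slices, rows, cols)
    background_hu: float = -80.0
    bone_hu: float = 700.0
    globe_hu: float = 10.0
    muscle_hu: float = 55.0
    noise_sd: float = 10.0
    muscle_radius_vox: float = 2.5
    enlargement_factor: float = 2.0
    enlarged_muscles: tuple[str, ...] = ("inferior",)
    jitter: float = 0.1

    def __post_init__(self):
        if len(self.grid_shape) != 3 or any(s < 8 for s in self.grid_shape):
            raise PhantomConfigError(
                f"grid_shape must be 3 counts >= 8, got {self.grid_shape}")
        for name in ("background_hu", "bone_hu", "globe_hu", "muscle_hu"):
            if not np.isfinite(getattr(self, name)):
                raise PhantomConfigError(f"{name} must be finite")
        if self.noise_sd < 0:
            raise PhantomConfigError(f"noise_sd must be >= 0, got {self.noise_sd}")
        if self.enlargement_factor < 1:
            raise PhantomConfigError(
                f"enlargement_factor must be >= 1, got {self.enlargement_factor}")
        if not 0 <= self.jitter < 0.5:
            raise PhantomConfigError(f"jitter must be in [0, 0.5), got {self.jitter}")
        if self.muscle_radius_vox <= 0:
            raise PhantomConfigError("muscle_radius_vox must be positive")
        if self.muscle_radius_vox * self.enlargement_factor >= min(self.grid_shape) / 4:
            raise PhantomConfigError(
                "muscle_radius_vox * enlargement_factor must stay below "
                f"min(grid_shape)/4 = {min(self.grid_shape) / 4} so muscles fit "
                "inside the orbit")
        unknown = set(self.enlarged_muscles) - set(MUSCLES)
        if unknown:
            raise PhantomConfigError(
                f"unknown muscle name(s) {sorted(unknown)}; valid: {MUSCLES}")


@dataclass
class HUVolume:
    """A rank-3 grid of Hounsfield-unit values plus acquisition metadata."""

    values: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    laterality: str = "unknown"

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float32)
        if self.values.ndim != 3 or self.values.size == 0:
            raise ValueError("HUVolume.values must be a non-empty rank-3 grid")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("HUVolume.values must be finite")
        if self.laterality not in ("left", "right", "unknown"):
            raise ValueError(f"invalid laterality {self.laterality!r}")

    @property
    def shape(self):
        return self.values.shape


def _geometry(spec: PhantomSpec, label: str, seed: int, laterality: str):
    """Deterministic masks for shell, globe and each muscle, plus HU palette."""
    if label not in ("normal", "abnormal"):
        raise PhantomConfigError(f"label must be 'normal' or 'abnormal', got {label!r}")
    rng = np.random.default_rng(seed)
    ns, nr, nc = spec.grid_shape
    j = spec.jitter

    def u():  # one jitter draw in [-j, j]
        return float(rng.uniform(-j, j))

    cy = nr / 2.0 * (1.0 + 0.2 * u())
    cx = nc / 2.0 * (1.0 + 0.2 * u())
    zz = np.arange(ns, dtype=np.float64)[:, None, None]
    yy = np.arange(nr, dtype=np.float64)[None, :, None] - cy
    xx = np.arange(nc, dtype=np.float64)[None, None, :] - cx
    rr = np.sqrt(yy ** 2 + xx ** 2)
    t = zz / max(ns - 1, 1)  # 0 anterior -> 1 posterior

    # bony shell: annulus whose radius funnels toward the apex
    r_out = 0.45 * min(nr, nc) * (1.0 + u()) * (1.0 - 0.45 * t)
    shell = (rr >= r_out - 3.0) & (rr < r_out)

    # globe: sphere in the anterior third
    g_r = 0.16 * min(nr, nc) * (1.0 + u())
    g_z = 0.18 * ns * (1.0 + u())
    globe = (zz - g_z) ** 2 + yy ** 2 + xx ** 2 < g_r ** 2

    # muscles: tapered tubes along the slice axis on a ring between globe
    # and shell; inferior at the bottom (rows grow downward)
    sign_lat = 1.0 if laterality == "right" else -1.0
    angles = {"inferior": (1.0, 0.0), "superior": (-1.0, 0.0),
              "medial": (0.0, -sign_lat), "lateral": (0.0, sign_lat)}
    z0, z1 = 0.25 * ns, 0.95 * ns
    span = (zz >= z0) & (zz <= z1)
    taper = 1.0 - 0.5 * np.clip((zz - z0) / max(z1 - z0, 1e-9), 0.0, 1.0)
    ring = 0.55 * (r_out - 3.0)

    muscle_masks = {}
    for m in MUSCLES:
        dy, dx = angles[m]
        base = spec.muscle_radius_vox * (1.0 + u())
        off = u() * 2.0  # small positional wobble, voxels
        if label == "abnormal" and m in spec.enlarged_muscles:
            base *= spec.enlargement_factor
        my = cy + dy * ring + (off if dx else 0.0)
        mx = cx + dx * ring + (off if dy else 0.0)
        dist2 = (np.arange(nr)[None, :, None] - my) ** 2 + \
                (np.arange(nc)[None, None, :] - mx) ** 2
        muscle_masks[m] = span & (dist2 < (base * taper) ** 2)

    palette = {"background": spec.background_hu * (1.0 + u()),
               "bone": spec.bone_hu * (1.0 + u()),
               "globe": spec.globe_hu * (1.0 + u()),
               "muscle": spec.muscle_hu * (1.0 + u())}
    return shell, globe, muscle_masks, palette, rng


def make_phantom(spec: PhantomSpec, label: str, seed: int,
                 laterality: str = "right",
                 spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)) -> HUVolume:
    """Render one phantom volume; deterministic for fixed (spec, label, seed)."""
    shell, globe, muscles, palette, rng = _geometry(spec, label, seed, laterality)
    vol = np.full(spec.grid_shape, palette["background"], dtype=np.float64)
    vol[shell] = palette["bone"]
    vol[globe] = palette["globe"]
    for m in MUSCLES:  # fixed paint order; later tubes override earlier
        vol[muscles[m]] = palette["muscle"]
    if spec.noise_sd > 0:
        vol += rng.normal(0.0, spec.noise_sd, size=vol.shape)
    return HUVolume(values=vol.astype(np.float32), spacing=spacing,
                    laterality=laterality)


def muscle_mask(spec: PhantomSpec, label: str, seed: int, muscle: str,
                laterality: str = "right") -> np.ndarray:
    """Boolean grid of voxels painted as ``muscle`` in the matching phantom."""
    if muscle not in MUSCLES:
        raise PhantomConfigError(f"unknown muscle {muscle!r}; valid: {MUSCLES}")
    _, _, masks, _, _ = _geometry(spec, label, seed, laterality)
    out = masks[muscle].copy()
    after = MUSCLES[MUSCLES.index(muscle) + 1:]
    for m in after:  # voxels overpainted by later tubes do not belong
        out &= ~masks[m]
    return out


def make_cohort(n_normal: int, n_abnormal: int, spec: PhantomSpec,
                seed: int) -> list[tuple[HUVolume, int]]:
    """n_normal label-0 then n_abnormal label-1 phantoms, reproducibly seeded."""
    if n_normal < 0 or n_abnormal < 0:
        raise PhantomConfigError("cohort counts must be non-negative")
    if n_normal + n_abnormal < 1:
        raise PhantomConfigError("cohort must contain at least one volume")
    out = []
    for i in range(n_normal + n_abnormal):
        label = 0 if i < n_normal else 1
        vol = make_phantom(spec, "normal" if label == 0 else "abnormal",
                           seed=mix_seed(seed, i))
        out.append((vol, label))
    return out


def cohort_manifest(cohort_seed: int, n_normal: int, n_abnormal: int) -> pd.DataFrame:
    """Filename/label/seed table for a cohort written to disk."""
    rows = []
    for i in range(n_normal + n_abnormal):
        label = 0 if i < n_normal else 1
        rows.append({"filename": f"phantom_{i:04d}.nii.gz", "label": label,
                     "seed": mix_seed(cohort_seed, i)})
    return pd.DataFrame(rows)
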