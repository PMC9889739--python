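"""Volume and manifest I/O: NIfTI, DICOM series, CSV tables."""

from __future__ import annotations

from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .phantom import HUVolume


def save_nifti(vol: HUVolume | np.ndarray, path) -> None:
    """Write a volume as NIfTI with voxel spacing in the affine."""
    if isinstance(vol, HUVolume):
        values, spacing, lat = vol.values, vol.spacing, vol.laterality
    else:
        values, spacing, lat = np.asarray(vol), (1.0, 1.0, 1.0), "unknown"
    affine = np.diag(list(spacing) + [1.0])
    img = nib.Nifti1Image(np.asarray(values, dtype=np.float32), affine)
    img.header.set_zooms(spacing)
    img.header["descrip"] = f"laterality={lat}".encode()
    nib.save(img, str(path))


def load_nifti(path) -> HUVolume:
    img = nib.load(str(path))
    values = np.asarray(img.get_fdata(), dtype=np.float32)
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    desc = bytes(img.header["descrip"].tobytes()).split(b"\x00")[0].decode(
        errors="replace")
    lat = "unknown"
    if "laterality=" in desc:
        cand = desc.split("laterality=")[1].strip()
        if cand in ("left", "right"):
            lat = cand
    return HUVolume(values=values, spacing=spacing, laterality=lat)


def load_dicom_series(directory) -> HUVolume:
    """Read a single-series DICOM directory into HU, slices sorted spatially.

    Applies RescaleSlope/RescaleIntercept; slice order follows
    ImagePositionPatient along the slice normal when present, falling
    back to InstanceNumber.
    """
    import pydicom

    directory = Path(directory)
    files = sorted(p for p in directory.iterdir() if p.is_file())
    if not files:
        raise FileNotFoundError(f"no DICOM files in {directory}")
    dsets = [pydicom.dcmread(str(p)) for p in files]

    def sort_key(ds):
        pos = getattr(ds, "ImagePositionPatient", None)
        if pos is not None and len(pos) == 3:
            return float(pos[2])
        return float(getattr(ds, "InstanceNumber", 0))

    dsets.sort(key=sort_key)
    slices = []
    for ds in dsets:
        arr = ds.pixel_array.astype(np.float32)
        slope = float(getattr(ds, "RescaleSlope", 1.0))
        intercept = float(getattr(ds, "RescaleIntercept", 0.0))
        slices.append(arr * slope + intercept)
    first = dsets[0]
    px = getattr(first, "PixelSpacing", [1.0, 1.0])
    dz = float(getattr(first, "SliceThickness", 1.0))
    return HUVolume(values=np.stack(slices, axis=0),
                    spacing=(dz, float(px[0]), float(px[1])))


def load_volume(path) -> HUVolume:
    """Dispatch on path type: directory -> DICOM series, file -> NIfTI."""
    path = Path(path)
    if path.is_dir():
        return load_dicom_series(path)
    return load_nifti(path)


def write_manifest(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False)


def read_manifest(path) -> pd.DataFrame:
    return pd.read_csv(path)
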