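"""File-format glue: NIfTI volumes/masks, TIFF/PNG patches, CSV tables."""

from __future__ import annotations

from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
import tifffile

from .radiomics.types import ImageVolume


def save_nifti(vol: ImageVolume | np.ndarray, path: str | Path,
               spacing=(1.0, 1.0, 1.0)) -> None:
    if isinstance(vol, ImageVolume):
        values, spacing = vol.values, vol.spacing
    else:
        values = np.asarray(vol, dtype=float)
    affine = np.diag(list(spacing) + [1.0])
    nib.save(nib.Nifti1Image(values.astype(np.float32), affine), str(path))


def load_nifti(path: str | Path) -> ImageVolume:
    img = nib.load(str(path))
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    return ImageVolume(np.asarray(img.dataobj, dtype=float), spacing)


def load_nifti_mask(path: str | Path) -> np.ndarray:
    return np.asarray(nib.load(str(path)).dataobj) > 0.5


def save_rgb(patch: np.ndarray, path: str | Path) -> None:
    tifffile.imwrite(str(path), np.asarray(patch, dtype=np.uint8))


def load_rgb(path: str | Path) -> np.ndarray:
    return tifffile.imread(str(path))


def save_labels(label_mask: np.ndarray, path: str | Path) -> None:
    tifffile.imwrite(str(path), np.asarray(label_mask, dtype=np.uint16))


def load_labels(path: str | Path) -> np.ndarray:
    return tifffile.imread(str(path)).astype(np.int64)


def save_table(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(str(path))


def load_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(str(path), index_col=0)
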