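"""Numeric feature extraction over a multi-sequence MRI study.

Given preprocessed volumes (one per sequence, already gray-standardized and on
an isotropic grid) plus a shared ROI mask, computes the implemented texture
families (first-order, GLCM, GLRLM, GLDM) on the original image, the 8
decimated wavelet subbands, and the 3 LoG scales.  Catalog entries for
families without numeric extraction (shape, GLSZM, NGTDM) are returned as NaN,
an explicit "enumerated but not computed" marker.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import texture
from .catalog import (
    IMPLEMENTED_FAMILIES,
    LOG_SIGMAS_MM,
    FeatureCatalog,
    enumerate_catalog,
    image_type_names,
)
from .preprocess import (
    discretize,
    downsample_mask,
    log_filter,
    pad_to_even,
    wavelet_subbands,
)
from .types import ImageVolume

_FAMILY_FUNCS = {
    "glcm": texture.glcm_features,
    "glrlm": texture.glrlm_features,
    "gldm": texture.gldm_features,
}


def _derived_images(
    vol: ImageVolume, mask: np.ndarray, image_types: tuple[str, ...]
) -> dict[str, tuple[ImageVolume, np.ndarray]]:
    """Map image-type name -> (derived volume, matching mask)."""
    out: dict[str, tuple[ImageVolume, np.ndarray]] = {}
    if "original" in image_types:
        out["original"] = (vol, mask)
    wanted_wav = [t for t in image_types if t.startswith("wavelet-")]
    if wanted_wav:
        padded = ImageVolume(
            pad_to_even(vol.values, edge=True), vol.spacing, vol.origin
        )
        sub = wavelet_subbands(padded)
        wmask = downsample_mask(mask)
        for t in wanted_wav:
            out[t] = (sub[t.split("-", 1)[1]], wmask)
    for t in image_types:
        if t.startswith("log-sigma"):
            sigma = float(t.split("-")[2] + "." + t.split("-")[3])
            out[t] = (log_filter(vol, sigma), mask)
    return out


def extract_features(
    volumes: dict[str, ImageVolume],
    mask: np.ndarray,
    catalog: FeatureCatalog | None = None,
    *,
    n_bins: int = 25,
    image_types: tuple[str, ...] | None = None,
) -> pd.Series:
    """Extract one FeatureTable row (a Series indexed by catalog identifiers).

    Parameters
    ----------
    volumes
        Mapping of sequence name (e.g. ``"T1"``) to preprocessed volume.
    mask
        Boolean ROI mask on the same grid as every volume.
    catalog
        Catalog restricting what is extracted; defaults to the full catalog
        over the supplied sequences.
    image_types
        Optional further restriction of derived images (e.g. only
        ``("original",)`` for quick studies).
    """
    mask = np.asarray(mask, dtype=bool)
    for seq, vol in volumes.items():
        if vol.shape != mask.shape:
            raise ValueError(f"mask/volume grid mismatch for sequence {seq!r}")
    if catalog is None:
        catalog = enumerate_catalog(tuple(volumes))
    types_present = tuple(
        t for t in image_type_names()
        if (image_types is None or t in image_types)
    )
    values: dict[str, float] = {}
    for seq, vol in volumes.items():
        derived = _derived_images(vol, mask, types_present)
        for img_type, (dvol, dmask) in derived.items():
            want = catalog.subset(sequence=seq, image_type=img_type)
            fams = {e.family for e in want} & set(IMPLEMENTED_FAMILIES)
            if not fams:
                continue
            if "firstorder" in fams:
                fo = texture.firstorder_features(dvol, dmask, n_bins=n_bins)
                for name, v in fo.items():
                    values[f"{seq}_{img_type}_firstorder_{name}"] = v
            matrix_fams = fams - {"firstorder"}
            if matrix_fams:
                d = discretize(dvol, dmask, n_bins=n_bins)
                for fam in sorted(matrix_fams):
                    for name, v in _FAMILY_FUNCS[fam](d).items():
                        values[f"{seq}_{img_type}_{fam}_{name}"] = v
    row = pd.Series(
        [values.get(fid, np.nan) for fid in catalog.identifiers],
        index=catalog.identifiers,
        dtype=float,
    )
    return row


def extract_feature_table(
    studies: dict[str, dict[str, ImageVolume]],
    masks: dict[str, np.ndarray],
    catalog: FeatureCatalog | None = None,
    **kwargs,
) -> pd.DataFrame:
    """Extract rows for many patients; index = patient id."""
    rows = {}
    for pid, vols in studies.items():
        rows[pid] = extract_features(vols, masks[pid], catalog, **kwargs)
    return pd.DataFrame(rows).T
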