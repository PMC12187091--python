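"""Volume preprocessing: gray-value standardization, resampling, discretization,
and the wavelet / Laplacian-of-Gaussian derived images.

The preprocessing chain mirrors common radiomics practice: intensities are
min-max standardized to [0, 255], volumes are resampled to an isotropic
1 x 1 x 1 mm grid with a cubic B-spline interpolator (masks nearest-neighbor),
and ROI intensities are discretized to a fixed number of bins (default 25)
over the ROI min-max range before any texture matrix is built.
"""

from __future__ import annotations

import warnings

import numpy as np
import pywt
import SimpleITK as sitk
from scipy import ndimage

from .types import DiscretizedROI, ImageVolume

#: Subband label alphabet: L = low-pass (approximation), H = high-pass (detail).
WAVELET_SUBBANDS = ("LLL", "LLH", "LHL", "LHH", "HLL", "HLH", "HHL", "HHH")


def standardize_gray(vol: ImageVolume, low: float = 0.0, high: float = 255.0) -> ImageVolume:
    """Min-max rescale intensities to [low, high].

    A constant volume has no dynamic range; it maps to ``low`` everywhere and a
    warning is emitted.
    """
    v = vol.values
    vmin, vmax = float(v.min()), float(v.max())
    if vmax == vmin:
        warnings.warn("constant volume: gray standardization maps all voxels to the lower bound")
        out = np.full_like(v, low)
    else:
        out = (v - vmin) / (vmax - vmin) * (high - low) + low
    return ImageVolume(out, vol.spacing, vol.origin)


def _to_sitk(values: np.ndarray, spacing, origin) -> sitk.Image:
    # SimpleITK uses (z, y, x) array order; our arrays are (x, y, z).
    img = sitk.GetImageFromArray(np.ascontiguousarray(values.transpose(2, 1, 0)))
    img.SetSpacing(tuple(float(s) for s in spacing))
    img.SetOrigin(tuple(float(o) for o in origin))
    return img


def _from_sitk(img: sitk.Image) -> np.ndarray:
    return sitk.GetArrayFromImage(img).transpose(2, 1, 0)


def resample(
    vol: ImageVolume,
    target_spacing: tuple[float, float, float] = (1.0, 1.0, 1.0),
    *,
    is_mask: bool = False,
) -> ImageVolume:
    """Resample onto ``target_spacing`` (cubic B-spline; masks nearest-neighbor).

    Output grid size is ``round(size * spacing / target)`` per axis (at least 1),
    so a volume already on the target grid is returned unchanged in shape.
    """
    if tuple(vol.spacing) == tuple(target_spacing):
        return ImageVolume(vol.values.copy(), vol.spacing, vol.origin)
    new_size = [
        max(1, int(round(n * s / t)))
        for n, s, t in zip(vol.shape, vol.spacing, target_spacing)
    ]
    img = _to_sitk(vol.values, vol.spacing, vol.origin)
    rs = sitk.ResampleImageFilter()
    rs.SetOutputSpacing(tuple(float(t) for t in target_spacing))
    rs.SetSize([int(n) for n in new_size])
    rs.SetOutputOrigin(img.GetOrigin())
    rs.SetOutputDirection(img.GetDirection())
    rs.SetInterpolator(sitk.sitkNearestNeighbor if is_mask else sitk.sitkBSpline)
    out = _from_sitk(rs.Execute(img))
    if is_mask:
        out = (out > 0.5).astype(float)
    return ImageVolume(out, tuple(target_spacing), vol.origin)


def normalize_and_resample(
    vol: ImageVolume,
    target_spacing: tuple[float, float, float] = (1.0, 1.0, 1.0),
) -> ImageVolume:
    """Gray standardization to [0, 255] followed by isotropic resampling."""
    return resample(standardize_gray(vol), target_spacing)


def discretize(
    vol: ImageVolume | np.ndarray,
    mask: np.ndarray,
    n_bins: int = 25,
) -> DiscretizedROI:
    """Fixed-bin-count discretization of ROI intensities.

    Bins are ``n_bins`` equal-width intervals over [min, max] of the ROI
    intensities, with the top edge inclusive, yielding integer levels
    1..n_bins.  A constant ROI collapses to the single level 1.
    """
    values = vol.values if isinstance(vol, ImageVolume) else np.asarray(vol, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    if values.shape != mask.shape:
        raise ValueError("volume/mask grid mismatch")
    if not mask.any():
        raise ValueError("empty ROI mask")
    roi = values[mask]
    vmin, vmax = float(roi.min()), float(roi.max())
    levels = np.zeros(values.shape, dtype=np.int64)
    if vmax == vmin:
        edges = np.array([vmin, vmax])
        levels[mask] = 1
        return DiscretizedROI(levels, mask, n_bins, edges)
    edges = np.linspace(vmin, vmax, n_bins + 1)
    lv = np.digitize(roi, edges[1:-1], right=False) + 1
    levels[mask] = lv
    return DiscretizedROI(levels, mask, n_bins, edges)


def wavelet_subbands(vol: ImageVolume, wavelet: str = "haar") -> dict[str, ImageVolume]:
    """Single-level 3-D separable orthonormal wavelet decomposition.

    Returns the 8 decimated subbands labeled ``LLL`` .. ``HHH``; letter *i* of
    the label is the filter (L low-pass / H high-pass) applied along axis *i*
    in (x, y, z) order.  Periodization boundary handling keeps the transform
    orthonormal, so summed squared coefficients over the 8 subbands equal the
    summed squared input exactly (Parseval).  Subbands have halved grid
    dimensions and doubled spacing.
    """
    v = vol.values
    if any(n < 2 for n in v.shape):
        raise ValueError("wavelet decomposition requires every dimension >= 2")
    if any(n % 2 for n in v.shape):
        raise ValueError("wavelet decomposition requires even dimensions (pad first)")
    coeffs = pywt.dwtn(v, wavelet, mode="periodization", axes=(0, 1, 2))
    spacing = tuple(2.0 * s for s in vol.spacing)
    out: dict[str, ImageVolume] = {}
    for key, arr in coeffs.items():
        label = "".join("L" if c == "a" else "H" for c in key)
        out[label] = ImageVolume(arr, spacing, vol.origin)
    return {label: out[label] for label in WAVELET_SUBBANDS}


def pad_to_even(values: np.ndarray, *, edge: bool) -> np.ndarray:
    """Pad trailing voxels so every dimension is even (edge-replicate or zero)."""
    pads = [(0, n % 2) for n in values.shape]
    if not any(p[1] for p in pads):
        return values
    mode = "edge" if edge else "constant"
    return np.pad(values, pads, mode=mode)


def downsample_mask(mask: np.ndarray) -> np.ndarray:
    """Block-majority 2x downsampling of a binary mask (for decimated subbands).

    A coarse voxel is inside when at least half of its 2x2x2 block is inside;
    if that empties a non-empty mask, falls back to block-any.
    """
    m = pad_to_even(np.asarray(mask, dtype=bool), edge=False)
    blocks = m.reshape(
        m.shape[0] // 2, 2, m.shape[1] // 2, 2, m.shape[2] // 2, 2
    ).sum(axis=(1, 3, 5))
    out = blocks >= 4
    if not out.any() and blocks.any():
        out = blocks > 0
    return out


def log_filter(vol: ImageVolume, sigma_mm: float) -> ImageVolume:
    """Laplacian-of-Gaussian response at spatial scale ``sigma_mm``.

    Requires isotropic spacing (resample first); the Gaussian scale is
    converted from millimetres to voxels via the spacing.  Boundary handling
    is reflective ('nearest' replication), so a constant volume maps to ~0
    response everywhere including edges.
    """
    if not vol.is_isotropic():
        raise ValueError("LoG filtering requires isotropic spacing; resample first")
    if sigma_mm <= 0:
        raise ValueError("sigma must be positive")
    sigma_vox = sigma_mm / vol.spacing[0]
    # gaussian_laplace returns spatial-derivative units of 1/voxel^2; rescale
    # to 1/mm^2 so the response is expressed at the physical scale.
    # truncate at 8 sigma so the discrete derivative weights sum to ~0 and a
    # constant field maps to ~0 response
    out = ndimage.gaussian_laplace(vol.values, sigma=sigma_vox, mode="nearest", truncate=8.0)
    out = out / (vol.spacing[0] ** 2)
    return ImageVolume(out, vol.spacing, vol.origin)
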