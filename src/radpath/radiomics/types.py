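"""Core grid containers for volumetric radiomics.

An :class:`ImageVolume` is a 3-D scalar grid with physical spacing metadata
(millimetres per voxel along each axis) and a world origin.  Voxel indices are
0-based; the world coordinate of voxel ``(i, j, k)`` is
``origin + index * spacing``.  Masks are boolean arrays on the same grid.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class ImageVolume:
    """3-D scalar image with spacing (mm) and origin (mm) metadata."""

    values: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3:
            raise ValueError("ImageVolume requires a 3-D array")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("ImageVolume values must be finite")
        self.spacing = tuple(float(s) for s in self.spacing)
        if any(s <= 0 for s in self.spacing):
            raise ValueError("spacing must be positive")
        self.origin = tuple(float(o) for o in self.origin)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape  # type: ignore[return-value]

    @property
    def voxel_volume(self) -> float:
        return float(np.prod(self.spacing))

    def is_isotropic(self, tol: float = 1e-9) -> bool:
        s = self.spacing
        return abs(s[0] - s[1]) <= tol and abs(s[1] - s[2]) <= tol


@dataclass
class DiscretizedROI:
    """Integer gray levels (1..n_bins) for ROI voxels; 0 outside the mask.

    ``levels`` shares the grid of the source volume; ``bin_edges`` are the
    n_bins+1 edges used for the fixed-bin-count discretization over the ROI
    intensity range (top edge inclusive).
    """

    levels: np.ndarray
    mask: np.ndarray
    n_bins: int
    bin_edges: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        self.levels = np.asarray(self.levels, dtype=np.int64)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.levels.shape != self.mask.shape:
            raise ValueError("levels/mask shape mismatch")
        inside = self.levels[self.mask]
        if inside.size and (inside.min() < 1 or inside.max() > self.n_bins):
            raise ValueError("ROI levels must lie in 1..n_bins")

    @property
    def roi_levels(self) -> np.ndarray:
        """Flat array of levels for ROI voxels."""
        return self.levels[self.mask]
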