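"""Feature catalog enumeration.

The catalog lists every feature identifier produced per patient:
``{sequence}_{image_type}_{family}_{name}``, e.g.
``T2_wavelet-LHL_firstorder_Median`` or ``T1C_log-sigma-5-0-mm-3D_glcm_Imc2``.

Shape features are defined only on the original image; every non-shape family
is replicated over the original image, the 8 wavelet subbands, and the 3 LoG
scales, giving 107 original + 744 wavelet + 279 LoG = 1,130 identifiers per
MRI sequence and 3,390 for the three sequences together.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterator, NamedTuple

from .preprocess import WAVELET_SUBBANDS
from .texture import (
    FIRSTORDER_FEATURES,
    GLCM_FEATURES,
    GLDM_FEATURES,
    GLRLM_FEATURES,
)

SEQUENCES = ("T1", "T2", "T1C")
LOG_SIGMAS_MM = (1.0, 3.0, 5.0)

SHAPE_FEATURES = (
    "Elongation", "Flatness", "LeastAxisLength", "MajorAxisLength",
    "Maximum2DDiameterColumn", "Maximum2DDiameterRow", "Maximum2DDiameterSlice",
    "Maximum3DDiameter", "MeshVolume", "MinorAxisLength", "Sphericity",
    "SurfaceArea", "SurfaceVolumeRatio", "VoxelVolume",
)
GLSZM_FEATURES = (
    "GrayLevelNonUniformity", "GrayLevelNonUniformityNormalized",
    "GrayLevelVariance", "HighGrayLevelZoneEmphasis", "LargeAreaEmphasis",
    "LargeAreaHighGrayLevelEmphasis", "LargeAreaLowGrayLevelEmphasis",
    "LowGrayLevelZoneEmphasis", "SizeZoneNonUniformity",
    "SizeZoneNonUniformityNormalized", "SmallAreaEmphasis",
    "SmallAreaHighGrayLevelEmphasis", "SmallAreaLowGrayLevelEmphasis",
    "ZoneEntropy", "ZonePercentage", "ZoneVariance",
)
NGTDM_FEATURES = ("Busyness", "Coarseness", "Complexity", "Contrast", "Strength")

#: family name -> feature name tuple
FAMILIES: dict[str, tuple[str, ...]] = {
    "shape": SHAPE_FEATURES,
    "firstorder": FIRSTORDER_FEATURES,
    "glcm": GLCM_FEATURES,
    "gldm": GLDM_FEATURES,
    "glrlm": GLRLM_FEATURES,
    "glszm": GLSZM_FEATURES,
    "ngtdm": NGTDM_FEATURES,
}

#: families with numeric extraction; shape/glszm/ngtdm are catalog-only.
IMPLEMENTED_FAMILIES = ("firstorder", "glcm", "gldm", "glrlm")

NONSHAPE_FAMILIES = ("firstorder", "glcm", "gldm", "glrlm", "glszm", "ngtdm")


def image_type_names() -> tuple[str, ...]:
    wav = tuple(f"wavelet-{s}" for s in WAVELET_SUBBANDS)
    log = tuple(
        "log-sigma-{}-{}-mm-3D".format(*str(float(s)).split(".")) for s in LOG_SIGMAS_MM
    )
    return ("original",) + wav + log


class FeatureID(NamedTuple):
    sequence: str
    image_type: str
    family: str
    name: str

    @property
    def identifier(self) -> str:
        return f"{self.sequence}_{self.image_type}_{self.family}_{self.name}"


@dataclass(frozen=True)
class FeatureCatalog:
    """Ordered, unique list of feature identifiers."""

    entries: tuple[FeatureID, ...]

    def __post_init__(self) -> None:
        ids = [e.identifier for e in self.entries]
        if len(set(ids)) != len(ids):
            raise ValueError("catalog identifiers must be unique")

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self) -> Iterator[FeatureID]:
        return iter(self.entries)

    @property
    def identifiers(self) -> list[str]:
        return [e.identifier for e in self.entries]

    def subset(self, **match: object) -> "FeatureCatalog":
        """Filter by field value(s), e.g. ``subset(sequence="T2", family="glcm")``.

        A tuple/list/set value matches any of its members.
        """
        def ok(e: FeatureID) -> bool:
            for k, v in match.items():
                attr = getattr(e, k)
                if isinstance(v, (tuple, list, set, frozenset)):
                    if attr not in v:
                        return False
                elif attr != v:
                    return False
            return True

        return FeatureCatalog(tuple(e for e in self.entries if ok(e)))


def enumerate_catalog(sequences: tuple[str, ...] = SEQUENCES) -> FeatureCatalog:
    """Enumerate the full per-patient feature catalog (3,390 identifiers)."""
    entries: list[FeatureID] = []
    for seq in sequences:
        for img in image_type_names():
            families = tuple(FAMILIES) if img == "original" else NONSHAPE_FAMILIES
            for family in families:
                for name in FAMILIES[family]:
                    entries.append(FeatureID(seq, img, family, name))
    return FeatureCatalog(tuple(entries))
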