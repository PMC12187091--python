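"""Generate an MRI phantom and extract its radiomic feature row.

Builds a 24^3 phantom with a spherical tumor ROI whose texture is a Gaussian
random field, then runs the full per-sequence extraction (first-order, GLCM,
GLRLM, GLDM over the original image, 8 wavelet subbands and 3 LoG scales).
"""

import numpy as np

from radpath.radiomics import enumerate_catalog, extract_features
from radpath.synthetic import PhantomSpec, generate_phantom

spec = PhantomSpec(seed=7)
vol, mask = generate_phantom(spec)
print(f"phantom shape {vol.shape}, ROI voxels {int(mask.sum())}")

catalog = enumerate_catalog(("T2",))
row = extract_features({"T2": vol}, mask, catalog)
print(f"catalog identifiers per sequence: {len(catalog)}")
print(f"numerically extracted: {int(row.notna().sum())} "
      "(shape/GLSZM/NGTDM are enumerated but not computed)")

for fid in (
    "T2_original_firstorder_Median",
    "T2_original_glcm_Autocorrelation",
    "T2_wavelet-LHL_firstorder_Median",
    "T2_log-sigma-3-0-mm-3D_glcm_Imc2",
):
    print(f"{fid:45s} {row[fid]: .4f}")
# The first-order Median sits near the ROI's planted mean intensity; GLCM
# Autocorrelation rises with the planted spatial correlation length.
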