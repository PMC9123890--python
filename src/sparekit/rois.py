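"""Default region-of-interest (ROI) parcellation used by the synthetic cohort.

The feature space is a fixed, ordered list of 145 named brain regions
(grey matter, white matter and ventricular CSF parcels) whose volumes in
mm^3 are the inputs to every SPARE model.  The default synthetic cohort
plants three kinds of structure on these regions:

* an *age-affected* subset whose volumes drift linearly with age,
* an *AD-affected* subset whose volumes shift with latent disease
  severity, overlapping the age-affected subset in a configurable
  number of regions, and
* a remainder that carries measurement noise only.

The anatomical names below are purely for readability of outputs; the
volumes attached to them are synthetic.
"""

from __future__ import annotations

N_ROIS = 145

# Regions affected by typical ageing only (25).
AGE_ONLY_ROIS = [
    "cerebellum_left",
    "cerebellum_right",
    "internal_capsule_anterior_limb_left",
    "internal_capsule_anterior_limb_right",
    "planum_polare_left",
    "planum_polare_right",
    "precentral_gyrus_left",
    "precentral_gyrus_right",
    "thalamus_left",
    "thalamus_right",
    "putamen_left",
    "putamen_right",
    "frontal_white_matter_left",
    "frontal_white_matter_right",
    "lateral_ventricle_left",
    "lateral_ventricle_right",
    "superior_frontal_gyrus_left",
    "superior_frontal_gyrus_right",
    "caudate_left",
    "caudate_right",
    "occipital_pole_left",
    "occipital_pole_right",
    "calcarine_cortex_left",
    "calcarine_cortex_right",
    "cuneus_left",
]

# Regions affected by both ageing and Alzheimer's disease (15).
OVERLAP_ROIS = [
    "hippocampus_left",
    "hippocampus_right",
    "middle_temporal_gyrus_left",
    "middle_temporal_gyrus_right",
    "inferior_lateral_ventricle_left",
    "inferior_lateral_ventricle_right",
    "amygdala_left",
    "amygdala_right",
    "anterior_insula_left",
    "anterior_insula_right",
    "fusiform_gyrus_left",
    "fusiform_gyrus_right",
    "precuneus_left",
    "precuneus_right",
    "posterior_cingulate_left",
]

# Regions affected by Alzheimer's disease only (15).
AD_ONLY_ROIS = [
    "entorhinal_area_left",
    "entorhinal_area_right",
    "parahippocampal_gyrus_left",
    "parahippocampal_gyrus_right",
    "inferior_temporal_gyrus_left",
    "inferior_temporal_gyrus_right",
    "temporal_pole_left",
    "temporal_pole_right",
    "angular_gyrus_left",
    "angular_gyrus_right",
    "supramarginal_gyrus_left",
    "supramarginal_gyrus_right",
    "posterior_cingulate_right",
    "superior_temporal_gyrus_left",
    "superior_temporal_gyrus_right",
]

_N_FILLER = N_ROIS - len(AGE_ONLY_ROIS) - len(OVERLAP_ROIS) - len(AD_ONLY_ROIS)
FILLER_ROIS = [f"gm_parcel_{i:03d}" for i in range(1, _N_FILLER + 1)]

#: Canonical column order of the ROI matrix.
DEFAULT_ROI_NAMES = AGE_ONLY_ROIS + OVERLAP_ROIS + AD_ONLY_ROIS + FILLER_ROIS

assert len(DEFAULT_ROI_NAMES) == N_ROIS
assert len(set(DEFAULT_ROI_NAMES)) == N_ROIS


def is_ventricle(name: str) -> bool:
    """CSF spaces expand (rather than shrink) with age and disease."""
    return "ventricle" in name
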