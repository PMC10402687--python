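"""Bundled benchmark dataset: dental-material DECT characterisation.

Measured mean values (and standard deviations) of CT number (CTN), relative
electron density (RED), effective atomic number (EAN), and mass density (MD)
for ten dental implant/restoration materials, acquired with two dual-energy
CT techniques — sequential acquisition CT (SACT, CTN on the 140 kVp images)
and dual-layer spectral CT (DLCT, CTN on the 120 kVp images) — inside a
46 cm x 8 cm-radius PMMA cylinder. CTN of 3071 HU denotes a saturated
standard Hounsfield scale (no extended scale was used).

Also bundled: the relative residuals (in %) of each SPR-prediction method
against water-column SPR measurements, for the cylindrical-insert study
(``CYLINDER_RESIDUALS``) and for the anthropomorphic head phantom with a
lithium disilicate restoration (``HEAD_RESIDUALS``), plus the handful of
published measured SPR values.

These tables are inputs to the evaluation and acceptance machinery, not
quantities the package computes.
"""

from __future__ import annotations

import pandas as pd

__all__ = [
    "CTN_SATURATION",
    "MATERIAL_PARAMETERS",
    "CYLINDER_RESIDUALS",
    "HEAD_RESIDUALS",
    "MEASURED_SPR",
    "HEAD_MEASURED_SPR",
    "HEAD_PREDICTED_SPR_DE_RHOZ_SACT",
    "HLUT_MAX_SPR",
    "METHODS",
    "cylinder_residuals",
    "head_residuals",
]

#: Upper end of the standard Hounsfield scale; values at this level are saturated.
CTN_SATURATION = 3071.0

#: Per-material radiological parameters by technique. ``ctn_*`` entries of
#: 3071 mean the scale saturated (true attenuation is off-scale). ``*_sd``
#: entries are pooled-voxel standard deviations, used to parameterise the
#: synthetic noise model. ``core_diameter`` (mm) is set where the physical
#: insert was a core surrounded by PMMA; ``z_max`` is the highest atomic
#: number present.
MATERIAL_PARAMETERS: dict[str, dict] = {
    "aluminum": dict(
        ctn_sact=2047.0, ctn_sact_sd=4.0, ctn_dlct=2279.0, ctn_dlct_sd=8.0,
        red_sact=2.423, red_sact_sd=0.002, red_dlct=2.331, red_dlct_sd=0.012,
        ean_sact=12.88, ean_sact_sd=0.05, ean_dlct=13.00, ean_dlct_sd=0.01,
        md_sact=2.578, md_dlct=2.485, artifact="mild", core_diameter=None, z_max=13,
    ),
    "cobalt_chrome": dict(
        ctn_sact=3030.0, ctn_sact_sd=8.0, ctn_dlct=CTN_SATURATION, ctn_dlct_sd=0.0,
        red_sact=3.980, red_sact_sd=0.006, red_dlct=4.049, red_dlct_sd=0.001,
        ean_sact=7.31, ean_sact_sd=0.05, ean_dlct=16.00, ean_dlct_sd=0.01,
        md_sact=4.001, md_dlct=4.516, artifact="severe", core_diameter=10.0, z_max=27,
    ),
    "composite_1": dict(
        ctn_sact=3037.0, ctn_sact_sd=4.0, ctn_dlct=CTN_SATURATION, ctn_dlct_sd=0.0,
        red_sact=3.898, red_sact_sd=0.006, red_dlct=2.072, red_dlct_sd=0.088,
        ean_sact=7.79, ean_sact_sd=0.02, ean_dlct=19.71, ean_dlct_sd=0.49,
        md_sact=3.929, md_dlct=2.376, artifact="severe", core_diameter=10.0, z_max=56,
    ),
    "composite_2": dict(
        ctn_sact=3026.0, ctn_sact_sd=3.0, ctn_dlct=CTN_SATURATION, ctn_dlct_sd=0.0,
        red_sact=3.967, red_sact_sd=0.007, red_dlct=4.049, red_dlct_sd=0.001,
        ean_sact=7.41, ean_sact_sd=0.03, ean_dlct=16.00, ean_dlct_sd=0.01,
        md_sact=3.990, md_dlct=4.516, artifact="severe", core_diameter=10.0, z_max=70,
    ),
    "glass_ceramic": dict(
        ctn_sact=2648.0, ctn_sact_sd=6.0, ctn_dlct=CTN_SATURATION, ctn_dlct_sd=0.0,
        red_sact=3.282, red_sact_sd=0.007, red_dlct=2.342, red_dlct_sd=0.003,
        ean_sact=10.38, ean_sact_sd=0.02, ean_dlct=16.00, ean_dlct_sd=0.01,
        md_sact=3.382, md_dlct=2.612, artifact="mild", core_diameter=10.0, z_max=39,
    ),
    "lithium_disilicate": dict(
        ctn_sact=3069.0, ctn_sact_sd=1.0, ctn_dlct=CTN_SATURATION, ctn_dlct_sd=0.0,
        red_sact=3.991, red_sact_sd=0.022, red_dlct=2.583, red_dlct_sd=0.004,
        ean_sact=7.78, ean_sact_sd=0.11, ean_dlct=17.00, ean_dlct_sd=0.01,
        md_sact=4.023, md_dlct=2.919, artifact="mild", core_diameter=10.0, z_max=40,
    ),
    "pmma": dict(
        ctn_sact=127.0, ctn_sact_sd=1.0, ctn_dlct=125.0, ctn_dlct_sd=2.0,
        red_sact=1.154, red_sact_sd=0.002, red_dlct=1.152, red_dlct_sd=0.001,
        ean_sact=6.38, ean_sact_sd=0.06, ean_dlct=6.50, ean_dlct_sd=0.55,
        md_sact=1.155, md_dlct=1.153, artifact="no", core_diameter=None, z_max=8,
    ),
    "silicone": dict(
        ctn_sact=431.0, ctn_sact_sd=1.0, ctn_dlct=509.0, ctn_dlct_sd=3.0,
        red_sact=1.268, red_sact_sd=0.006, red_dlct=1.259, red_dlct_sd=0.002,
        ean_sact=10.68, ean_sact_sd=0.06, ean_dlct=11.00, ean_dlct_sd=0.01,
        md_sact=1.311, md_dlct=1.307, artifact="no", core_diameter=None, z_max=14,
    ),
    "titanium": dict(
        ctn_sact=3069.0, ctn_sact_sd=1.0, ctn_dlct=CTN_SATURATION, ctn_dlct_sd=0.0,
        red_sact=3.976, red_sact_sd=0.013, red_dlct=4.026, red_dlct_sd=0.014,
        ean_sact=8.09, ean_sact_sd=0.09, ean_dlct=16.00, ean_dlct_sd=0.01,
        md_sact=4.016, md_dlct=4.490, artifact="moderate", core_diameter=None, z_max=22,
    ),
    "zirconium_dioxide": dict(
        ctn_sact=3023.0, ctn_sact_sd=7.0, ctn_dlct=CTN_SATURATION, ctn_dlct_sd=0.0,
        red_sact=4.000, red_sact_sd=0.005, red_dlct=4.049, red_dlct_sd=0.001,
        ean_sact=7.18, ean_sact_sd=0.06, ean_dlct=16.00, ean_dlct_sd=0.01,
        md_sact=4.018, md_dlct=4.516, artifact="severe", core_diameter=10.0, z_max=40,
    ),
}

#: SPR prediction method labels used throughout.
METHODS = ["SE-140-SACT", "DE-DirectSPR-SACT", "DE-RhoZ-SACT", "SE-120-DLCT", "DE-RhoZ-DLCT"]

# Relative residuals (%) of predicted vs measured SPR for the cylindrical
# insert phantom, per material and prediction method.
_CYL = {
    "aluminum":           [-3.08, 5.98, 2.93, -6.29, 3.83],
    "cobalt_chrome":      [-55.68, -31.36, -31.56, -59.69, -35.43],
    "composite_1":        [58.88, 138.78, 139.56, 44.25, 7.52],
    "composite_2":        [47.88, 127.68, 128.78, 34.58, 113.38],
    "glass_ceramic":      [14.67, 55.96, 56.38, 12.89, 3.65],
    "lithium_disilicate": [24.39, 89.79, 89.44, 12.24, 11.53],
    "pmma":               [-6.57, 0.49, 0.68, -6.93, 0.61],
    "silicone":           [1.06, 2.03, 2.28, 1.09, 1.35],
    "titanium":           [-19.92, 19.40, 18.94, -27.74, 14.17],
    "zirconium_dioxide":  [-38.05, -3.31, -3.40, -43.58, -9.59],
}

# Same, for ROIs in the anthropomorphic head phantom (tooth surrogates and
# the 7 mm lithium disilicate restoration).
_HEAD = {
    "tooth_dentin":       [1.53, -0.25, -0.33, 1.53, -0.29],
    "tooth_enamel":       [10.94, -0.58, -0.57, 10.89, -0.97],
    "lithium_disilicate_restoration": [10.91, 35.04, 34.27, 8.42, 0.22],
}

CYLINDER_RESIDUALS = pd.DataFrame.from_dict(_CYL, orient="index", columns=METHODS)
CYLINDER_RESIDUALS.index.name = "material"
HEAD_RESIDUALS = pd.DataFrame.from_dict(_HEAD, orient="index", columns=METHODS)
HEAD_RESIDUALS.index.name = "material"

#: Water-column measured SPR per material. Only PMMA and cobalt-chrome were
#: published (they bracket the measured span 1.169-5.823); the remaining
#: entries are SYNTHETIC literature-typical nominals used solely to give the
#: synthetic generator a ground truth, and carry no benchmark weight.
MEASURED_SPR: dict[str, float] = {
    "pmma": 1.169,               # published
    "cobalt_chrome": 5.823,      # published
    "aluminum": 2.12,            # synthetic nominal
    "composite_1": 1.95,         # synthetic nominal
    "composite_2": 1.90,         # synthetic nominal
    "glass_ceramic": 2.40,       # synthetic nominal
    "lithium_disilicate": 2.10,  # synthetic nominal
    "silicone": 1.23,            # synthetic nominal
    "titanium": 3.13,            # synthetic nominal
    "zirconium_dioxide": 4.80,   # synthetic nominal
}

#: Measured SPR of the head-phantom tooth surrogates (water-column reference).
HEAD_MEASURED_SPR: dict[str, float] = {
    "tooth_dentin": 1.501,
    "tooth_enamel": 1.763,
}

#: DE-RhoZ-SACT predicted SPR means for the tooth surrogates.
HEAD_PREDICTED_SPR_DE_RHOZ_SACT: dict[str, float] = {
    "tooth_dentin": 1.496,
    "tooth_enamel": 1.753,
}

#: Clinical HLUT clamp (maximum SPR) per single-energy profile.
HLUT_MAX_SPR: dict[str, float] = {
    "SE-140-SACT": 2.602,
    "SE-120-DLCT": 2.347,
}


def cylinder_residuals(method: str, exclude: tuple[str, ...] = ()) -> pd.Series:
    """Residual column for one method, optionally excluding materials."""
    col = CYLINDER_RESIDUALS[method]
    return col.drop(index=list(exclude))


def head_residuals(method: str) -> pd.Series:
    """Head-phantom residual column for one method."""
    return HEAD_RESIDUALS[method]
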