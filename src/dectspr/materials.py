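"""Material specifications and bundled material catalogs.

A :class:`MaterialSpec` carries the nominal radiological truth of one
insert material: relative electron density (RED, water = 1), effective
atomic number (EAN), mass density (MD, g/cm3), stopping-power ratio
(SPR, water = 1), and its cylindrical insert geometry.  These truths feed
the synthetic phantom generator and serve as ground truth for every
downstream stage.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional

__all__ = ["MaterialSpec", "PMMA", "WATER", "dental_catalog", "tissue_surrogates"]


@dataclass(frozen=True)
class MaterialSpec:
    """Nominal radiological properties and insert geometry of one material.

    Parameters
    ----------
    name:
        Material label, used as key throughout the pipeline.
    red_nominal:
        Relative electron density (dimensionless, water = 1). Must be > 0.
    ean_nominal:
        Effective atomic number (dimensionless).
    md_nominal:
        Mass density in g/cm3.
    spr_truth:
        Stopping-power ratio relative to water (dimensionless). Must be > 0.
    outer_diameter:
        Insert outer diameter in mm.
    core_diameter:
        Diameter of an inner core of this material in mm, if the insert is
        fabricated as a core surrounded by PMMA; ``None`` for solid inserts.
    z_max:
        Highest atomic number present, used to trigger saturation/streak
        behaviour in the synthetic generator.
    """

    name: str
    red_nominal: float
    ean_nominal: float
    md_nominal: float
    spr_truth: float
    outer_diameter: float = 28.0
    core_diameter: Optional[float] = None
    z_max: int = 8

    def __post_init__(self) -> None:
        if self.red_nominal <= 0:
            raise ValueError(f"{self.name}: red_nominal must be > 0")
        if self.spr_truth <= 0:
            raise ValueError(f"{self.name}: spr_truth must be > 0")
        if self.core_diameter is not None and self.core_diameter > self.outer_diameter:
            raise ValueError(f"{self.name}: core_diameter exceeds outer_diameter")

    def with_(self, **kwargs) -> "MaterialSpec":
        """Return a copy with some fields replaced."""
        return replace(self, **kwargs)


# PMMA as characterised on the dual-layer system: RED 1.152, EAN 6.50,
# MD 1.153 g/cm3, measured SPR 1.169.  The phantom background material.
PMMA = MaterialSpec(
    name="pmma",
    red_nominal=1.152,
    ean_nominal=6.50,
    md_nominal=1.153,
    spr_truth=1.169,
    z_max=8,
)

WATER = MaterialSpec(
    name="water",
    red_nominal=1.0,
    ean_nominal=7.45,
    md_nominal=1.0,
    spr_truth=1.0,
    z_max=8,
)


def dental_catalog(technique: str = "DLCT") -> list[MaterialSpec]:
    """Dental implant/restoration materials as characterised per technique.

    RED/EAN/MD are the per-technique measured means from the bundled study
    dataset (see :mod:`dectspr.datasets`); ``spr_truth`` is the water-column
    measured SPR where published, otherwise a literature-typical nominal
    value (those entries are synthetic stand-ins and marked in the docstring
    of :data:`dectspr.datasets.MEASURED_SPR`).
    """
    from . import datasets

    technique = technique.upper()
    if technique not in ("SACT", "DLCT"):
        raise ValueError("technique must be 'SACT' or 'DLCT'")
    out = []
    for name, row in datasets.MATERIAL_PARAMETERS.items():
        out.append(
            MaterialSpec(
                name=name,
                red_nominal=row[f"red_{technique.lower()}"],
                ean_nominal=row[f"ean_{technique.lower()}"],
                md_nominal=row[f"md_{technique.lower()}"],
                spr_truth=datasets.MEASURED_SPR[name],
                outer_diameter=28.0,
                core_diameter=row["core_diameter"],
                z_max=row["z_max"],
            )
        )
    return out


def tissue_surrogates() -> list[MaterialSpec]:
    """Generic tissue-equivalent surrogate set (electron-density-phantom style).

    Spans lung-like (RED ~0.3) to cortical-bone-like (RED ~1.7).  SPR truths
    are filled in by :func:`dectspr.synthetic.generate_calibration_set` from
    the package's own Bethe model so that generator and predictor share one
    physics; here ``spr_truth`` is seeded with RED as a placeholder.
    """
    rows = [
        # name, md, red, ean
        ("lung_ln300", 0.30, 0.29, 7.65),
        ("lung_ln450", 0.45, 0.44, 7.65),
        ("adipose", 0.94, 0.925, 6.21),
        ("breast", 0.98, 0.955, 6.93),
        ("water", 1.00, 1.00, 7.45),
        ("solid_water", 1.015, 0.99, 7.60),
        ("liver", 1.095, 1.06, 7.60),
        ("inner_bone", 1.14, 1.09, 10.40),
        ("b200_bone", 1.15, 1.10, 10.40),
        ("cb2_30", 1.34, 1.28, 10.90),
        ("cb2_50", 1.56, 1.47, 12.50),
        ("cortical_bone", 1.82, 1.69, 13.60),
    ]
    return [
        MaterialSpec(name=n, red_nominal=red, ean_nominal=ean, md_nominal=md,
                     spr_truth=red, z_max=20 if ean > 10 else 8)
        for (n, md, red, ean) in rows
    ]
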