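"""Synthetic phantom, head-slab and Bragg-curve generators.

Every input of the pipeline can be generated here with known ground truth:

* a PMMA cylinder phantom (46 cm long, 8 cm radius by default) with
  cylindrical dental-material inserts stacked along the bore, imaged as
  co-registered CTN/RED/EAN volumes for either DECT technique, including
  Hounsfield-scale saturation at 3071 HU and phenomenological streak
  artifacts around high-Z inserts;
* a water-equivalent head slab with a removable tooth (7 mm sphere or a
  1 mm crown cap) on a PMMA base, with the truth SPR map;
* pristine Bragg curves with controllable range and straggling;
* a tissue-surrogate calibration set whose RED/EAN/SPR/CTN truths all come
  from the package's own forward models.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.ndimage import gaussian_filter1d

from .bragg import DepthDoseCurve
from .materials import MaterialSpec, PMMA, tissue_surrogates
from .spectrum import DEFAULT_SPECTRA, HU_MAX, HU_MIN, SpectrumModel
from .spr import BeamSpec, IValueModel, SPRMap, bethe_spr

__all__ = [
    "NoiseModel",
    "PhantomLayout",
    "SpectralImageSet",
    "HeadPhantom",
    "TECHNIQUE_KVPS",
    "forward_ctn",
    "generate_insert_phantom",
    "generate_head_slab",
    "generate_bragg_curve",
    "generate_calibration_set",
]

#: CTN volumes produced per acquisition technique.
TECHNIQUE_KVPS = {"SACT": ("80kVp", "140kVp"), "DLCT": ("120kVp",)}

# Air values used outside the phantom body.
_AIR_RED = 0.001
_AIR_EAN = 7.64


@dataclass(frozen=True)
class NoiseModel:
    """Additive noise and streak-artifact parameters for the generator.

    ``ctn_sd``/``red_sd``/``ean_sd`` are Gaussian SDs per map; streaks are
    radial sinusoidal HU perturbations seeded at high-Z inserts with
    amplitude ``streak_amplitude`` and ``streak_count`` angular lobes.
    Identical ``seed`` gives identical output.
    """

    ctn_sd: float = 0.0
    red_sd: float = 0.0
    ean_sd: float = 0.0
    streak_amplitude: float = 0.0
    streak_count: int = 8
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.ctn_sd, self.red_sd, self.ean_sd, self.streak_amplitude) < 0:
            raise ValueError("noise SDs and streak amplitude must be >= 0")


@dataclass(frozen=True)
class PhantomLayout:
    """Geometry of the one-bore cylindrical insert phantom.

    Inserts are coaxial cylinders stacked along the phantom (z) axis at
    ``insert_positions`` (mm, start of each insert), each ``insert_length``
    mm long, separated by ``insert_spacing`` when positions are derived
    automatically.
    """

    cylinder_radius: float = 80.0
    cylinder_height: float = 460.0
    background: MaterialSpec = PMMA
    insert_spacing: float = 80.0
    insert_length: float = 20.0
    voxel_spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    insert_positions: Optional[tuple[float, ...]] = None

    def __post_init__(self) -> None:
        if self.cylinder_radius <= 0 or self.cylinder_height <= 0:
            raise ValueError("cylinder dimensions must be positive")
        if self.insert_spacing < 0:
            raise ValueError("insert spacing must be >= 0")

    def positions_for(self, n_inserts: int) -> tuple[float, ...]:
        if self.insert_positions is not None:
            pos = self.insert_positions
            if len(pos) < n_inserts:
                raise ValueError("fewer insert positions than materials")
            return tuple(pos[:n_inserts])
        pitch = self.insert_length + self.insert_spacing
        start = self.insert_spacing
        pos = tuple(start + i * pitch for i in range(n_inserts))
        if pos and pos[-1] + self.insert_length > self.cylinder_height:
            raise ValueError("inserts do not fit inside the cylinder height")
        return pos


@dataclass
class SpectralImageSet:
    """Co-registered CTN/RED/EAN volumes with technique tag and geometry.

    Volumes are indexed (x, y, z) with voxel-center coordinates
    ``position = index * spacing`` (zero-based). All CTN values lie on the
    standard Hounsfield scale [-1024, 3071].
    """

    ctn_volumes: dict[str, np.ndarray]
    red_volume: np.ndarray
    ean_volume: np.ndarray
    technique: str
    voxel_spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)

    def __post_init__(self) -> None:
        if self.technique not in ("SACT", "DLCT"):
            raise ValueError("technique must be 'SACT' or 'DLCT'")
        shape = self.red_volume.shape
        if self.ean_volume.shape != shape:
            raise ValueError("RED and EAN volumes must share shape")
        for kvp, vol in self.ctn_volumes.items():
            if vol.shape != shape:
                raise ValueError(f"CTN volume {kvp} shape mismatch")
            if vol.min() < HU_MIN or vol.max() > HU_MAX:
                raise ValueError(f"CTN volume {kvp} outside [{HU_MIN}, {HU_MAX}]")
        self.voxel_spacing = tuple(float(s) for s in self.voxel_spacing)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.red_volume.shape


@dataclass(frozen=True)
class HeadPhantom:
    """Synthetic head slab: image set, truth SPR map and override masks."""

    imageset: SpectralImageSet
    truth: SPRMap
    tooth_mask: np.ndarray
    base_mask: np.ndarray
    tooth_center: tuple[float, float, float]


def forward_ctn(red, ean, spectrum: SpectrumModel | tuple[float, float],
                clip: bool = True):
    """Forward CT number (HU) from RED and EAN for one spectrum.

    ``spectrum`` is a :class:`~dectspr.spectrum.SpectrumModel` or a bare
    ``(k1, k2)`` pair of the two free stoichiometric coefficients. Output is
    clipped to the standard Hounsfield scale [-1024, 3071] unless
    ``clip=False``.
    """
    if not isinstance(spectrum, SpectrumModel):
        k1, k2 = spectrum
        spectrum = SpectrumModel(k1=float(k1), k2=float(k2))
    return spectrum.ctn(red, ean, clip=clip)


def _grids(shape, spacing):
    ax = [np.arange(n) * s for n, s in zip(shape, spacing)]
    return np.meshgrid(*ax, indexing="ij")


def generate_insert_phantom(
    layout: PhantomLayout,
    materials: Sequence[MaterialSpec],
    noise: NoiseModel | None = None,
    technique: str = "DLCT",
    spectra: dict[str, SpectrumModel] | None = None,
    streak_z_threshold: int = 20,
):
    """Generate the cylindrical insert phantom as a spectral image set.

    Voxels inside each insert carry that material's nominal RED/EAN and the
    forward CT number (the core material inside ``core_diameter``, PMMA in
    the annulus outside it); the background cylinder carries PMMA values and
    the exterior air. Gaussian noise per map and radial streaks around
    inserts with ``z_max >= streak_z_threshold`` are added, then CTN is
    clipped to the standard scale.

    Returns
    -------
    (imageset, labels, names):
        The spectral image set, an integer truth label volume (0 air,
        1 background, i+2 for material i) and a label->name mapping.
    """
    noise = noise or NoiseModel()
    spectra = spectra or DEFAULT_SPECTRA
    kvps = TECHNIQUE_KVPS.get(technique.upper())
    if kvps is None:
        raise ValueError("technique must be 'SACT' or 'DLCT'")

    dx, dy, dz = layout.voxel_spacing
    nx = int(round(2 * layout.cylinder_radius / dx))
    ny = int(round(2 * layout.cylinder_radius / dy))
    nz = int(round(layout.cylinder_height / dz))
    shape = (nx, ny, nz)
    xx, yy, zz = _grids(shape, layout.voxel_spacing)
    cx = (nx - 1) * dx / 2.0
    cy = (ny - 1) * dy / 2.0
    r2 = (xx - cx) ** 2 + (yy - cy) ** 2

    positions = layout.positions_for(len(materials))
    spans = [(p, p + layout.insert_length) for p in positions]
    for (a0, a1), (b0, b1) in zip(spans, spans[1:]):
        if b0 < a1:
            raise ValueError("overlapping inserts")
    for m in materials:
        if m.outer_diameter / 2.0 > layout.cylinder_radius:
            raise ValueError(f"insert {m.name} does not fit in the cylinder")

    bg = layout.background
    red = np.full(shape, _AIR_RED)
    ean = np.full(shape, _AIR_EAN)
    labels = np.zeros(shape, dtype=np.int16)
    in_cyl = r2 <= layout.cylinder_radius**2
    red[in_cyl] = bg.red_nominal
    ean[in_cyl] = bg.ean_nominal
    labels[in_cyl] = 1

    for i, (m, (z0, z1)) in enumerate(zip(materials, spans)):
        d = m.core_diameter if m.core_diameter is not None else m.outer_diameter
        mask = (r2 <= (d / 2.0) ** 2) & (zz >= z0) & (zz < z1)
        red[mask] = m.red_nominal
        ean[mask] = m.ean_nominal
        labels[mask] = i + 2

    ctn = {kvp: forward_ctn(red, ean, spectra[kvp]) for kvp in kvps}

    rng = np.random.default_rng(noise.seed)
    if noise.red_sd > 0:
        red = red + rng.normal(0.0, noise.red_sd, shape)
        red = np.maximum(red, 1e-4)
    if noise.ean_sd > 0:
        ean = ean + rng.normal(0.0, noise.ean_sd, shape)
        ean = np.maximum(ean, 1e-2)
    for kvp in kvps:
        vol = ctn[kvp]
        if noise.ctn_sd > 0:
            vol = vol + rng.normal(0.0, noise.ctn_sd, shape)
        if noise.streak_amplitude > 0:
            theta = np.arctan2(yy - cy, xx - cx)
            r = np.sqrt(r2)
            for m, (z0, z1) in zip(materials, spans):
                if m.z_max < streak_z_threshold:
                    continue
                rad = (m.core_diameter or m.outer_diameter) / 2.0
                zsel = (zz >= z0) & (zz < z1) & (r > rad) & in_cyl
                pattern = np.sin(noise.streak_count * theta) * np.exp(
                    -(r - rad) / 20.0
                )
                vol = np.where(zsel, vol + noise.streak_amplitude * pattern, vol)
        ctn[kvp] = np.clip(vol, HU_MIN, HU_MAX)

    imageset = SpectralImageSet(
        ctn_volumes=ctn, red_volume=red, ean_volume=ean,
        technique=technique.upper(), voxel_spacing=layout.voxel_spacing,
    )
    names = {0: "air", 1: bg.name}
    names.update({i + 2: m.name for i, m in enumerate(materials)})
    return imageset, labels, names


def generate_head_slab(
    tooth: str = "sphere",
    restoration: MaterialSpec | None = None,
    base: MaterialSpec = PMMA,
    *,
    shape: tuple[int, int, int] = (60, 60, 100),
    voxel_spacing: tuple[float, float, float] = (1.0, 1.0, 1.0),
    tooth_depth: float = 25.0,
    technique: str = "DLCT",
    spectra: dict[str, SpectrumModel] | None = None,
    sphere_diameter: float = 7.0,
    crown_thickness: float = 1.0,
    crown_diameter: float = 7.0,
    base_length: float = 15.0,
) -> HeadPhantom:
    """Simplified water-equivalent head slab with a removable tooth.

    The slab is a water-equivalent stack (SPR 1) with the beam along +z.
    The tooth is either a ``"sphere"`` (7 mm diameter) of restoration
    material or a ``"crown"`` (1 mm thick cap of restoration material),
    sitting on a PMMA base cylinder directly behind it. The truth SPR map
    holds each region's ``spr_truth`` for reference-dataset construction.
    """
    if restoration is None:
        from .materials import dental_catalog
        restoration = next(m for m in dental_catalog(technique)
                           if m.name == "lithium_disilicate")
    if tooth not in ("sphere", "crown"):
        raise ValueError("tooth must be 'sphere' or 'crown'")
    spectra = spectra or DEFAULT_SPECTRA
    kvps = TECHNIQUE_KVPS[technique.upper()]

    xx, yy, zz = _grids(shape, voxel_spacing)
    cx = (shape[0] - 1) * voxel_spacing[0] / 2.0
    cy = (shape[1] - 1) * voxel_spacing[1] / 2.0
    rho2 = (xx - cx) ** 2 + (yy - cy) ** 2

    if tooth == "sphere":
        zc = tooth_depth + sphere_diameter / 2.0
        tooth_mask = rho2 + (zz - zc) ** 2 <= (sphere_diameter / 2.0) ** 2
        tooth_end = tooth_depth + sphere_diameter
        lateral = rho2 <= (sphere_diameter / 2.0) ** 2
    else:
        tooth_mask = ((rho2 <= (crown_diameter / 2.0) ** 2)
                      & (zz >= tooth_depth)
                      & (zz < tooth_depth + crown_thickness))
        tooth_end = tooth_depth + crown_thickness
        lateral = rho2 <= (crown_diameter / 2.0) ** 2
    base_mask = lateral & (zz >= tooth_end) & (zz < tooth_end + base_length)
    base_mask &= ~tooth_mask

    red = np.ones(shape)
    ean = np.full(shape, 7.45)
    truth = np.ones(shape)
    for mask, mat in ((base_mask, base), (tooth_mask, restoration)):
        red[mask] = mat.red_nominal
        ean[mask] = mat.ean_nominal
        truth[mask] = mat.spr_truth

    ctn = {kvp: forward_ctn(red, ean, spectra[kvp]) for kvp in kvps}
    imageset = SpectralImageSet(ctn_volumes=ctn, red_volume=red, ean_volume=ean,
                                technique=technique.upper(),
                                voxel_spacing=voxel_spacing)
    truth_map = SPRMap(volume=truth, spacing=voxel_spacing, method="truth")
    zc_report = tooth_depth + (sphere_diameter / 2.0 if tooth == "sphere"
                               else crown_thickness / 2.0)
    return HeadPhantom(imageset=imageset, truth=truth_map,
                       tooth_mask=tooth_mask, base_mask=base_mask,
                       tooth_center=(cx, cy, zc_report))


# Bragg-Kleeman exponent p ~ 1.77 gives a fluence-stopping rise ~ (R-z)^(1/p - 1).
_BK_EXPONENT = 1.0 / 1.77 - 1.0  # ~ -0.435


def generate_bragg_curve(range_r80: float, straggling_sigma: float,
                         depth_step: float = 0.1,
                         depth_max: float | None = None) -> DepthDoseCurve:
    """Pristine Bragg curve with prescribed distal-80% range and straggling.

    A power-law fluence-stopping rise ~ (R - z)^(-0.435) is convolved with a
    Gaussian of width ``straggling_sigma`` (mm) and the depth axis is then
    shifted so the distal-80% depth equals ``range_r80`` within one grid
    step. Dose is normalised to a maximum of 1.
    """
    if range_r80 <= 0 or straggling_sigma <= 0:
        raise ValueError("range_r80 and straggling_sigma must be positive")
    if depth_step >= straggling_sigma:
        raise ValueError("depth step must be smaller than the straggling sigma "
                         "(peak unresolvable)")
    if depth_max is None:
        depth_max = range_r80 + 6.0 * straggling_sigma + 5.0

    fine = min(depth_step, straggling_sigma / 10.0)
    pad = 6.0 * straggling_sigma + 5.0
    z = np.arange(0.0, depth_max + pad, fine)
    raw = np.zeros_like(z)
    rise = z < range_r80 - fine / 2.0
    raw[rise] = (range_r80 - z[rise]) ** _BK_EXPONENT
    dose = gaussian_filter1d(raw, straggling_sigma / fine, mode="constant")

    # shift so the distal 80% level of the smoothed curve sits at range_r80
    i_max = int(np.argmax(dose))
    level = 0.8 * dose[i_max]
    distal = dose[i_max:]
    j = i_max + int(np.nonzero(distal < level)[0][0])
    d80 = z[j - 1] + (dose[j - 1] - level) * fine / (dose[j - 1] - dose[j])
    shift = range_r80 - d80

    grid = np.arange(0.0, depth_max + depth_step / 2.0, depth_step)
    out = np.interp(grid - shift, z, dose, left=dose[0], right=0.0)
    return DepthDoseCurve(depth=grid, dose=out / out.max())


def generate_calibration_set(
    beam: BeamSpec | None = None,
    ivm: IValueModel | None = None,
    spectrum: SpectrumModel | None = None,
) -> tuple[list[MaterialSpec], dict[str, float]]:
    """Tissue-surrogate calibration set with self-consistent truths.

    Returns the surrogate materials (lung-like RED ~0.3 to cortical-bone-like
    RED ~1.7) with ``spr_truth`` computed from the package's Bethe model, and
    a dict of their forward CT numbers under ``spectrum`` (default 120 kVp)
    emulating a measured calibration scan.
    """
    beam = beam or BeamSpec()
    ivm = ivm or IValueModel()
    spectrum = spectrum or DEFAULT_SPECTRA["120kVp"]
    out = []
    ctn = {}
    for m in tissue_surrogates():
        spr = bethe_spr(m.red_nominal, m.ean_nominal, beam, ivm)
        out.append(m.with_(spr_truth=spr))
        ctn[m.name] = forward_ctn(m.red_nominal, m.ean_nominal, spectrum)
    return out, ctn
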