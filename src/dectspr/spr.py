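"""Stopping-power-ratio prediction models.

Two routes from CT data to SPR are implemented:

* **DE-RhoZ** (dual-energy): voxelwise Bethe-equation evaluation from
  relative electron density (RED) and effective atomic number (EAN) maps,
  with the mean excitation energy (I-value) estimated from EAN by a
  piecewise-linear tissue fit,

      SPR = RED * [ln(2 m_e c^2 b^2 / (I (1-b^2))) - b^2]
                / [ln(2 m_e c^2 b^2 / (I_w(1-b^2))) - b^2]

  at a fixed kinetic energy of 100 MeV/u (the energy dependence of the
  ratio is far below other uncertainties in the therapeutic range).

* **SE-HLUT** (single-energy): a Hounsfield look-up table calibrated with
  the two-parameter stoichiometric model on tissue surrogates, mapping CT
  number piecewise-linearly to SPR with a clinical clamp at ``max_spr``.

A DEEDZ-style polynomial converts (RED, EAN) to mass density for material
characterisation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np

from .materials import MaterialSpec
from .spectrum import HU_MAX, SpectrumModel, Z_EFF_WATER, fit_spectrum

__all__ = [
    "ELECTRON_REST_ENERGY_EV",
    "I_WATER_EV",
    "BeamSpec",
    "IValueModel",
    "DeedzParams",
    "HLUT",
    "SPRMap",
    "i_value",
    "bethe_spr",
    "deedz_mass_density",
    "hlut_calibrate",
    "hlut_apply",
    "spr_map",
    "override_spr",
]

#: m_e c^2 in eV.
ELECTRON_REST_ENERGY_EV = 0.51099895e6
#: Default mean excitation energy of water (eV), ICRU-90-consistent.
I_WATER_EV = 78.73


@dataclass(frozen=True)
class BeamSpec:
    """Ion beam kinematics: kinetic energy per nucleon in MeV/u.

    ``beta_squared`` follows from relativistic kinematics with the nucleon
    rest energy (938.272 MeV by default; using the atomic mass unit instead
    changes SPR by <0.1%).
    """

    kinetic_energy_per_nucleon: float = 100.0
    nucleon_rest_energy: float = 938.272

    def __post_init__(self) -> None:
        if not 0 < self.beta_squared < 1:
            raise ValueError("kinetic energy must give 0 < beta^2 < 1")

    @property
    def beta_squared(self) -> float:
        gamma = 1.0 + self.kinetic_energy_per_nucleon / self.nucleon_rest_energy
        return 1.0 - 1.0 / gamma**2


#: Default piecewise-linear I(EAN) knots (EAN, I in eV): adipose-like,
#: water, cortical-bone-like tissue anchors; clamped outside. Institutions
#: can (and should) substitute their own fitted knot set.
_DEFAULT_KNOTS: tuple[tuple[float, float], ...] = (
    (6.2, 63.2),
    (7.45, I_WATER_EV),
    (13.5, 106.4),
)


@dataclass(frozen=True)
class IValueModel:
    """Piecewise-linear mean-excitation-energy model I(EAN).

    Linear interpolation between knots; constant (clamped) extrapolation
    beyond the outer knots.
    """

    knots: tuple[tuple[float, float], ...] = _DEFAULT_KNOTS
    i_water: float = I_WATER_EV

    def __post_init__(self) -> None:
        eans = [k[0] for k in self.knots]
        ivals = [k[1] for k in self.knots]
        if len(self.knots) < 1:
            raise ValueError("need at least one knot")
        if any(b <= a for a, b in zip(eans, eans[1:])):
            raise ValueError("knot EANs must be strictly increasing")
        if any(i <= 0 for i in ivals) or self.i_water <= 0:
            raise ValueError("I-values must be positive")

    def __call__(self, ean):
        eans = np.array([k[0] for k in self.knots])
        ivals = np.array([k[1] for k in self.knots])
        out = np.interp(np.asarray(ean, dtype=float), eans, ivals)
        return out if np.ndim(out) else float(out)


def i_value(ean, model: IValueModel | None = None):
    """Mean excitation energy in eV for a given effective atomic number."""
    return (model or IValueModel())(ean)


def _stopping_number(i_ev, beta_squared: float):
    """Bethe stopping number L = ln(2 m_e c^2 b^2 / (I (1-b^2))) - b^2."""
    i_ev = np.asarray(i_ev, dtype=float)
    arg = 2.0 * ELECTRON_REST_ENERGY_EV * beta_squared / (i_ev * (1.0 - beta_squared))
    if np.any(arg <= 1.0):
        raise ValueError(
            "Bethe logarithm argument <= 1: I-value too large for this beam "
            f"energy (min argument {float(np.min(arg)):.3g})"
        )
    return np.log(arg) - beta_squared


def bethe_spr(red, ean, beam: BeamSpec | None = None,
              ivm: IValueModel | None = None):
    """Stopping-power ratio from RED and EAN via the Bethe equation.

    Accepts scalars or arrays (broadcast together). ``red`` must be
    positive; the I-value is obtained from ``ean`` through ``ivm``.
    """
    beam = beam or BeamSpec()
    ivm = ivm or IValueModel()
    red = np.asarray(red, dtype=float)
    if np.any(red <= 0):
        raise ValueError("red must be positive")
    b2 = beam.beta_squared
    ratio = _stopping_number(ivm(ean), b2) / _stopping_number(ivm.i_water, b2)
    out = red * ratio
    return out if np.ndim(out) else float(out)


@dataclass(frozen=True)
class DeedzParams:
    """Coefficients of the (RED, EAN) -> mass density polynomial.

    rho = rho_e * (1 + sum_{n=0..2} e_n * x^n),  x = (Z_eff/Z_eff,w)^m - 1.

    Default ``e`` coefficients were fitted once to the bundled tissue
    surrogate catalog with e0 pinned at 0 so water maps exactly to 1 g/cm3;
    institutions using published tissue fits should override them.
    """

    e: tuple[float, float, float] = (0.0, 0.0221468, -0.0016133)
    m: float = 3.3
    z_eff_water: float = Z_EFF_WATER

    def __post_init__(self) -> None:
        if self.m <= 0 or self.z_eff_water <= 0:
            raise ValueError("m and z_eff_water must be positive")


def deedz_mass_density(red, ean, params: DeedzParams | None = None):
    """Mass density in g/cm3 from RED and EAN."""
    p = params or DeedzParams()
    red = np.asarray(red, dtype=float)
    ean = np.asarray(ean, dtype=float)
    if np.any(red <= 0) or np.any(ean <= 0):
        raise ValueError("red and ean must be positive")
    x = (ean / p.z_eff_water) ** p.m - 1.0
    e0, e1, e2 = p.e
    out = red * (1.0 + e0 + e1 * x + e2 * x * x)
    return out if np.ndim(out) else float(out)


@dataclass(frozen=True)
class HLUT:
    """Monotone piecewise-linear CT-number -> SPR look-up table with clamp.

    ``nodes`` is an (N, 2) array of (CTN in HU, SPR), strictly increasing in
    CTN and non-decreasing in SPR. Below the first node the first node's SPR
    is returned; above the last node the clamp value ``max_spr`` applies,
    mirroring the clinical maximum-SPR behaviour of institutional tables.
    """

    nodes: np.ndarray
    max_spr: float = np.inf
    profile: str = ""
    spectrum: Optional[SpectrumModel] = None

    def __post_init__(self) -> None:
        nodes = np.atleast_2d(np.asarray(self.nodes, dtype=float))
        if nodes.shape[1] != 2 or nodes.shape[0] < 2:
            raise ValueError("nodes must be an (N>=2, 2) array of (ctn, spr)")
        if np.any(np.diff(nodes[:, 0]) <= 0):
            raise ValueError("node CTNs must be strictly increasing")
        if np.any(np.diff(nodes[:, 1]) < 0):
            raise ValueError("node SPRs must be non-decreasing")
        object.__setattr__(self, "nodes", nodes)

    def apply(self, ctn):
        ctn = np.asarray(ctn, dtype=float)
        out = np.interp(ctn, self.nodes[:, 0], self.nodes[:, 1])
        out = np.where(ctn > self.nodes[-1, 0], self.max_spr, out)
        out = np.minimum(out, self.max_spr)
        return out if np.ndim(out) else float(out)


def hlut_apply(ctn, hlut: HLUT):
    """Convert CT numbers to SPR through a look-up table."""
    return hlut.apply(ctn)


def hlut_calibrate(
    measured_ctn: dict[str, float],
    materials: Sequence[MaterialSpec],
    reference_tissues: Sequence[MaterialSpec] | None = None,
    *,
    beam: BeamSpec | None = None,
    ivm: IValueModel | None = None,
    max_spr: float = np.inf,
    profile: str = "",
    spectrum_template: SpectrumModel | None = None,
) -> HLUT:
    """Stoichiometric HLUT calibration.

    1. Fit the two free spectrum coefficients (k1, k2) to the measured CT
       numbers of the calibration materials by least squares.
    2. Predict CT numbers of the reference tissues (the calibration set
       itself by default) with the fitted spectrum.
    3. Compute reference-tissue SPR via the Bethe equation.
    4. Build monotone piecewise-linear nodes through (CTN, SPR), forcing the
       water node (0 HU, 1.0); ties in CTN are averaged in SPR.
    5. Clamp at ``max_spr``.
    """
    beam = beam or BeamSpec()
    ivm = ivm or IValueModel()
    mats = list(materials)
    if len(mats) < 3:
        raise ValueError("need >=3 calibration materials spanning the CTN range")
    missing = [m.name for m in mats if m.name not in measured_ctn]
    if missing:
        raise ValueError(f"measured CTN missing for: {missing}")

    spec = fit_spectrum(
        [m.red_nominal for m in mats],
        [m.ean_nominal for m in mats],
        [measured_ctn[m.name] for m in mats],
        template=spectrum_template,
    )

    refs = list(reference_tissues) if reference_tissues is not None else mats
    ctn_pred = np.array([spec.ctn(m.red_nominal, m.ean_nominal) for m in refs])
    spr_pred = np.array(
        [bethe_spr(m.red_nominal, m.ean_nominal, beam, ivm) for m in refs]
    )

    # force the water anchor, average SPR at duplicate CTNs
    ctn_all = np.append(ctn_pred, 0.0)
    spr_all = np.append(spr_pred, 1.0)
    order = np.argsort(ctn_all, kind="stable")
    ctn_all, spr_all = ctn_all[order], spr_all[order]
    uniq, inverse = np.unique(np.round(ctn_all, 6), return_inverse=True)
    spr_nodes = np.array([spr_all[inverse == i].mean() for i in range(uniq.size)])

    if np.any(np.diff(spr_nodes) < 0):
        raise ValueError(
            "calibration produced a non-monotone CTN->SPR node set; "
            "check the calibration materials and I-value model"
        )
    return HLUT(nodes=np.column_stack([uniq, spr_nodes]), max_spr=max_spr,
                profile=profile, spectrum=spec)


@dataclass
class SPRMap:
    """Voxelised SPR volume with provenance.

    ``volume`` is a 3D array of SPR values; ``spacing`` the voxel size in mm
    per axis (voxel-center convention, zero-based indices); ``method`` the
    prediction route; ``overrides`` an append-only provenance list of
    (description, value) for material overrides applied to the map.
    """

    volume: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    method: str = ""
    overrides: list[tuple[str, float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.volume = np.asarray(self.volume, dtype=float)
        if self.volume.ndim != 3:
            raise ValueError("volume must be 3D")
        if np.any(self.volume < 0):
            raise ValueError("SPR must be >= 0 everywhere")
        self.spacing = tuple(float(s) for s in self.spacing)


def spr_map(imageset, method: str, *, hlut: HLUT | None = None,
            kvp: str | None = None, beam: BeamSpec | None = None,
            ivm: IValueModel | None = None) -> SPRMap:
    """Voxelwise SPR prediction from a spectral image set.

    ``method`` is ``"se-hlut"`` (needs ``hlut`` and the ``kvp`` label of the
    CTN volume to convert) or ``"de-rhoz"`` (needs the RED and EAN volumes;
    optional ``beam``/``ivm``).
    """
    method = method.lower()
    if method == "se-hlut":
        if hlut is None or kvp is None:
            raise ValueError("se-hlut requires hlut and kvp")
        if kvp not in imageset.ctn_volumes:
            raise ValueError(f"no CTN volume for {kvp!r}")
        vol = hlut.apply(imageset.ctn_volumes[kvp])
        label = f"SE-HLUT({kvp}{',' + hlut.profile if hlut.profile else ''})"
    elif method == "de-rhoz":
        if imageset.red_volume is None or imageset.ean_volume is None:
            raise ValueError("de-rhoz requires RED and EAN volumes")
        vol = bethe_spr(imageset.red_volume, imageset.ean_volume, beam, ivm)
        label = "DE-RhoZ"
    else:
        raise ValueError(f"unknown method {method!r}")
    return SPRMap(volume=np.asarray(vol), spacing=imageset.voxel_spacing, method=label)


def override_spr(sprmap: SPRMap, mask: np.ndarray, value: float,
                 description: str = "override") -> SPRMap:
    """Set SPR inside ``mask`` to ``value`` (measured-value material override).

    Returns a new map with provenance appended. An empty mask is a warned
    no-op. Idempotent for identical (mask, value).
    """
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != sprmap.volume.shape:
        raise ValueError("mask shape must match volume")
    if value < 0:
        raise ValueError("override SPR must be >= 0")
    if not mask.any():
        warnings.warn("override_spr: empty mask, no-op", stacklevel=2)
        return sprmap
    vol = sprmap.volume.copy()
    vol[mask] = value
    return SPRMap(volume=vol, spacing=sprmap.spacing, method=sprmap.method,
                  overrides=[*sprmap.overrides, (description, float(value))])
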