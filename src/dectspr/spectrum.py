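"""Two-parameter stoichiometric CT-number model.

The CT number of a material at a given tube potential is modelled from its
relative electron density (RED) and effective atomic number (EAN) with the
classic stoichiometric decomposition of the photon cross-section into
photoelectric (~Z^3.62), coherent-scatter (~Z^1.86) and Klein-Nishina
(Z-independent) parts:

    u = RED * (k1 * EAN^3.62 + k2 * EAN^1.86 + k3)
            / (k1 * Zw^3.62  + k2 * Zw^1.86  + k3)
    CTN = 1000 * (u - 1)        [HU], clipped to [-1024, 3071]

k3 multiplies the Klein-Nishina term and is fixed (only the ratio of the
coefficients matters), so (k1, k2) are the two free spectrum parameters that
are fitted per tube potential. The same model is used both as the forward
model of the synthetic generator and, refitted to measured CT numbers, as the
stoichiometric step of the HLUT calibration.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

__all__ = [
    "HU_MIN",
    "HU_MAX",
    "Z_EFF_WATER",
    "SpectrumModel",
    "DEFAULT_SPECTRA",
    "fit_spectrum",
]

HU_MIN = -1024.0
#: Top of the standard (non-extended) Hounsfield scale.
HU_MAX = 3071.0
#: Default effective atomic number of water.
Z_EFF_WATER = 7.45

#: Photoelectric and coherent-scatter exponents of the cross-section model.
P_PHOTOELECTRIC = 3.62
P_COHERENT = 1.86


@dataclass(frozen=True)
class SpectrumModel:
    """Fitted spectrum coefficients for one tube potential.

    ``k3`` (the Klein-Nishina weight) is fixed at 1 by convention; only
    ``k1``/``k3`` and ``k2``/``k3`` are identifiable.
    """

    k1: float
    k2: float
    k3: float = 1.0
    z_eff_water: float = Z_EFF_WATER
    p_photoelectric: float = P_PHOTOELECTRIC
    p_coherent: float = P_COHERENT

    def _cross_section(self, ean):
        ean = np.asarray(ean, dtype=float)
        return (self.k1 * ean**self.p_photoelectric
                + self.k2 * ean**self.p_coherent
                + self.k3)

    def attenuation(self, red, ean):
        """Attenuation relative to water, u = mu/mu_w."""
        red = np.asarray(red, dtype=float)
        ean = np.asarray(ean, dtype=float)
        if np.any(red <= 0) or np.any(ean <= 0):
            raise ValueError("red and ean must be positive")
        return red * self._cross_section(ean) / self._cross_section(self.z_eff_water)

    def ctn(self, red, ean, clip: bool = True):
        """CT number in HU; clipped to the standard scale unless ``clip=False``."""
        hu = 1000.0 * (self.attenuation(red, ean) - 1.0)
        if clip:
            hu = np.clip(hu, HU_MIN, HU_MAX)
        return hu if np.ndim(hu) else float(hu)


# Frozen per-kVp defaults, solved so that PMMA maps to its characteristic
# CT number at each tube potential and a cortical-bone-like point
# (RED 1.69, EAN 13.6) to a typical bone HU (harder spectrum -> lower HU).
DEFAULT_SPECTRA: dict[str, SpectrumModel] = {
    "80kVp": SpectrumModel(k1=6.34681847e-05, k2=-1.98204917e-03),
    "120kVp": SpectrumModel(k1=1.23313753e-05, k2=2.01616633e-03),
    "140kVp": SpectrumModel(k1=6.75924868e-06, k2=2.04425327e-03),
}


def fit_spectrum(red, ean, ctn_measured, template: SpectrumModel | None = None) -> SpectrumModel:
    """Least-squares fit of the two free coefficients (k1, k2) to measured CTN.

    Parameters
    ----------
    red, ean:
        Per-material relative electron density and effective atomic number.
    ctn_measured:
        Measured CT numbers in HU (same length). Saturated entries should be
        excluded by the caller; the fit uses the unclipped model.
    template:
        Spectrum model supplying the fixed pieces (k3, exponents, water EAN).
    """
    red = np.asarray(red, dtype=float)
    ean = np.asarray(ean, dtype=float)
    hu = np.asarray(ctn_measured, dtype=float)
    if not (red.shape == ean.shape == hu.shape):
        raise ValueError("red, ean and ctn_measured must have matching shapes")
    if red.size < 2:
        raise ValueError("need at least two materials to fit (k1, k2)")
    tpl = template or SpectrumModel(k1=1e-5, k2=2e-3)

    def resid(k):
        m = SpectrumModel(k1=k[0], k2=k[1], k3=tpl.k3, z_eff_water=tpl.z_eff_water,
                          p_photoelectric=tpl.p_photoelectric, p_coherent=tpl.p_coherent)
        return m.ctn(red, ean, clip=False) - hu

    sol = least_squares(resid, x0=[tpl.k1, tpl.k2], method="lm")
    return SpectrumModel(k1=float(sol.x[0]), k2=float(sol.x[1]), k3=tpl.k3,
                         z_eff_water=tpl.z_eff_water,
                         p_photoelectric=tpl.p_photoelectric,
                         p_coherent=tpl.p_coherent)
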