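"""Bragg-peak analysis and water-column SPR measurement.

The stopping-power ratio of a sample is measured from the upstream shift of
a pristine Bragg peak in a water column when the sample intersects the beam:

    SPR_meas = (P_w - P_m) / d_m

where P is the mean of four characteristic depths of the depth-dose curve —
the fitted dose maximum, the grid dose maximum, and the distal 90% and 80%
dose levels — without (P_w) and with (P_m) the sample of thickness d_m in
the beam. Averaging four depths makes the peak position robust against
sampling noise near the flat peak top.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

__all__ = ["DepthDoseCurve", "PeakDepths", "characteristic_depths", "measured_spr"]


@dataclass(frozen=True)
class DepthDoseCurve:
    """Depth-dose curve on a strictly increasing depth grid (mm)."""

    depth: np.ndarray
    dose: np.ndarray

    def __post_init__(self) -> None:
        depth = np.asarray(self.depth, dtype=float)
        dose = np.asarray(self.dose, dtype=float)
        if depth.ndim != 1 or depth.shape != dose.shape:
            raise ValueError("depth and dose must be matching 1D arrays")
        if depth.size < 20:
            raise ValueError("need at least 20 samples")
        if np.any(np.diff(depth) <= 0):
            raise ValueError("depth grid must be strictly increasing")
        if np.any(dose < 0):
            raise ValueError("dose must be non-negative")
        object.__setattr__(self, "depth", depth)
        object.__setattr__(self, "dose", dose)

    def shifted(self, delta_mm: float) -> "DepthDoseCurve":
        """Curve translated in depth by ``delta_mm`` (positive = deeper)."""
        return DepthDoseCurve(self.depth + delta_mm, self.dose)


@dataclass(frozen=True)
class PeakDepths:
    """Four characteristic depths of a Bragg curve and their mean (mm)."""

    fitted_max_depth: float
    grid_max_depth: float
    d90_distal: float
    d80_distal: float

    @property
    def p_mean(self) -> float:
        return (self.fitted_max_depth + self.grid_max_depth
                + self.d90_distal + self.d80_distal) / 4.0


def _distal_crossing(depth: np.ndarray, dose: np.ndarray, i_max: int,
                     level: float) -> float:
    """First distal depth where dose falls below ``level``, linearly interpolated."""
    distal_dose = dose[i_max:]
    below = np.nonzero(distal_dose < level)[0]
    if below.size == 0:
        raise ValueError("distal falloff does not reach the requested dose level")
    j = i_max + below[0]
    if j == i_max:  # peak sample itself below level (clipped fit); degenerate
        return float(depth[j])
    d0, d1 = dose[j - 1], dose[j]
    z0, z1 = depth[j - 1], depth[j]
    return float(z0 + (d0 - level) * (z1 - z0) / (d0 - d1))


def characteristic_depths(curve: DepthDoseCurve,
                          fit_window_mm: float = 2.0) -> PeakDepths:
    """Fitted/grid peak depth and distal 90%/80% depths of a Bragg curve.

    The fitted maximum is the vertex of a parabola fitted over a window of
    +/- ``fit_window_mm`` around the grid maximum; the distal dose levels
    reference the fitted maximum dose (robust to single-sample spikes).
    The curve must cover the full distal falloff (last sample < 50% of max).
    """
    depth, dose = curve.depth, curve.dose
    dmax = dose.max()
    if dose[-1] >= 0.5 * dmax:
        raise ValueError("curve does not cover the distal falloff "
                         "(last dose >= 50% of maximum)")

    peak_idx = np.nonzero(dose == dmax)[0]
    if peak_idx.size > 1:
        warnings.warn("non-unique dose maximum; using the deepest grid point",
                      stacklevel=2)
    i_max = int(peak_idx[-1])
    grid_max_depth = float(depth[i_max])

    in_win = np.abs(depth - grid_max_depth) <= fit_window_mm
    if in_win.sum() >= 3:
        a, b, c = np.polyfit(depth[in_win], dose[in_win], 2)
        if a < 0:
            vertex = -b / (2.0 * a)
            # keep the vertex inside the fit window
            vertex = float(np.clip(vertex, grid_max_depth - fit_window_mm,
                                   grid_max_depth + fit_window_mm))
            fitted_max_depth = vertex
            fitted_max_dose = float(np.polyval([a, b, c], vertex))
        else:
            fitted_max_depth, fitted_max_dose = grid_max_depth, float(dmax)
    else:
        fitted_max_depth, fitted_max_dose = grid_max_depth, float(dmax)
    fitted_max_dose = min(fitted_max_dose, float(dmax) * 1.05)

    d90 = _distal_crossing(depth, dose, i_max, 0.90 * fitted_max_dose)
    d80 = _distal_crossing(depth, dose, i_max, 0.80 * fitted_max_dose)
    return PeakDepths(fitted_max_depth=fitted_max_depth,
                      grid_max_depth=grid_max_depth,
                      d90_distal=d90, d80_distal=d80)


def measured_spr(curve_without: DepthDoseCurve, curve_with: DepthDoseCurve,
                 sample_thickness_d: float) -> float:
    """Water-column SPR of a sample from the Bragg-peak shift it causes.

    ``curve_without``/``curve_with`` are the depth-dose curves in the water
    absorber without and with the sample of thickness ``sample_thickness_d``
    (mm) in the beam.
    """
    if sample_thickness_d <= 0:
        raise ValueError("sample thickness must be positive")
    p_w = characteristic_depths(curve_without).p_mean
    p_m = characteristic_depths(curve_with).p_mean
    spr = (p_w - p_m) / sample_thickness_d
    if spr < 0:
        warnings.warn("negative measured SPR: check curve labelling/geometry",
                      stacklevel=2)
    return float(spr)
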