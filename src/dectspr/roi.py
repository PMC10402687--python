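"""ROI statistics, technique comparison and artifact scoring.

Per-material statistics are extracted from circular regions-of-interest of
~70% of the insert's cross-sectional diameter, placed on every retained
axial slice of the insert (slices at both ends are excluded to avoid
gradient effects at the material boundary), and pooled over all retained
voxels. A quantitative artifact proxy maps Hounsfield-scale saturation and
streak strength to the four-point severity scale (1 no, 2 mild, 3 moderate,
4 severe artifacts).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .spectrum import HU_MAX

__all__ = [
    "ROIStats",
    "ArtifactScore",
    "ArtifactThresholds",
    "extract_roi",
    "compare_techniques",
    "artifact_score",
]


@dataclass(frozen=True)
class ROIStats:
    """Pooled-voxel mean and SD over the retained ROI slices."""

    mean: float
    sd: float
    n_voxels: int
    slices_used: tuple[int, int]
    source_map: str = ""

    def __post_init__(self) -> None:
        if self.sd < 0 or self.n_voxels <= 0:
            raise ValueError("sd must be >= 0 and n_voxels > 0")


def extract_roi(
    volume: np.ndarray,
    spacing: tuple[float, float, float],
    center: tuple[float, float, float],
    insert_diameter: float,
    *,
    insert_length: float | None = None,
    fraction: float = 0.70,
    end_slice_exclusion: int = 1,
    source_map: str = "",
) -> ROIStats:
    """Circular-ROI statistics for one insert.

    ``center`` is the insert centre in mm (voxel-center convention,
    position = index * spacing). The ROI diameter is
    ``fraction * insert_diameter``; slices covered are those within the
    insert's axial extent (``insert_length`` mm centred on ``center``; the
    whole volume when omitted) minus ``end_slice_exclusion`` slices per end.
    """
    if not 0 < fraction <= 1:
        raise ValueError("fraction must be in (0, 1]")
    if end_slice_exclusion < 0:
        raise ValueError("end_slice_exclusion must be >= 0")
    dx, dy, dz = spacing
    cx, cy, cz = center
    radius = fraction * insert_diameter / 2.0

    if insert_length is None:
        z_lo, z_hi = 0, volume.shape[2] - 1
    else:
        z_lo = int(np.ceil((cz - insert_length / 2.0) / dz))
        z_hi = int(np.floor((cz + insert_length / 2.0) / dz))
    z_lo += end_slice_exclusion
    z_hi -= end_slice_exclusion
    if z_hi < z_lo:
        raise ValueError("no slices remain after end-slice exclusion")
    z_lo = max(z_lo, 0)
    z_hi = min(z_hi, volume.shape[2] - 1)

    x = np.arange(volume.shape[0]) * dx
    y = np.arange(volume.shape[1]) * dy
    in_roi = ((x[:, None] - cx) ** 2 + (y[None, :] - cy) ** 2) <= radius**2
    if cx - radius < -dx / 2 or cx + radius > x[-1] + dx / 2 \
            or cy - radius < -dy / 2 or cy + radius > y[-1] + dy / 2:
        raise ValueError("ROI extends outside the volume")
    if not in_roi.any():
        raise ValueError("empty ROI: diameter below voxel size")

    vals = volume[:, :, z_lo:z_hi + 1][in_roi, :].ravel()
    return ROIStats(
        mean=float(vals.mean()),
        sd=float(vals.std(ddof=1)) if vals.size > 1 else 0.0,
        n_voxels=int(vals.size),
        slices_used=(z_lo, z_hi),
        source_map=source_map,
    )


def compare_techniques(a: ROIStats, b: ROIStats) -> float:
    """Relative deviation in % between two techniques' ROI means.

    Symmetric convention: 100 * |a - b| / ((a + b) / 2).
    """
    if a.source_map != b.source_map:
        raise ValueError("ROIs come from different source maps")
    denom = (a.mean + b.mean) / 2.0
    if denom == 0:
        raise ValueError("mean sum is zero; relative deviation undefined")
    return float(100.0 * abs(a.mean - b.mean) / abs(denom))


@dataclass(frozen=True)
class ArtifactThresholds:
    """Config thresholds mapping the quantitative proxy to categories 1-4."""

    streak_mild: float = 5.0      # HU
    streak_moderate: float = 25.0
    streak_severe: float = 75.0
    saturation_moderate: float = 0.05  # fraction of insert voxels at 3071 HU
    saturation_severe: float = 0.5


@dataclass(frozen=True)
class ArtifactScore:
    """Quantitative artifact proxy and its four-point category."""

    saturated_fraction: float
    streak_index: float
    category: int

    def __post_init__(self) -> None:
        if not 0.0 <= self.saturated_fraction <= 1.0:
            raise ValueError("saturated_fraction must be in [0, 1]")
        if self.category not in (1, 2, 3, 4):
            raise ValueError("category must be 1..4")


def artifact_score(
    ctn_volume: np.ndarray,
    insert_mask: np.ndarray,
    shell_mask: np.ndarray,
    background_sd: float = 0.0,
    thresholds: ArtifactThresholds | None = None,
) -> ArtifactScore:
    """Score artifact severity around one insert.

    ``saturated_fraction`` is the share of insert voxels pinned at the top of
    the Hounsfield scale; ``streak_index`` is the CTN standard deviation in
    the surrounding shell minus the background SD. Categories are assigned by
    the config thresholds (monotone in both inputs).
    """
    t = thresholds or ArtifactThresholds()
    if not insert_mask.any():
        raise ValueError("empty insert mask")
    if not shell_mask.any():
        raise ValueError("empty shell mask")
    sat = float(np.mean(ctn_volume[insert_mask] >= HU_MAX - 0.5))
    streak = float(max(ctn_volume[shell_mask].std() - background_sd, 0.0))

    category = 1
    for th in (t.streak_mild, t.streak_moderate, t.streak_severe):
        if streak >= th:
            category += 1
    if sat >= t.saturation_severe:
        category = 4
    elif sat >= t.saturation_moderate:
        category = max(category, 3)
    return ArtifactScore(saturated_fraction=sat, streak_index=streak,
                         category=category)
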