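"""Residual evaluation and report assembly.

The agreement of a CT-based SPR prediction with the water-column measurement
is quantified by the signed relative residual

    residual = (SPR_CT - SPR_meas) / SPR_meas * 100%

reported at two decimals in tables. Per-method summaries use the mean of the
*absolute* residuals (one decimal) together with the signed min/max range.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = ["ResidualRecord", "SummaryStats", "relative_residual",
           "summarize_residuals", "build_report"]


def relative_residual(spr_ct, spr_meas):
    """Signed relative residual in % of a predicted vs measured SPR."""
    spr_meas_arr = np.asarray(spr_meas, dtype=float)
    if np.any(spr_meas_arr <= 0):
        raise ValueError("measured SPR must be positive")
    out = 100.0 * (np.asarray(spr_ct, dtype=float) - spr_meas_arr) / spr_meas_arr
    return out if np.ndim(out) else float(out)


@dataclass(frozen=True)
class ResidualRecord:
    """One material x method residual with its underlying SPR values."""

    material: str
    method: str
    spr_ct: float
    spr_meas: float
    residual_pct: float = field(init=False)

    def __post_init__(self) -> None:
        object.__setattr__(self, "residual_pct",
                           relative_residual(self.spr_ct, self.spr_meas))


@dataclass(frozen=True)
class SummaryStats:
    """Mean absolute residual plus signed range over included records."""

    mean_abs_residual: float
    min_residual: float
    max_residual: float
    n: int
    exclusions: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.min_residual > self.max_residual:
            raise ValueError("min residual exceeds max")


def _residual_series(records) -> pd.Series:
    if isinstance(records, pd.Series):
        return records.astype(float)
    if isinstance(records, Mapping):
        return pd.Series(records, dtype=float)
    recs = list(records)
    if recs and isinstance(recs[0], ResidualRecord):
        return pd.Series({r.material: r.residual_pct for r in recs}, dtype=float)
    return pd.Series(np.asarray(recs, dtype=float))


def summarize_residuals(records, exclusions: Iterable[str] = ()) -> SummaryStats:
    """Summarise residuals (mean |residual|, signed min/max) after exclusions.

    ``records`` may be a sequence of :class:`ResidualRecord`, a mapping or
    pandas Series of material -> residual %, or a plain residual array (in
    which case exclusions must be empty).
    """
    series = _residual_series(records)
    exclusions = tuple(exclusions)
    if exclusions:
        missing = [e for e in exclusions if e not in series.index]
        if missing:
            raise KeyError(f"exclusions not present: {missing}")
        series = series.drop(index=list(exclusions))
    if series.empty:
        raise ValueError("no records remain after exclusions")
    return SummaryStats(
        mean_abs_residual=float(series.abs().mean()),
        min_residual=float(series.min()),
        max_residual=float(series.max()),
        n=int(series.size),
        exclusions=exclusions,
    )


def build_report(
    predicted: pd.DataFrame,
    measured: Mapping[str, float],
    *,
    summary_exclusions: Sequence[str] = (),
    decimals: int = 2,
) -> tuple[pd.DataFrame, dict]:
    """Assemble a residual table (material rows x method columns) + summary.

    ``predicted`` holds SPR_CT per material (index) and method (columns);
    ``measured`` maps material -> SPR_meas. Materials without a measured SPR
    are kept in the table, flagged in the ``missing_measurement`` column,
    with NaN residuals. The summary block (per method: mean absolute
    residual at one decimal plus signed range) skips flagged rows and any
    named ``summary_exclusions``.

    Returns the display-rounded residual table and a JSON-ready summary dict
    with full-precision values.
    """
    residuals = pd.DataFrame(index=predicted.index, columns=predicted.columns,
                             dtype=float)
    flags = pd.Series(False, index=predicted.index)
    for material in predicted.index:
        if material not in measured:
            flags[material] = True
            continue
        residuals.loc[material] = relative_residual(
            predicted.loc[material].to_numpy(dtype=float), measured[material])

    summary: dict = {"exclusions": list(summary_exclusions),
                     "flagged_missing": list(predicted.index[flags])}
    drop = set(summary_exclusions) | set(predicted.index[flags])
    for method in predicted.columns:
        col = residuals[method].drop(index=[m for m in drop
                                            if m in residuals.index])
        col = col.dropna()
        if col.empty:
            continue
        stats = summarize_residuals(col)
        summary[method] = {
            "mean_abs_residual_pct": stats.mean_abs_residual,
            "mean_abs_residual_display": round(stats.mean_abs_residual, 1),
            "min_residual_pct": stats.min_residual,
            "max_residual_pct": stats.max_residual,
            "n": stats.n,
        }

    table = residuals.round(decimals)
    table["missing_measurement"] = flags
    return table, summary
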