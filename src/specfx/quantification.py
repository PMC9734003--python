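"""External-standard calibration, content conversion, and method validation.

A calibration curve regresses peak area on standard concentration (mg/mL).
Sample content in mg per g of freeze-dried powder follows from the inverted
curve and the preparation's dilution factor (default 0.1 g made up to 10 mL,
i.e. content = 100 * concentration).  Validation metrics are the relative
standard deviation of replicate sets and the spike recovery percentage.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "CalibrationCurve",
    "fit_calibration",
    "area_to_content",
    "rsd_percent",
    "recovery_percent",
    "validation_metrics",
    "ContentSummary",
    "content_summary",
]


@dataclass(frozen=True)
class CalibrationCurve:
    """area = slope * concentration + intercept, valid over ``linear_range`` (mg/mL)."""

    compound: str
    slope: float
    intercept: float
    r: float
    linear_range: tuple[float, float]

    def __post_init__(self) -> None:
        if self.slope <= 0:
            raise ValueError("calibration slope must be positive")
        if abs(self.r) > 1 + 1e-12:
            raise ValueError("|r| cannot exceed 1")
        lo, hi = self.linear_range
        if not lo < hi:
            raise ValueError("linear range must satisfy low < high")

    def predict_area(self, conc: float) -> float:
        return self.slope * conc + self.intercept


def fit_calibration(
    conc: Sequence[float], area: Sequence[float], compound: str = ""
) -> CalibrationCurve:
    """Ordinary least squares of peak area on standard concentration."""
    conc = np.asarray(conc, dtype=float)
    area = np.asarray(area, dtype=float)
    if conc.size < 3:
        raise ValueError("calibration needs at least 3 points")
    if np.ptp(conc) == 0:
        raise ValueError("calibration concentrations are constant")
    res = stats.linregress(conc, area)
    return CalibrationCurve(
        compound, float(res.slope), float(res.intercept), float(res.rvalue),
        (float(conc.min()), float(conc.max())),
    )


def area_to_content(
    curve: CalibrationCurve,
    area: float,
    sample_mass: float = 0.1,
    volume: float = 10.0,
) -> float:
    """Convert a peak area to mg of analyte per g of freeze-dried powder.

    conc = (area - intercept)/slope in mg/mL; content = conc * volume / mass.
    Concentrations outside the curve's linear range warn but do not fail.
    """
    if sample_mass <= 0 or volume <= 0:
        raise ValueError("sample mass and volume must be positive")
    conc = (area - curve.intercept) / curve.slope
    if conc < 0:
        raise ValueError(
            f"area {area} below intercept for {curve.compound or 'curve'}: negative concentration"
        )
    lo, hi = curve.linear_range
    if not lo <= conc <= hi:
        warnings.warn(
            f"concentration {conc:.4g} mg/mL outside linear range [{lo}, {hi}] "
            f"for {curve.compound or 'curve'}",
            stacklevel=2,
        )
    return conc * volume / sample_mass


def rsd_percent(values: Sequence[float]) -> float:
    """Relative standard deviation, 100 * sd / mean with the sample (n-1) sd."""
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise ValueError("RSD needs at least two replicates")
    m = v.mean()
    if m == 0:
        raise ValueError("RSD undefined for zero mean")
    return float(100.0 * v.std(ddof=1) / m)


def recovery_percent(measured_total: float, original: float, added: float) -> float:
    """Spike recovery, 100 * (measured_total - original) / added."""
    if added == 0:
        raise ValueError("recovery undefined when nothing was added")
    return 100.0 * (measured_total - original) / added


def validation_metrics(repeat_sets: Mapping[str, Sequence[float]]) -> pd.DataFrame:
    """Mean, sample SD and RSD% for each named replicate set (precision,
    repeatability, stability, ...)."""
    rows = []
    for name, values in repeat_sets.items():
        v = np.asarray(values, dtype=float)
        rows.append(
            {"set": name, "n": v.size, "mean": v.mean(), "sd": v.std(ddof=1),
             "rsd_pct": rsd_percent(v)}
        )
    return pd.DataFrame(rows).set_index("set")


@dataclass
class ContentSummary:
    """Descriptive summaries of a batches x compounds content matrix."""

    means: pd.Series                # per compound, sorted descending
    ranking: list[str]              # compound labels, highest mean first
    ranking_chain: str              # "X4 > X5 > ..." display form
    totals: pd.Series               # per batch row sums
    zscores: pd.DataFrame           # per-compound z-scored matrix (heatmap input)
    constant_compounds: list[str]   # compounds with zero variance, excluded from zscores
    box_stats: pd.DataFrame         # per compound: q1, median, q3, iqr, whiskers


def content_summary(matrix: pd.DataFrame) -> ContentSummary:
    """Summaries behind the heatmap, box plot, totals bar and mean ranking.

    Ranking sorts compounds by mean content (ties broken by label); the
    heatmap matrix is per-compound z-scored (sample sd); box statistics use
    linearly interpolated quartiles with Tukey 1.5*IQR whiskers clipped to
    the data range.
    """
    if matrix.empty:
        raise ValueError("content matrix is empty")
    means = matrix.mean(axis=0)
    order = sorted(means.index, key=lambda c: (-means[c], c))
    means = means.loc[order]
    totals = matrix.sum(axis=1)

    sds = matrix.std(ddof=1)
    constant = [c for c in matrix.columns if not sds[c] > 0]
    live = [c for c in matrix.columns if c not in constant]
    zscores = (matrix[live] - matrix[live].mean()) / matrix[live].std(ddof=1)

    rows = []
    for c in matrix.columns:
        col = matrix[c].to_numpy()
        q1, med, q3 = np.percentile(col, [25, 50, 75])  # linear interpolation
        iqr = q3 - q1
        lo = col[col >= q1 - 1.5 * iqr].min()
        hi = col[col <= q3 + 1.5 * iqr].max()
        rows.append({"compound": c, "q1": q1, "median": med, "q3": q3,
                     "iqr": iqr, "whisker_low": lo, "whisker_high": hi,
                     "mean": matrix[c].mean()})
    box = pd.DataFrame(rows).set_index("compound")

    return ContentSummary(
        means=means,
        ranking=order,
        ranking_chain=" > ".join(order),
        totals=totals,
        zscores=zscores,
        constant_compounds=constant,
        box_stats=box,
    )
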