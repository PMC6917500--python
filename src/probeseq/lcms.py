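"""Stable-isotope / analog internal-standard LC-MS/MS quantification.

Quantification proceeds in three steps:

1.  A *working curve* relates the analyte/internal-standard concentration
    ratio Y = C_A/C_IS to the measured peak-area ratio X = P_A/P_IS through
    a straight line Y = p·X + q fitted on standards of known concentration.
2.  For a sample measured against k internal standards, the k back-computed
    concentrations are averaged with weights equal to the internal-standard
    peak areas, C̄ = Σ C_k·A_k / Σ A_k.
3.  Concentrations in the extraction solvent are converted to intracellular
    concentrations by the volume ratio C_intra = C̄ · V_extract / (N · V_cell),
    with a default 40 µL extract and a mean single-cell volume of
    1.3e-6 µL.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import statsmodels.api as sm

__all__ = [
    "WorkingCurve",
    "CellExtract",
    "Quantification",
    "fit_working_curve",
    "conc_from_peaks",
    "weighted_mean_conc",
    "intracellular_conc",
    "residual_percent",
]


@dataclass(frozen=True)
class WorkingCurve:
    """Linear calibration Y = p·X + q of concentration ratio on peak-area ratio."""

    analyte: str
    internal_standard: str
    p: float
    q: float
    valid_range: tuple[float, float]  # (min, max) of calibrated concentration ratio
    r2: float

    def __post_init__(self) -> None:
        if self.p == 0:
            raise ValueError("working-curve slope p must be nonzero")
        if not self.valid_range[0] < self.valid_range[1]:
            raise ValueError(f"invalid valid_range {self.valid_range}")


@dataclass(frozen=True)
class CellExtract:
    """Extraction metadata converting extract to intracellular concentration."""

    extract_volume: float = 40.0  # µL
    cell_count: float = 2e5
    mean_cell_volume: float = 1.3e-6  # µL per cell

    def __post_init__(self) -> None:
        for name in ("extract_volume", "cell_count", "mean_cell_volume"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be strictly positive")


@dataclass(frozen=True)
class Quantification:
    """A back-computed concentration with an extrapolation flag."""

    conc: float
    in_range: bool


def fit_working_curve(
    points: Sequence[tuple[float, float]],
    analyte: str = "",
    internal_standard: str = "",
) -> WorkingCurve:
    """OLS fit of concentration ratio Y on peak-area ratio X.

    Needs >= 3 calibration points spanning a nonzero X range.  The intercept
    is fitted freely (not forced through zero or a blank).  ``valid_range``
    is set to the [min, max] of the calibrated Y values.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[0] < 3:
        raise ValueError("need at least 3 (peak_ratio, conc_ratio) calibration points")
    x, y = pts[:, 0], pts[:, 1]
    if np.ptp(x) == 0:
        raise ValueError("degenerate calibration: peak ratios have zero variance")
    res = sm.OLS(y, sm.add_constant(x)).fit()
    q, p = res.params
    return WorkingCurve(
        analyte=analyte,
        internal_standard=internal_standard,
        p=float(p),
        q=float(q),
        valid_range=(float(y.min()), float(y.max())),
        r2=float(res.rsquared),
    )


def conc_from_peaks(curve: WorkingCurve, p_a: float, p_is: float, c_is: float) -> Quantification:
    """Back-compute C_A = (p·P_A/P_IS + q) · C_IS from measured peak areas.

    Results outside the curve's calibrated ratio range are flagged, not
    rejected.
    """
    if p_is <= 0:
        raise ZeroDivisionError("internal-standard peak area must be positive")
    if c_is <= 0:
        raise ValueError("internal-standard concentration must be positive")
    y = curve.p * (p_a / p_is) + curve.q
    lo, hi = curve.valid_range
    return Quantification(conc=y * c_is, in_range=bool(lo <= y <= hi))


def weighted_mean_conc(concs: Sequence[float], is_areas: Sequence[float]) -> float:
    """Peak-area-weighted mean of concentrations from multiple internal standards.

    C̄ = Σ_k C_k·A_k / Σ_k A_k.  Written for the three-standard case but
    accepts any length >= 1.  Invariant under uniform rescaling of the
    weights.
    """
    c = np.asarray(concs, dtype=float)
    a = np.asarray(is_areas, dtype=float)
    if c.shape != a.shape or c.ndim != 1 or c.size < 1:
        raise ValueError("concs and is_areas must be equal-length 1-D sequences")
    if np.any(a < 0):
        raise ValueError("peak areas must be non-negative")
    total = a.sum()
    if total <= 0:
        raise ZeroDivisionError("all internal-standard peak areas are zero")
    return float(np.dot(c, a) / total)


def intracellular_conc(c_bar: float, extract: CellExtract) -> float:
    """Convert extract concentration to intracellular concentration.

    C_intra = C̄ · V_extract / (N · V_cell).
    """
    return c_bar * extract.extract_volume / (extract.cell_count * extract.mean_cell_volume)


def residual_percent(conc_t: float, conc_t0: float) -> float:
    """Percentage of analyte remaining relative to the t=0 concentration."""
    if conc_t0 <= 0:
        raise ValueError("initial concentration must be positive")
    return 100.0 * conc_t / conc_t0
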