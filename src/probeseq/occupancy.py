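"""Competitive-binding constants and multi-ligand target-occupancy fractions.

A cofactor-competitive inhibitor assayed at cofactor concentration ``[SAM]``
shows an apparent potency

    IC50 = [SAM] * Kd / Km_SAM + Kd,

a Cheng–Prusoff-type relation that is linear in ``[SAM]`` with y-intercept
``Kd`` (the inhibitor dissociation constant) and slope ``Kd / Km_SAM``.
Fitting IC50 against a titration of the cofactor therefore yields both the
true inhibitor affinity and ``Km_SAM`` (ratio of intercept to slope).

At equilibrium inside a cell, an enzyme partitions between the apo state,
the cofactor-bound state and one state per competing inhibitor.  With
``w_SAM = C_SAM / Km_SAM`` and ``w_i = C_i / Kd_i`` the occupied fractions
are

    apo   = 1 / (1 + w_SAM + sum_i w_i)
    SAM   = w_SAM / (1 + w_SAM + sum_i w_i)
    inh_i = w_i / (1 + w_SAM + sum_i w_i)

All concentrations are micromolar and are treated as *free* concentrations
(ligand in large excess over enzyme; no depletion term).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import statsmodels.api as sm

__all__ = [
    "BindingConstants",
    "LigandConcentrations",
    "OccupancyState",
    "CompetitionFit",
    "kd_from_ic50",
    "ic50_from_kd",
    "fit_sam_competition_line",
    "occupancy",
    "occupancy_timecourse",
]


@dataclass(frozen=True)
class BindingConstants:
    """Dissociation constants (µM) of the cofactor and each inhibitor.

    ``kd_sam`` doubles as the Michaelis constant of the cofactor: the
    occupancy model uses the approximation Km,SAM ≈ Kd,SAM throughout.
    """

    enzyme_name: str
    kd_sam: float
    inhibitors: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.kd_sam > 0:
            raise ValueError(f"kd_sam must be positive, got {self.kd_sam}")
        object.__setattr__(self, "inhibitors", dict(self.inhibitors))
        for name, kd in self.inhibitors.items():
            if not kd > 0:
                raise ValueError(f"Kd of inhibitor {name!r} must be positive, got {kd}")


@dataclass(frozen=True)
class LigandConcentrations:
    """Free intracellular ligand concentrations (µM)."""

    sam: float
    inhibitors: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.sam < 0:
            raise ValueError(f"SAM concentration must be non-negative, got {self.sam}")
        object.__setattr__(self, "inhibitors", dict(self.inhibitors))
        for name, c in self.inhibitors.items():
            if c < 0:
                raise ValueError(f"concentration of {name!r} must be non-negative, got {c}")


@dataclass(frozen=True)
class OccupancyState:
    """Percentages of enzyme in the apo, cofactor-bound and inhibitor-bound states.

    Invariant: ``apo_pct + sam_pct + sum(inhibitor_pct.values()) == 100``
    (to 1e-9 relative tolerance).
    """

    apo_pct: float
    sam_pct: float
    inhibitor_pct: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        object.__setattr__(self, "inhibitor_pct", dict(self.inhibitor_pct))
        total = self.apo_pct + self.sam_pct + sum(self.inhibitor_pct.values())
        if not math.isclose(total, 100.0, rel_tol=1e-9):
            raise ValueError(f"occupancies must sum to 100, got {total}")

    @property
    def total_inhibitor_pct(self) -> float:
        """Combined occupancy by all inhibitors (%)."""
        return sum(self.inhibitor_pct.values())


def kd_from_ic50(ic50: float, sam_conc: float, kd_sam: float) -> float:
    """Invert the competitive relation: Kd = IC50 / (1 + [SAM]/Km,SAM).

    Parameters are in any single consistent concentration unit.
    """
    if not ic50 > 0:
        raise ValueError(f"ic50 must be positive, got {ic50}")
    if not kd_sam > 0:
        raise ValueError(f"kd_sam must be positive, got {kd_sam}")
    if sam_conc < 0:
        raise ValueError(f"sam_conc must be non-negative, got {sam_conc}")
    return ic50 / (1.0 + sam_conc / kd_sam)


def ic50_from_kd(kd: float, sam_conc: float, kd_sam: float) -> float:
    """Forward competitive relation: IC50 = [SAM] * Kd / Km,SAM + Kd."""
    if not kd > 0:
        raise ValueError(f"kd must be positive, got {kd}")
    if not kd_sam > 0:
        raise ValueError(f"kd_sam must be positive, got {kd_sam}")
    if sam_conc < 0:
        raise ValueError(f"sam_conc must be non-negative, got {sam_conc}")
    return sam_conc * kd / kd_sam + kd


@dataclass(frozen=True)
class CompetitionFit:
    """OLS fit of IC50 against cofactor concentration.

    ``kd`` is the y-intercept, ``slope`` is Kd/Km,SAM, and ``km_sam`` their
    ratio.  ``nonphysical`` flags a fit whose intercept or slope is not
    strictly positive; values are still reported.
    """

    kd: float
    slope: float
    km_sam: float
    kd_se: float
    slope_se: float
    r2: float
    residuals: np.ndarray
    nonphysical: bool


def fit_sam_competition_line(points: Sequence[tuple[float, float]]) -> CompetitionFit:
    """Fit IC50 = slope * [SAM] + Kd by ordinary least squares.

    ``points`` are ([SAM], IC50) pairs in one concentration unit.  Requires
    at least three points with non-identical [SAM] values.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[0] < 3:
        raise ValueError("need at least 3 (sam_conc, ic50) points")
    sam, ic50 = pts[:, 0], pts[:, 1]
    if np.ptp(sam) == 0:
        raise ValueError("sam_conc values must not all be identical")

    X = sm.add_constant(sam)
    res = sm.OLS(ic50, X).fit()
    intercept, slope = res.params
    nonphysical = not (intercept > 0 and slope > 0)
    km_sam = intercept / slope if slope != 0 else math.nan
    return CompetitionFit(
        kd=float(intercept),
        slope=float(slope),
        km_sam=float(km_sam),
        kd_se=float(res.bse[0]),
        slope_se=float(res.bse[1]),
        r2=float(res.rsquared),
        residuals=np.asarray(res.resid),
        nonphysical=nonphysical,
    )


def occupancy(concs: LigandConcentrations, constants: BindingConstants) -> OccupancyState:
    """Equilibrium occupancy fractions for a cofactor and competing inhibitors.

    Ligands named in ``concs.inhibitors`` must have a Kd in ``constants``;
    inhibitors with no supplied concentration are treated as absent.
    """
    unknown = set(concs.inhibitors) - set(constants.inhibitors)
    if unknown:
        raise KeyError(f"no binding constant for ligand(s): {sorted(unknown)}")

    w_sam = concs.sam / constants.kd_sam
    w = {name: c / constants.inhibitors[name] for name, c in concs.inhibitors.items()}
    denom = 1.0 + w_sam + sum(w.values())
    return OccupancyState(
        apo_pct=100.0 / denom,
        sam_pct=100.0 * w_sam / denom,
        inhibitor_pct={name: 100.0 * wi / denom for name, wi in w.items()},
    )


def occupancy_timecourse(
    series: Sequence[tuple[float, LigandConcentrations]],
    constants: BindingConstants,
) -> list[tuple[float, OccupancyState]]:
    """Element-wise occupancy over a time series of ligand concentrations.

    Times must be strictly increasing.  Supports modeling of the buildup of
    combined target engagement as intracellular inhibitor species accumulate.
    """
    times = [t for t, _ in series]
    if any(t1 >= t2 for t1, t2 in zip(times, times[1:])):
        raise ValueError("times must be strictly increasing")
    return [(t, occupancy(c, constants)) for t, c in series]
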