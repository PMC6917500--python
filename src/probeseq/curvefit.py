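"""Dose-response, percent-inhibition and thermal-melt curve fitting.

Covers the three fitted readouts of the biochemical and cellular assays:

* radiometric percent inhibition from scintillation counts,
* half-maximal potency from a four-parameter logistic in log10 dose
  (``fit_ic50``) or a saturation hyperbola
  Inhibition% = Max% · [I] / ([I] + EC50) (``fit_saturation_ec50``),
* melting temperature from a Boltzmann sigmoid on min/max-normalized
  fluorescence or band-intensity melts, with Tm the midpoint temperature
  (50% relative signal).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.optimize import curve_fit

__all__ = [
    "DoseResponseFit",
    "MeltCurve",
    "FitError",
    "percent_inhibition",
    "fit_ic50",
    "fit_saturation_ec50",
    "normalize_fluorescence",
    "fit_melting_curve",
]


class FitError(RuntimeError):
    """Nonlinear least squares failed to converge or is ill-posed."""


@dataclass(frozen=True)
class DoseResponseFit:
    """Result of a dose-response fit.

    ``model`` is ``"sigmoid_logconc"`` (4PL on log10 dose; ``ec50`` is the
    back-transformed inflection, ``hill`` the slope) or
    ``"saturation_hyperbola"`` (``ec50`` and ``max_effect_pct``).
    Standard errors come from the asymptotic covariance of the fit.
    """

    model: str
    ec50: float
    max_effect_pct: float | None = None
    hill: float | None = None
    floor: float | None = None
    ceiling: float | None = None
    ec50_se: float = float("nan")
    max_effect_se: float = float("nan")
    dof: int = 0  # residual degrees of freedom, for t-based intervals
    residuals: np.ndarray = field(default_factory=lambda: np.empty(0))

    def __post_init__(self) -> None:
        if not self.ec50 > 0:
            raise FitError(f"fitted ec50 must be positive, got {self.ec50}")


@dataclass(frozen=True)
class MeltCurve:
    """A normalized melt with its fitted midpoint temperature."""

    temperatures: np.ndarray
    signal: np.ndarray
    tm: float
    tm_se: float
    slope: float
    in_range: bool


def percent_inhibition(cpm: float, cpm_high: float, cpm_background: float) -> float:
    """Percent inhibition from scintillation counts.

    100 · (high − observed) / (high − background).  The no-inhibitor
    reaction supplies the high readout and the enzyme-free reaction the
    background.  Values outside [0, 100] are returned unclipped so noise is
    visible to the caller.
    """
    if cpm_high <= cpm_background:
        raise ValueError("cpm_high must exceed cpm_background")
    return 100.0 * (cpm_high - cpm) / (cpm_high - cpm_background)


def _logistic4(logc, floor, ceiling, logec50, hill):
    return floor + (ceiling - floor) / (1.0 + 10.0 ** ((logec50 - logc) * hill))


def fit_ic50(
    concs: Sequence[float],
    inhibition_pct: Sequence[float],
    fix_floor: float | None = None,
    fix_ceiling: float | None = None,
) -> DoseResponseFit:
    """Four-parameter logistic fit of percent inhibition on log10 concentration.

    Asymptotes are free by default; pass ``fix_floor=0`` / ``fix_ceiling=100``
    to constrain them.  Requires >= 4 positive doses.
    """
    x = np.asarray(concs, dtype=float)
    y = np.asarray(inhibition_pct, dtype=float)
    if x.size < 4:
        raise ValueError("need at least 4 dose points")
    if np.any(x <= 0):
        raise ValueError("concentrations must be positive")
    logx = np.log10(x)

    p0_log_ec50 = float(np.median(logx))
    free: list[str] = []
    p0: list[float] = []

    def model(logc, *params):
        d = dict(zip(free, params))
        floor = fix_floor if fix_floor is not None else d["floor"]
        ceiling = fix_ceiling if fix_ceiling is not None else d["ceiling"]
        return _logistic4(logc, floor, ceiling, d["logec50"], d["hill"])

    if fix_floor is None:
        free.append("floor"), p0.append(float(y.min()))
    if fix_ceiling is None:
        free.append("ceiling"), p0.append(float(y.max()))
    free += ["logec50", "hill"]
    p0 += [p0_log_ec50, 1.0]

    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            popt, pcov = curve_fit(model, logx, y, p0=p0, maxfev=20000)
    except RuntimeError as exc:  # pragma: no cover - scipy message passthrough
        raise FitError(f"IC50 fit did not converge: {exc}") from exc
    d = dict(zip(free, popt))
    se = dict(zip(free, np.sqrt(np.maximum(np.diag(pcov), 0.0))))
    ec50 = 10.0 ** d["logec50"]
    resid = y - model(logx, *popt)
    return DoseResponseFit(
        model="sigmoid_logconc",
        ec50=float(ec50),
        hill=float(d["hill"]),
        floor=fix_floor if fix_floor is not None else float(d["floor"]),
        ceiling=fix_ceiling if fix_ceiling is not None else float(d["ceiling"]),
        # delta method: SE(ec50) = ln(10) * ec50 * SE(log10 ec50)
        ec50_se=float(np.log(10.0) * ec50 * se["logec50"]),
        dof=int(x.size - len(popt)),
        residuals=resid,
    )


def fit_saturation_ec50(
    concs: Sequence[float], inhibition_pct: Sequence[float]
) -> DoseResponseFit:
    """Nonlinear least squares for Inhibition% = Max% · [I] / ([I] + EC50)."""
    x = np.asarray(concs, dtype=float)
    y = np.asarray(inhibition_pct, dtype=float)
    if x.size < 3:
        raise ValueError("need at least 3 dose points")
    if np.any(x < 0):
        raise ValueError("concentrations must be non-negative")

    def model(c, vmax, ec50):
        return vmax * c / (c + ec50)

    p0 = [max(float(y.max()), 1.0), float(np.median(x[x > 0])) if np.any(x > 0) else 1.0]
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            popt, pcov = curve_fit(model, x, y, p0=p0, maxfev=20000)
    except RuntimeError as exc:  # pragma: no cover
        raise FitError(f"saturation fit did not converge: {exc}") from exc
    vmax, ec50 = popt
    se = np.sqrt(np.maximum(np.diag(pcov), 0.0))
    return DoseResponseFit(
        model="saturation_hyperbola",
        ec50=float(ec50),
        max_effect_pct=float(vmax),
        ec50_se=float(se[1]),
        max_effect_se=float(se[0]),
        dof=int(x.size - 2),
        residuals=y - model(x, *popt),
    )


def normalize_fluorescence(raw: Sequence[float]) -> np.ndarray:
    """Affine map of raw readouts onto [0, 100]% (min → 0, max → 100)."""
    r = np.asarray(raw, dtype=float)
    lo, hi = r.min(), r.max()
    if hi == lo:
        raise ValueError("constant signal cannot be normalized")
    return 100.0 * (r - lo) / (hi - lo)


def fit_melting_curve(
    temps: Sequence[float], normalized_signal: Sequence[float]
) -> MeltCurve:
    """Boltzmann sigmoid fit of a normalized melt; Tm is the midpoint.

    signal(T) = floor + (ceiling − floor) / (1 + exp((tm − T)/slope)).
    The fitted ``tm`` is the temperature of 50% relative signal.  Both
    rising (fluorescence) and falling (soluble-fraction) melts are handled
    by the sign of ``slope``.  A midpoint outside the measured temperature
    range raises a warning and flags the result.
    """
    t = np.asarray(temps, dtype=float)
    y = np.asarray(normalized_signal, dtype=float)
    if t.size < 5:
        raise ValueError("need at least 5 temperature points")
    if np.any(np.diff(t) <= 0):
        raise ValueError("temperatures must be strictly increasing")

    def model(T, floor, ceiling, tm, slope):
        return floor + (ceiling - floor) / (1.0 + np.exp((tm - T) / slope))

    rising = y[-1] >= y[0]
    p0 = [float(y.min()), float(y.max()), float(t[np.argmin(np.abs(y - 50.0))]),
          (1.0 if rising else -1.0) * max(np.ptp(t) / 20.0, 0.5)]
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            popt, pcov = curve_fit(model, t, y, p0=p0, maxfev=20000)
    except RuntimeError as exc:  # pragma: no cover
        raise FitError(f"melting-curve fit did not converge: {exc}") from exc
    floor, ceiling, tm, slope = popt
    tm_se = float(np.sqrt(max(pcov[2, 2], 0.0)))
    in_range = bool(t.min() <= tm <= t.max())
    if not in_range:
        warnings.warn(
            f"fitted Tm {tm:.2f} lies outside the measured range "
            f"[{t.min():.2f}, {t.max():.2f}]",
            stacklevel=2,
        )
    return MeltCurve(
        temperatures=t, signal=y, tm=float(tm), tm_se=tm_se,
        slope=float(slope), in_range=in_range,
    )
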