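"""Viability computation and four-parameter logistic (4PL) IC50 fitting.

Viability is the plate-reader absorbance of treated wells relative to
untreated controls, ×100. The dose-response model is the standard 4PL
sigmoid in log10 concentration,

    v(c) = bottom + (top − bottom) / (1 + 10^(hill · (log10 c − log10 IC50)))

with ``hill > 0`` meaning viability falls as concentration rises. The
curve passes through (top+bottom)/2 exactly at c = IC50 by construction.
Replicates enter the fit as individual points so the IC50 standard error
reflects replicate scatter.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit

__all__ = [
    "PlateMeasurement",
    "DoseResponseFit",
    "FitError",
    "viability_percent",
    "serial_dilution",
    "logistic4",
    "fit_4pl",
]


@dataclass(frozen=True)
class PlateMeasurement:
    """One microplate well: concentration, absorbance, replicate index."""

    concentration: float  # mg/mL; 0 allowed only for control wells
    absorbance: float  # AU
    replicate: int
    is_control: bool = False

    def __post_init__(self) -> None:
        if self.concentration < 0:
            raise ValueError("concentration must be non-negative")
        if self.absorbance < 0:
            raise ValueError("absorbance must be non-negative")


@dataclass(frozen=True)
class DoseResponseFit:
    """A fitted 4PL curve with IC50 and its standard error."""

    top: float  # upper viability plateau, %
    bottom: float  # lower plateau, %
    ic50: float  # concentration at the curve midpoint
    hill: float  # slope factor (positive: viability decreases)
    se_ic50: float  # standard error of IC50 from the fit covariance
    converged: bool

    def predict(self, concentration: float | np.ndarray) -> np.ndarray:
        return logistic4(
            np.asarray(concentration, dtype=float),
            self.top,
            self.bottom,
            math.log10(self.ic50),
            self.hill,
        )


class FitError(RuntimeError):
    """Too few points, degenerate response, or optimizer failure."""


def viability_percent(abs_test: float, abs_control: float) -> float:
    """Cell viability %: test-well absorbance over control absorbance ×100."""
    if abs_control <= 0:
        raise ValueError("control absorbance must be positive")
    return abs_test / abs_control * 100.0


def serial_dilution(start: float, factor: float, n: int) -> list[float]:
    """Geometric dilution series start/factor^k for k = 0..n−1."""
    if start <= 0:
        raise ValueError("start concentration must be positive")
    if factor <= 1:
        raise ValueError("dilution factor must exceed 1")
    if n < 1:
        raise ValueError("need at least one concentration")
    return [start / factor**k for k in range(n)]


def logistic4(
    conc: np.ndarray, top: float, bottom: float, log10_ic50: float, hill: float
) -> np.ndarray:
    """4PL response at the given concentrations (log10 parameterization).

    Zero concentration is the untreated limit and evaluates to ``top``
    exactly (for hill > 0), so control wells can enter a fit as plateau
    anchors.
    """
    with np.errstate(divide="ignore"):
        log_c = np.log10(conc)
    return bottom + (top - bottom) / (1.0 + 10.0 ** (hill * (log_c - log10_ic50)))


def fit_4pl(points: list[tuple[float, float]]) -> DoseResponseFit:
    """Least-squares 4PL fit of (concentration, viability %) points.

    Zero-concentration points (untreated controls) are accepted and pin
    the upper plateau — essential when, as in a dilution series whose
    lowest dose sits near the IC50, the data alone never reach the top
    plateau. Initialization comes from the data: plateaus from the
    response range, IC50 from the concentration whose mean response is
    closest to the half-way level, hill = 1. IC50 is bounded inside the
    tested concentration range ×[0.01, 100] so the optimizer cannot
    wander onto an unconstrained plateau. Non-convergence raises
    :class:`FitError`.
    """
    conc = np.asarray([c for c, _ in points], dtype=float)
    resp = np.asarray([v for _, v in points], dtype=float)
    if np.any(conc < 0):
        raise ValueError("concentrations must be non-negative")
    distinct = np.unique(conc[conc > 0])
    if distinct.size < 5:
        raise FitError(
            f"need ≥5 distinct positive concentrations, got {distinct.size}"
        )
    if np.ptp(resp) < 1e-9:
        raise FitError("degenerate (constant) response")

    top0 = float(np.max(resp))
    bottom0 = float(np.min(resp))
    half = (top0 + bottom0) / 2.0
    means = np.array([resp[conc == c].mean() for c in distinct])
    ic50_0 = float(distinct[np.argmin(np.abs(means - half))])
    p0 = [top0, bottom0, math.log10(ic50_0), 1.0]
    log_lo = math.log10(distinct.min() * 0.01)
    log_hi = math.log10(distinct.max() * 100.0)
    bounds = ([-np.inf, -np.inf, log_lo, 0.01], [np.inf, np.inf, log_hi, 50.0])
    try:
        popt, pcov = curve_fit(
            logistic4, conc, resp, p0=p0, bounds=bounds, maxfev=20000
        )
    except (RuntimeError, ValueError) as exc:
        raise FitError(f"4PL fit did not converge: {exc}") from exc

    top, bottom, log_ic50, hill = popt
    ic50 = 10.0**log_ic50
    var_log = pcov[2, 2]
    converged = bool(np.all(np.isfinite(pcov)))
    # delta method: se(ic50) = ic50 · ln(10) · se(log10 ic50)
    se_ic50 = (
        float(ic50 * math.log(10) * math.sqrt(var_log))
        if np.isfinite(var_log) and var_log >= 0
        else float("nan")
    )
    if bottom > top:
        # Mirror parameterization: swap plateaus and flip the slope sign so
        # the reported fit always has bottom ≤ top.
        top, bottom, hill = bottom, top, -hill
    return DoseResponseFit(
        top=float(top),
        bottom=float(bottom),
        ic50=float(ic50),
        hill=float(hill),
        se_ic50=se_ic50,
        converged=converged,
    )


def viability_table(measurements: list[PlateMeasurement]) -> list[tuple[float, float]]:
    """Convert plate wells to (concentration, viability %) fit points.

    Control wells define the reference absorbance as their mean and are
    kept as zero-concentration points (anchoring the 4PL top plateau);
    treated wells become individual points, one per replicate.
    """
    controls = [m.absorbance for m in measurements if m.is_control]
    if not controls:
        raise ValueError("no control wells in plate data")
    reference = sum(controls) / len(controls)
    return [
        (
            0.0 if m.is_control else m.concentration,
            viability_percent(m.absorbance, reference),
        )
        for m in measurements
    ]
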