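"""Cuticle deposition kinetics.

The cuticular membrane (CM) is deposited rapidly early in development;
later the deposition rate falls until mass per unit area is constant —
deposition then just keeps pace with surface expansion.  This module
computes mass-per-area time courses from disc mass measurements, fits a
saturating model to mass-per-area vs time, and derives deposition rates
as the analytic first derivative.  Whole-fruit deposition rates (the
default) multiply the fitted mass-per-area curve by the fitted fruit
surface area, so the reported flux is per organ, not per mm^2.

Models for mass-per-area m(t):

exp_rise : m(t) = m_inf * (1 - exp(-r (t - t0)))
logistic : m(t) = m_inf / (1 + exp(-r (t - t0)))
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit

from .growth import SigmoidFit, growth_rate

__all__ = [
    "MassRecord",
    "DepositionFit",
    "mass_per_area",
    "fit_deposition",
    "deposition_rate",
    "whole_fruit_deposition_rate",
    "area_matched_onset",
]

import warnings


class MassInputWarning(UserWarning):
    pass


@dataclass(frozen=True)
class MassRecord:
    """Dry masses of one cuticle disc (ug) and its area (mm^2)."""

    cultivar: str
    dafb: float
    cm_mass_ug: float
    dcm_mass_ug: float
    disc_area_mm2: float

    def __post_init__(self):
        if self.disc_area_mm2 <= 0:
            raise ValueError("disc_area_mm2 must be > 0")
        if self.dcm_mass_ug < 0 or self.cm_mass_ug < 0:
            raise ValueError("masses must be >= 0")
        if self.cm_mass_ug < self.dcm_mass_ug:
            warnings.warn(
                f"CM mass < DCM mass at {self.dafb} DAFB (negative wax); kept",
                MassInputWarning,
                stacklevel=3,
            )

    @property
    def wax_mass_ug(self) -> float:
        return self.cm_mass_ug - self.dcm_mass_ug


def mass_per_area(rec: MassRecord) -> tuple[float, float, float]:
    """(CM, DCM, wax) mass per unit area in ug/mm^2 (== g/m^2)."""
    a = rec.disc_area_mm2
    return rec.cm_mass_ug / a, rec.dcm_mass_ug / a, rec.wax_mass_ug / a


def _exp_rise(t, m_inf, r, t0):
    return m_inf * (1.0 - np.exp(-r * (np.asarray(t, dtype=float) - t0)))


def _logistic_m(t, m_inf, r, t0):
    return m_inf / (1.0 + np.exp(-r * (np.asarray(t, dtype=float) - t0)))


_MODELS = {"exp_rise": _exp_rise, "logistic": _logistic_m}


@dataclass(frozen=True)
class DepositionFit:
    model: str
    m_inf: float
    r: float
    t0: float
    rss: float
    converged: bool
    t_range: tuple[float, float]

    def predict(self, t):
        return _MODELS[self.model](t, self.m_inf, self.r, self.t0)

    def derivative(self, t):
        t = np.asarray(t, dtype=float)
        if self.model == "exp_rise":
            out = self.m_inf * self.r * np.exp(-self.r * (t - self.t0))
        else:
            e = np.exp(-self.r * (t - self.t0))
            out = self.m_inf * self.r * e / (1.0 + e) ** 2
        return float(out) if out.ndim == 0 else out


def fit_deposition(times, masses, model: str = "exp_rise") -> DepositionFit:
    """Fit a saturating model to a (mass or mass-per-area) vs DAFB series."""
    if model not in _MODELS:
        raise ValueError(f"model must be one of {tuple(_MODELS)}, got {model!r}")
    t = np.asarray(times, dtype=float)
    m = np.asarray(masses, dtype=float)
    if len(t) < 4:
        raise ValueError(f"need >= 4 time points, got {len(t)}")
    m_inf0 = 1.05 * float(np.max(m))
    t00 = float(np.min(t)) - 1.0
    r0 = 1.0 / max(float(np.ptp(t)) / 4.0, 1.0)
    try:
        popt, _ = curve_fit(
            _MODELS[model],
            t,
            m,
            p0=(m_inf0, r0, t00),
            bounds=([1e-12, 1e-12, -np.inf], [np.inf, np.inf, np.inf]),
            maxfev=20000,
        )
        resid = m - _MODELS[model](t, *popt)
        rss = float(resid @ resid)
        converged = bool(np.isfinite(rss))
    except RuntimeError:
        popt, rss, converged = (m_inf0, r0, t00), float("nan"), False
    return DepositionFit(
        model=model,
        m_inf=float(popt[0]),
        r=float(popt[1]),
        t0=float(popt[2]),
        rss=rss,
        converged=converged,
        t_range=(float(np.min(t)), float(np.max(t))),
    )


def deposition_rate(fit: DepositionFit, t):
    """Per-area deposition rate dm/dt (ug mm^-2 day^-1), analytic."""
    return fit.derivative(t)


def whole_fruit_deposition_rate(fit: DepositionFit, growth_fit: SigmoidFit, t):
    """Whole-fruit deposition rate dM/dt in ug/day.

    M(t) = m(t) * A(t) with A in mm^2; by the product rule
    dM/dt = m'(t) A(t) + m(t) A'(t).  Requires the per-area fit and a
    converged surface-area growth fit.
    """
    t = np.asarray(t, dtype=float)
    area_mm2 = np.asarray(growth_fit.predict(t)) * 100.0  # cm^2 -> mm^2
    darea_mm2 = np.asarray(growth_rate(growth_fit, t)) * 100.0
    out = fit.derivative(t) * area_mm2 + fit.predict(t) * darea_mm2
    return float(out) if out.ndim == 0 else out


def area_matched_onset(
    fit: DepositionFit, rel_tol: float = 0.01, grid_step: float = 0.5
) -> float | None:
    """Earliest DAFB at which mass per area has become effectively constant.

    Scans the fitted per-area curve over the data range and returns the
    first grid time where |dm/dt| falls below ``rel_tol`` times its
    magnitude at the start of the range.  From this time on, deposition
    keeps pace with surface expansion.  Returns None (flagged missing)
    when the threshold is never reached in range, e.g. for wax whose
    per-area mass keeps rising.
    """
    lo, hi = fit.t_range
    grid = np.arange(lo, hi + grid_step / 2, grid_step)
    rates = np.abs(np.asarray(fit.derivative(grid)))
    threshold = rel_tol * rates[0]
    below = np.nonzero(rates <= threshold)[0]
    if len(below) == 0:
        return None
    return float(grid[below[0]])
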