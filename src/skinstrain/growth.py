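"""Sigmoid growth kinetics of fruit surface area.

A developing fruit expands its surface in a sigmoid pattern: slow early
growth, a near-linear phase around an inflection, and saturation toward a
final area.  This module fits three-parameter sigmoid models to
area-vs-time series (time in days after full bloom, DAFB) and derives the
area growth rate as the analytic first derivative of the fitted curve.

Models
------
logistic : A(t) = A_max / (1 + exp(-k (t - t_mid)))
    Maximum rate A_max*k/4, attained at t_mid.
gompertz : A(t) = A_max * exp(-exp(-k (t - t_mid)))
    Maximum rate A_max*k/e, attained at t_mid.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit
from scipy.special import expit

__all__ = [
    "GrowthSeries",
    "SigmoidFit",
    "fit_sigmoid",
    "growth_rate",
    "max_growth_rate",
    "regional_growth_summary",
    "logistic",
    "gompertz",
]

MODELS = ("logistic", "gompertz")


class InsufficientDataError(ValueError):
    pass


class NotConvergedError(RuntimeError):
    pass


def logistic(t, a_max, k, t_mid):
    return a_max / (1.0 + np.exp(-k * (np.asarray(t, dtype=float) - t_mid)))


def gompertz(t, a_max, k, t_mid):
    return a_max * np.exp(-np.exp(-k * (np.asarray(t, dtype=float) - t_mid)))


_MODEL_FUNCS = {"logistic": logistic, "gompertz": gompertz}


@dataclass(frozen=True)
class GrowthSeries:
    """One area-vs-time series (whole fruit or one surface region)."""

    cultivar: str
    times: np.ndarray  # DAFB, strictly increasing
    areas: np.ndarray  # cm^2 (whole fruit) or relative units (dot pattern)
    region: str = "whole"

    def __post_init__(self):
        t = np.asarray(self.times, dtype=float)
        a = np.asarray(self.areas, dtype=float)
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "areas", a)
        if t.ndim != 1 or a.shape != t.shape:
            raise ValueError("times and areas must be 1-D and the same length")
        if len(t) and np.any(np.diff(t) <= 0):
            raise ValueError("times must be strictly increasing")
        if np.any(a <= 0):
            raise ValueError("areas must be positive")


@dataclass(frozen=True)
class SigmoidFit:
    """Result of a sigmoid least-squares fit."""

    model: str
    a_max: float
    k: float
    t_mid: float
    rss: float
    converged: bool
    n: int = 0
    cultivar: str = ""
    region: str = "whole"

    def predict(self, t):
        return _MODEL_FUNCS[self.model](t, self.a_max, self.k, self.t_mid)


def _initial_guess(t: np.ndarray, a: np.ndarray) -> tuple[float, float, float]:
    """Deterministic starting values.

    A_max from 1.05x the largest observed area, t_mid from the first time
    the series crosses half of that, and k from a log-linear regression of
    logit(A/A_max0) on t over interior points (falls back to 4/range).
    """
    a_max0 = 1.05 * float(np.max(a))
    half = 0.5 * a_max0
    above = np.nonzero(a >= half)[0]
    t_mid0 = float(t[above[0]]) if len(above) else float(np.median(t))
    frac = np.clip(a / a_max0, 1e-6, 1.0 - 1e-6)
    z = np.log(frac / (1.0 - frac))
    interior = (frac > 0.05) & (frac < 0.95)
    if interior.sum() >= 2 and np.ptp(t[interior]) > 0:
        k0 = float(np.polyfit(t[interior], z[interior], 1)[0])
    else:
        k0 = 4.0 / max(float(np.ptp(t)), 1.0)
    if not np.isfinite(k0) or k0 <= 0:
        k0 = 4.0 / max(float(np.ptp(t)), 1.0)
    return a_max0, k0, t_mid0


def fit_sigmoid(series: GrowthSeries, model: str = "logistic") -> SigmoidFit:
    """Least-squares fit of a sigmoid model to one growth series.

    Optimizer failure is reported via ``converged=False`` rather than an
    exception, so batch fits over many regions never abort.  The
    initialization rule is deterministic, so refitting the same series
    always returns the same parameters.
    """
    if model not in MODELS:
        raise ValueError(f"model must be one of {MODELS}, got {model!r}")
    t, a = series.times, series.areas
    if len(t) < 4:
        raise InsufficientDataError(f"need >= 4 points to fit, got {len(t)}")
    p0 = _initial_guess(t, a)
    func = _MODEL_FUNCS[model]
    try:
        popt, _ = curve_fit(
            func,
            t,
            a,
            p0=p0,
            bounds=([1e-12, 1e-12, -np.inf], [np.inf, np.inf, np.inf]),
            maxfev=20000,
        )
        resid = a - func(t, *popt)
        rss = float(resid @ resid)
        converged = bool(np.isfinite(rss)) and popt[1] > 1e-10
        # flat/degenerate series: any (k, t_mid) with the whole data range in
        # the saturated (or pre-growth) regime fits equally well; flag it
        k_fit, t_mid_fit = popt[1], popt[2]
        if k_fit * (float(t[0]) - t_mid_fit) > 10.0 or k_fit * (t_mid_fit - float(t[-1])) > 10.0:
            converged = False
    except RuntimeError:
        popt, rss, converged = p0, float("nan"), False
    return SigmoidFit(
        model=model,
        a_max=float(popt[0]),
        k=float(popt[1]),
        t_mid=float(popt[2]),
        rss=rss,
        converged=converged,
        n=len(t),
        cultivar=series.cultivar,
        region=series.region,
    )


def growth_rate(fit: SigmoidFit, t) -> np.ndarray | float:
    """Analytic first derivative of the fitted model: dA/dt in cm^2/day."""
    if not fit.converged:
        raise NotConvergedError("growth_rate requires a converged fit")
    t = np.asarray(t, dtype=float)
    if fit.model == "logistic":
        # s(1-s) form is overflow-free far from the inflection
        s = expit(fit.k * (t - fit.t_mid))
        out = fit.a_max * fit.k * s * (1.0 - s)
    else:  # gompertz
        u = np.exp(-fit.k * (t - fit.t_mid))
        out = fit.a_max * fit.k * u * np.exp(-u)
    return float(out) if out.ndim == 0 else out


def max_growth_rate(fit: SigmoidFit) -> tuple[float, float]:
    """Peak growth rate and the DAFB at which it occurs (closed form)."""
    if not fit.converged:
        raise NotConvergedError("max_growth_rate requires a converged fit")
    if fit.model == "logistic":
        return fit.a_max * fit.k / 4.0, fit.t_mid
    return fit.a_max * fit.k / math.e, fit.t_mid


@dataclass
class RegionalSummaryRow:
    region: str
    fit: SigmoidFit
    max_rate: float | None
    t_at_max: float | None
    relative_rate_at_max: float | None  # rate / area at the rate maximum (1/day)
    failed: bool = False


def regional_growth_summary(
    series_list: list[GrowthSeries], model: str = "logistic"
) -> list[RegionalSummaryRow]:
    """Fit each regional series and tabulate absolute and relative rates.

    The relative rate (rate divided by current area) removes the arbitrary
    scale of dot-pattern areas, so regions measured in different units are
    comparable.  Regions whose fit fails are reported with ``failed=True``,
    never dropped.
    """
    if not series_list:
        raise ValueError("series_list must not be empty")
    rows: list[RegionalSummaryRow] = []
    for series in series_list:
        fit = fit_sigmoid(series, model=model)
        if fit.converged:
            rate, t_at = max_growth_rate(fit)
            area_at = float(fit.predict(t_at))
            rows.append(
                RegionalSummaryRow(series.region, fit, rate, t_at, rate / area_at)
            )
        else:
            rows.append(RegionalSummaryRow(series.region, fit, None, None, None, True))
    return rows
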