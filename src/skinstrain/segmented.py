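"""Two-segment continuous piecewise-linear ("broken-stick") regression.

Used to formalize biphasic strain-vs-strain relationships: the elastic and
wax-fixed strain components track total cumulative strain slowly at first,
then rise faster once cuticle deposition stops keeping pace with surface
expansion.  The breakpoint locates the regime change on the eps_total axis.

Estimation is a deterministic exhaustive grid search: every interior data
x value and every midpoint between consecutive x values is a candidate
breakpoint; for each candidate the continuity-constrained least-squares
problem is linear (basis 1, x, max(x - c, 0)) and solved exactly; the
global RSS minimizer wins.  No iterative refinement, so no convergence
pathologies and bitwise-reproducible results.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = ["SegmentedFit", "fit_segmented", "biphasic_test"]

MIN_POINTS = 6
# candidates must leave at least this many points strictly on each side
EDGE_MARGIN = 2


@dataclass(frozen=True)
class SegmentedFit:
    """Continuous two-segment linear fit y = intercept_1 + slope_1*x for
    x <= breakpoint_x, continuing with slope_2 beyond it."""

    breakpoint_x: float
    slope_1: float
    slope_2: float
    intercept_1: float
    rss: float
    linear_rss: float  # single-line fit on the same data, for comparison
    n: int

    def predict(self, x):
        x = np.asarray(x, dtype=float)
        hinge = np.maximum(x - self.breakpoint_x, 0.0)
        return self.intercept_1 + self.slope_1 * x + (self.slope_2 - self.slope_1) * hinge


def _candidate_breakpoints(xs: np.ndarray) -> np.ndarray:
    """Interior x values plus midpoints, excluding the first/last 2 points."""
    lo, hi = xs[EDGE_MARGIN], xs[-EDGE_MARGIN - 1]
    uniq = np.unique(xs)
    mids = 0.5 * (uniq[:-1] + uniq[1:])
    cand = np.concatenate([uniq, mids])
    return np.unique(cand[(cand >= lo) & (cand <= hi)])


def fit_segmented(x, y) -> SegmentedFit:
    """Fit the two-segment model by exhaustive breakpoint search."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D arrays of equal length")
    if len(x) < MIN_POINTS:
        raise ValueError(f"need >= {MIN_POINTS} points, got {len(x)}")
    order = np.argsort(x, kind="stable")
    xs, ys = x[order], y[order]
    if np.ptp(xs) == 0:
        raise ValueError("x values are all equal (degenerate)")

    # single-line baseline
    X1 = np.column_stack([np.ones_like(xs), xs])
    coef1, *_ = np.linalg.lstsq(X1, ys, rcond=None)
    linear_rss = float(np.sum((ys - X1 @ coef1) ** 2))

    best = None
    for c in _candidate_breakpoints(xs):
        X = np.column_stack([np.ones_like(xs), xs, np.maximum(xs - c, 0.0)])
        coef, *_ = np.linalg.lstsq(X, ys, rcond=None)
        rss = float(np.sum((ys - X @ coef) ** 2))
        if best is None or rss < best[0] - 1e-12 * max(best[0], 1.0):
            best = (rss, c, coef)
    rss, c, coef = best
    return SegmentedFit(
        breakpoint_x=float(c),
        slope_1=float(coef[1]),
        slope_2=float(coef[1] + coef[2]),
        intercept_1=float(coef[0]),
        rss=rss,
        linear_rss=linear_rss,
        n=len(xs),
    )


def biphasic_test(fit: SegmentedFit, n: int | None = None) -> tuple[float, float]:
    """F-test of the segmented model (4 params) against a single line (2).

    Returns (F, p).  With a perfect segmented fit (rss == 0 but a worse
    line) F is infinite and p is 0.  Requires n > 5 so the denominator
    degrees of freedom n - 4 exceed 1.
    """
    n = fit.n if n is None else n
    df_extra, df_resid = 2, n - 4
    if n <= 5:
        raise ValueError("biphasic test needs n > 5 points")
    if fit.linear_rss <= 0.0:
        # a single line is already exact; no evidence of a break
        return 0.0, 1.0
    if fit.rss <= 1e-10 * fit.linear_rss:
        # segmented fit exact to roundoff: F degenerates
        return float("inf"), 0.0
    f_stat = ((fit.linear_rss - fit.rss) / df_extra) / (fit.rss / df_resid)
    f_stat = max(f_stat, 0.0)
    p = float(stats.f.sf(f_stat, df_extra, df_resid))
    return float(f_stat), p
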