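"""Uniaxial tensile analysis of cuticular-membrane strips.

A hydrated CM strip (clamping distance l0 = 10 mm, width 5 mm) is pulled
at constant rate while force (N) is recorded against uniaxial strain
(percent of l0).  From each curve we extract:

stiffness S : the maximum slope of the force-vs-strain diagram, estimated
    as the largest within-window least-squares slope over a sliding window
    (default 10% of the samples, minimum 3) — robust to single-point noise
    while honoring the "maximum slope" definition.
F_max, eps_max : force and strain at failure, taken at the global force
    maximum; the post-peak force drop defines fracture and those samples
    are ignored for stiffness.

Whether fracture occurred at a lenticel is a per-strip annotation; the
failure-frequency statistic is the fraction of annotated strips flagged.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "TensileCurve",
    "TensileSummary",
    "analyze_curve",
    "lenticel_failure_frequency",
]

MIN_SAMPLES = 10


@dataclass(frozen=True)
class TensileCurve:
    strip_id: str
    cultivar: str
    dafb: float
    strain_pct: np.ndarray  # ascending, >= 0
    force_n: np.ndarray
    l0_mm: float = 10.0
    width_mm: float = 5.0
    failed_at_lenticel: bool | None = None  # None = not annotated

    def __post_init__(self):
        s = np.asarray(self.strain_pct, dtype=float)
        f = np.asarray(self.force_n, dtype=float)
        object.__setattr__(self, "strain_pct", s)
        object.__setattr__(self, "force_n", f)
        if s.shape != f.shape or s.ndim != 1:
            raise ValueError("strain and force must be 1-D and the same length")
        if len(s) < MIN_SAMPLES:
            raise ValueError(f"need >= {MIN_SAMPLES} samples, got {len(s)}")
        if np.any(s < 0) or np.any(np.diff(s) <= 0):
            raise ValueError("strain must be non-negative and strictly ascending")
        if np.any(f < 0):
            raise ValueError("forces must be >= 0")


@dataclass(frozen=True)
class TensileSummary:
    strip_id: str
    cultivar: str
    dafb: float
    stiffness_n_per_pct: float
    f_max_n: float
    eps_max_pct: float
    window_samples: int
    failed_at_lenticel: bool | None = None


def analyze_curve(curve: TensileCurve, window_frac: float = 0.1) -> TensileSummary:
    """Extract stiffness, fracture force and fracture strain from one curve."""
    if not 0.0 < window_frac <= 0.5:
        raise ValueError("window_frac must be in (0, 0.5]")
    s, f = curve.strain_pct, curve.force_n
    i_peak = int(np.argmax(f))
    if i_peak == 0:
        raise ValueError("force is maximal at the first sample (monotone-decreasing curve)")
    f_max = float(f[i_peak])
    eps_max = float(s[i_peak])
    # stiffness from the rising portion only
    s_r, f_r = s[: i_peak + 1], f[: i_peak + 1]
    n = len(s_r)
    w = max(3, int(round(window_frac * n)))
    w = min(w, n)
    best = _max_window_slope(s_r, f_r, w)
    return TensileSummary(
        strip_id=curve.strip_id,
        cultivar=curve.cultivar,
        dafb=curve.dafb,
        stiffness_n_per_pct=float(best),
        f_max_n=f_max,
        eps_max_pct=eps_max,
        window_samples=w,
        failed_at_lenticel=curve.failed_at_lenticel,
    )


def _max_window_slope(x: np.ndarray, y: np.ndarray, w: int) -> float:
    """Largest least-squares slope over all length-w sliding windows."""
    xw = np.lib.stride_tricks.sliding_window_view(x, w)
    yw = np.lib.stride_tricks.sliding_window_view(y, w)
    xm = xw - xw.mean(axis=1, keepdims=True)
    ym = yw - yw.mean(axis=1, keepdims=True)
    denom = np.einsum("ij,ij->i", xm, xm)
    num = np.einsum("ij,ij->i", xm, ym)
    slopes = np.where(denom > 0, num / np.where(denom > 0, denom, 1.0), -np.inf)
    return float(np.max(slopes))


def lenticel_failure_frequency(summaries: list[TensileSummary]) -> float | None:
    """Fraction of annotated strips whose fracture involved a lenticel.

    Strips without annotation are excluded from the denominator; returns
    None (missing) when no strip is annotated.
    """
    annotated = [s for s in summaries if s.failed_at_lenticel is not None]
    if not annotated:
        return None
    return sum(1 for s in annotated if s.failed_at_lenticel) / len(annotated)
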