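"""Stress/strain relaxation analysis of the fruit cuticle.

During growth the cuticular membrane (CM) is held under elastic strain by
the expanding fruit surface.  Releasing that stress stepwise — excising a
skin disc, enzymatically isolating the CM, then extracting the waxes —
lets the membrane relax in measurable steps.  Comparing the disc area
before excision (A_i), the isolated CM disc area (A_CM) and the dewaxed
CM area (A_DCM) partitions the strain:

Apparent strains (percent, relative to the fully relaxed dewaxed disc at
the same sampling time):

    eps'_exc+iso = (A_i  - A_CM ) / A_DCM * 100
    eps'_extr    = (A_CM - A_DCM) / A_DCM * 100

Cumulative strains (dimensionless, relative to the reference surface area
A0 at bloom, with disc ratios scaled to the whole fruit):

    eps_total   = (A_total - A0)        / A0
    eps_exc+iso = (A_total - A_CM_fruit)/ A0      (elastic)
    eps_extr    = (A_CM_fruit - A_DCM_fruit)/A0   (wax-fixed, plastic in vivo)
    eps_resid   = (A_DCM_fruit - A0)    / A0      (fixed in the cutin matrix)

By construction eps_total = eps_exc+iso + eps_extr + eps_resid exactly,
and eps_plastic = eps_extr + eps_resid.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .growth import SigmoidFit

__all__ = [
    "DiscStrainRecord",
    "ApparentStrains",
    "CumulativeStrainSet",
    "apparent_strains",
    "whole_fruit_cm_areas",
    "cumulative_strains",
    "strain_time_course",
    "DEFAULT_A0_CM2",
]

#: Reference surface area at bloom (cm^2); the conventional choice for the
#: carpel at initiation, configurable everywhere it is used.
DEFAULT_A0_CM2 = 1.0


class StrainInputWarning(UserWarning):
    """Measurement-noise violations of the expected area ordering."""


@dataclass(frozen=True)
class DiscStrainRecord:
    """The area triplet for one skin disc at one sampling time.

    Areas are in mm^2; ``a_i_mm2`` is the disc area before excision
    (punch cross-section, curvature-corrected), ``a_cm_mm2`` the isolated
    CM disc, ``a_dcm_mm2`` the dewaxed CM.  Typically
    A_i >= A_CM >= A_DCM; violations (negative strain release, possible
    with measurement noise) are kept and flagged with a warning rather
    than rejected, since silently dropping them would bias means.
    """

    cultivar: str
    dafb: float
    a_i_mm2: float
    a_cm_mm2: float
    a_dcm_mm2: float

    def __post_init__(self):
        for name in ("a_i_mm2", "a_cm_mm2", "a_dcm_mm2"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if not (self.a_i_mm2 >= self.a_cm_mm2 >= self.a_dcm_mm2):
            warnings.warn(
                f"disc at {self.dafb} DAFB violates A_i >= A_CM >= A_DCM "
                f"({self.a_i_mm2:.3g}, {self.a_cm_mm2:.3g}, {self.a_dcm_mm2:.3g}); "
                "kept (will yield negative strain release)",
                StrainInputWarning,
                stacklevel=3,
            )


@dataclass(frozen=True)
class ApparentStrains:
    eps_exc_iso_pct: float
    eps_extr_pct: float

    @property
    def eps_total_pct(self) -> float:
        return self.eps_exc_iso_pct + self.eps_extr_pct


@dataclass(frozen=True)
class CumulativeStrainSet:
    """Whole-fruit cumulative strain partition at one sampling time."""

    cultivar: str
    dafb: float
    a0_cm2: float
    a_total_cm2: float
    a_cm_fruit_cm2: float
    a_dcm_fruit_cm2: float
    eps_total: float
    eps_exc_iso: float
    eps_extr: float
    eps_resid: float

    @property
    def eps_plastic(self) -> float:
        return self.eps_extr + self.eps_resid


def apparent_strains(rec: DiscStrainRecord) -> ApparentStrains:
    """Percent strain released on excision+isolation and on wax extraction."""
    d = rec.a_dcm_mm2
    return ApparentStrains(
        eps_exc_iso_pct=(rec.a_i_mm2 - rec.a_cm_mm2) / d * 100.0,
        eps_extr_pct=(rec.a_cm_mm2 - rec.a_dcm_mm2) / d * 100.0,
    )


def whole_fruit_cm_areas(
    rec: DiscStrainRecord, a_total_cm2: float
) -> tuple[float, float]:
    """Scale disc-level CM and DCM areas to the whole fruit (cm^2).

    Assumes strain release is uniform over the fruit surface, so the
    disc ratios A_CM/A_i and A_DCM/A_i apply to the whole surface area.
    """
    if a_total_cm2 <= 0:
        raise ValueError("a_total_cm2 must be > 0")
    return (
        a_total_cm2 * rec.a_cm_mm2 / rec.a_i_mm2,
        a_total_cm2 * rec.a_dcm_mm2 / rec.a_i_mm2,
    )


def cumulative_strains(
    rec: DiscStrainRecord, a_total_cm2: float, a0_cm2: float = DEFAULT_A0_CM2
) -> CumulativeStrainSet:
    """Partition the whole-fruit cumulative strain at one sampling time.

    The four components are all referenced to the same base area ``a0_cm2``,
    so the conservation identity eps_total = eps_exc+iso + eps_extr +
    eps_resid holds exactly (floating-point roundoff only).
    """
    if a0_cm2 <= 0:
        raise ValueError("a0_cm2 must be > 0")
    a_cm, a_dcm = whole_fruit_cm_areas(rec, a_total_cm2)
    return CumulativeStrainSet(
        cultivar=rec.cultivar,
        dafb=rec.dafb,
        a0_cm2=a0_cm2,
        a_total_cm2=a_total_cm2,
        a_cm_fruit_cm2=a_cm,
        a_dcm_fruit_cm2=a_dcm,
        eps_total=(a_total_cm2 - a0_cm2) / a0_cm2,
        eps_exc_iso=(a_total_cm2 - a_cm) / a0_cm2,
        eps_extr=(a_cm - a_dcm) / a0_cm2,
        eps_resid=(a_dcm - a0_cm2) / a0_cm2,
    )


_COMPONENTS = ("eps_total", "eps_exc_iso", "eps_extr", "eps_resid", "eps_plastic")


def strain_time_course(
    records: list[DiscStrainRecord],
    growth_fit: SigmoidFit,
    a0_cm2: float = DEFAULT_A0_CM2,
    fitted_times: np.ndarray | None = None,
) -> pd.DataFrame:
    """Mean +/- SE of each cumulative strain component per sampling time.

    The fitted growth model supplies the whole-fruit surface area at each
    DAFB.  Times outside the range the growth model was fitted on are
    extrapolations of the sigmoid; they are flagged in the ``extrapolated``
    column and a warning is emitted.

    Returns a DataFrame indexed by DAFB with ``<comp>_mean`` / ``<comp>_se``
    columns, ``n`` discs per time, a monotonicity diagnostic on the mean
    eps_total, and the extrapolation flag.  SE is NaN for n = 1.
    """
    if len({r.dafb for r in records}) < 2:
        raise ValueError("need records at >= 2 sampling times")
    rows = []
    for rec in records:
        a_total = float(growth_fit.predict(rec.dafb))
        cs = cumulative_strains(rec, a_total, a0_cm2)
        rows.append(
            {
                "dafb": rec.dafb,
                "eps_total": cs.eps_total,
                "eps_exc_iso": cs.eps_exc_iso,
                "eps_extr": cs.eps_extr,
                "eps_resid": cs.eps_resid,
                "eps_plastic": cs.eps_plastic,
            }
        )
    df = pd.DataFrame(rows)
    grouped = df.groupby("dafb")
    out = pd.DataFrame(index=grouped.size().index)
    out["n"] = grouped.size()
    for comp in _COMPONENTS:
        out[f"{comp}_mean"] = grouped[comp].mean()
        out[f"{comp}_se"] = grouped[comp].sem(ddof=1)  # NaN when n == 1
    out["eps_total_monotone"] = out["eps_total_mean"].is_monotonic_increasing
    if fitted_times is not None:
        out = flag_extrapolation(out, np.asarray(fitted_times, dtype=float))
    return out


def flag_extrapolation(
    table: pd.DataFrame, fitted_times: np.ndarray
) -> pd.DataFrame:
    """Mark time points outside the range the growth model was fitted on."""
    lo, hi = float(np.min(fitted_times)), float(np.max(fitted_times))
    table = table.copy()
    table["extrapolated"] = (table.index < lo) | (table.index > hi)
    if table["extrapolated"].any():
        warnings.warn(
            "some strain time points lie outside the fitted growth range; "
            "surface areas there are sigmoid extrapolations",
            UserWarning,
            stacklevel=2,
        )
    return table
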