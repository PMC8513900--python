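"""Lenticel and cell morphometrics.

Lenticels are pore-like discontinuities of the fruit skin and the usual
initiation sites of cuticular microcracks.  Their density (count per mm^2
of epidermal segment), per-lenticel area trend over development, and the
shape descriptors of epidermal/hypodermal cells (anticlinal aspect ratio,
periclinal area) are simple but load-bearing statistics for comparing a
russet-susceptible with a non-susceptible cultivar.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "LenticelCount",
    "CellMeasure",
    "lenticel_density",
    "marginal_means",
    "cell_descriptors",
    "lenticel_area_trend",
    "REGIONS",
]

REGIONS = ("apex", "cheek", "stem_end", "back", "nak")
LAYERS = ("epidermis", "hypodermis")


@dataclass(frozen=True)
class LenticelCount:
    cultivar: str
    dafb: float
    region: str
    count: int
    disc_area_mm2: float

    def __post_init__(self):
        if self.region not in REGIONS:
            raise ValueError(f"region must be one of {REGIONS}, got {self.region!r}")
        if self.count < 0:
            raise ValueError("count must be >= 0")
        if self.disc_area_mm2 <= 0:
            raise ValueError("disc_area_mm2 must be > 0")


@dataclass(frozen=True)
class CellMeasure:
    layer: str
    anticlinal_diam_um: float
    periclinal_diam_um: float
    depth_um: float | None = None  # 30/50/70 for hypodermis

    def __post_init__(self):
        if self.layer not in LAYERS:
            raise ValueError(f"layer must be one of {LAYERS}")
        if self.anticlinal_diam_um <= 0 or self.periclinal_diam_um <= 0:
            raise ValueError("cell diameters must be > 0")


def lenticel_density(rec: LenticelCount) -> float:
    """Lenticels per mm^2 of epidermal-segment area."""
    return rec.count / rec.disc_area_mm2


def cell_descriptors(m: CellMeasure) -> tuple[float, float]:
    """(anticlinal aspect ratio, periclinal area um^2).

    Aspect ratio > 1 is 'portrait' (radially elongated), 1 'square',
    < 1 'landscape'.  Cells are isodiametric in the tangential plane, so
    the periclinal area is the square of the periclinal diameter.
    """
    aspect = m.anticlinal_diam_um / m.periclinal_diam_um
    area = m.periclinal_diam_um**2
    return aspect, area


def marginal_means(
    table: pd.DataFrame,
    value: str = "density",
    weighted: bool = False,
) -> dict[str, pd.DataFrame | float]:
    """Marginal means of a cultivar x dafb x region table of densities.

    Expects columns ``cultivar``, ``dafb``, ``region`` and the value
    column.  Replicates within a cell are first averaged into cell means;
    margins are then unweighted means of cell means (each region counts
    equally), which reproduces a published report table's margin rows.
    ``weighted=True`` instead pools replicates across the margin.

    Returns a dict with:

    - ``cell_means``: cultivar x dafb x region cell means
    - ``cultivar_time_means``: per cultivar x dafb mean (+/- SE) over regions
    - ``cultivar_means``: per cultivar grand mean over all cells
    - ``region_means``: per region mean over cultivars and times
    - ``grand_mean``: overall mean
    """
    required = {"cultivar", "dafb", "region", value}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"table is missing columns: {sorted(missing)}")
    if table.empty:
        raise ValueError("empty table")

    if weighted:
        units = table[["cultivar", "dafb", "region", value]].copy()
    else:
        units = (
            table.groupby(["cultivar", "dafb", "region"], as_index=False)[value].mean()
        )
    cells = units.groupby(["cultivar", "dafb", "region"])[value].mean()

    def _mean_se(g):
        vals = g.to_numpy(dtype=float)
        se = np.nan if len(vals) < 2 else float(np.std(vals, ddof=1) / np.sqrt(len(vals)))
        return pd.Series({"mean": float(np.mean(vals)), "se": se, "n": len(vals)})

    by = units.groupby(["cultivar", "dafb"])[value].apply(lambda g: _mean_se(g)).unstack()
    cultivar_means = units.groupby("cultivar")[value].apply(lambda g: _mean_se(g)).unstack()
    region_means = units.groupby("region")[value].apply(lambda g: _mean_se(g)).unstack()
    grand = _mean_se(units[value])

    return {
        "cell_means": cells,
        "cultivar_time_means": by,
        "cultivar_means": cultivar_means,
        "region_means": region_means,
        "grand_mean": float(grand["mean"]),
    }


def lenticel_area_trend(dafb, area_mm2) -> tuple[float, float, float]:
    """OLS line through per-lenticel area vs DAFB.

    Returns (slope mm^2/day, intercept mm^2, r_squared).  Per-lenticel
    area grows roughly linearly through development; the slope is the
    cultivar-level dilation rate of individual lenticels.
    """
    t = np.asarray(dafb, dtype=float)
    a = np.asarray(area_mm2, dtype=float)
    if len(t) < 3:
        raise ValueError("need >= 3 time points")
    if np.ptp(t) == 0:
        raise ValueError("degenerate x: all DAFB equal")
    X = np.column_stack([np.ones_like(t), t])
    coef, *_ = np.linalg.lstsq(X, a, rcond=None)
    resid = a - X @ coef
    ss_res = float(resid @ resid)
    ss_tot = float(np.sum((a - a.mean()) ** 2))
    r2 = 1.0 if ss_tot == 0 else 1.0 - ss_res / ss_tot
    return float(coef[1]), float(coef[0]), r2
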