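"""Small bundled reference tables.

Only tiny plain-value tables live here; all larger inputs are produced by
the synthetic generator (:mod:`skinstrain.synthetic`).
"""

from __future__ import annotations

import pandas as pd

__all__ = ["published_lenticel_densities"]

# Published region-level mean lenticel densities (no. mm^-2) of the
# russet-susceptible 'Apple' and the non-susceptible 'Tommy Atkins' mango,
# at three development stages (DAFB).  Used as reference input for
# marginal-mean reporting.
_LENTICEL_DENSITY_ROWS = [
    # cultivar, dafb, apex, cheek, stem_end, back, nak
    ("Apple", 78, 0.45, 0.18, 0.26, 0.25, 0.14),
    ("Apple", 107, 0.31, 0.08, 0.24, 0.16, 0.09),
    ("Apple", 152, 0.28, 0.04, 0.19, 0.10, 0.09),
    ("Tommy Atkins", 78, 1.05, 0.38, 0.37, 0.62, 0.64),
    ("Tommy Atkins", 107, 0.73, 0.24, 0.23, 0.35, 0.30),
    ("Tommy Atkins", 152, 0.40, 0.15, 0.21, 0.18, 0.18),
]

_REGION_ORDER = ("apex", "cheek", "stem_end", "back", "nak")


def published_lenticel_densities() -> pd.DataFrame:
    """Long-form table: cultivar, dafb, region, density (no. mm^-2)."""
    rows = []
    for cultivar, dafb, *vals in _LENTICEL_DENSITY_ROWS:
        for region, v in zip(_REGION_ORDER, vals):
            rows.append(
                {"cultivar": cultivar, "dafb": dafb, "region": region, "density": v}
            )
    return pd.DataFrame(rows)
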