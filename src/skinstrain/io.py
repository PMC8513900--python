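"""CSV schemas and validated readers.

All inputs are UTF-8 CSVs with a mandatory header row and decimal points.
Schema violations raise :class:`SchemaError` with the file, column and
(1-based data) row so a user can fix the offending cell directly.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

__all__ = ["SCHEMAS", "SchemaError", "read_table"]

#: required columns per input table; numeric columns are validated as such
SCHEMAS: dict[str, dict] = {
    "fruit_dimensions": {
        "columns": ["cultivar", "fruit_id", "dafb", "length_mm", "diam1_mm", "diam2_mm", "mass_g"],
        "numeric": ["dafb", "length_mm", "diam1_mm", "diam2_mm", "mass_g"],
    },
    "growth": {
        "columns": ["cultivar", "fruit_id", "region", "dafb", "area_cm2"],
        "numeric": ["dafb", "area_cm2"],
    },
    "disc_areas": {
        "columns": ["cultivar", "fruit_id", "dafb", "a_i_mm2", "a_cm_mm2", "a_dcm_mm2"],
        "numeric": ["dafb", "a_i_mm2", "a_cm_mm2", "a_dcm_mm2"],
    },
    "cuticle_mass": {
        "columns": ["cultivar", "fruit_id", "dafb", "cm_ug", "dcm_ug", "disc_area_mm2"],
        "numeric": ["dafb", "cm_ug", "dcm_ug", "disc_area_mm2"],
    },
    "tensile_curves": {
        "columns": ["strip_id", "cultivar", "dafb", "strain_pct", "force_n"],
        "numeric": ["dafb", "strain_pct", "force_n"],
    },
    "tensile_annotations": {
        "columns": ["strip_id", "failed_at_lenticel"],
        "numeric": ["failed_at_lenticel"],
    },
    "lenticel_counts": {
        "columns": ["cultivar", "dafb", "region", "count", "disc_area_mm2"],
        "numeric": ["dafb", "count", "disc_area_mm2"],
    },
    "lenticel_areas": {
        "columns": ["cultivar", "dafb", "lenticel_id", "area_mm2"],
        "numeric": ["dafb", "area_mm2"],
    },
    "cell_measures": {
        "columns": ["cultivar", "dafb", "layer", "depth_um", "anticlinal_diam_um", "periclinal_diam_um"],
        "numeric": ["dafb", "anticlinal_diam_um", "periclinal_diam_um"],
        "nullable": ["depth_um"],
    },
}


class SchemaError(ValueError):
    """A CSV does not match its declared schema."""

    def __init__(self, file: str, column: str, row: int | None, message: str):
        self.file, self.column, self.row = file, column, row
        where = f"{file}, column {column!r}" + (f", row {row}" if row is not None else "")
        super().__init__(f"{where}: {message}")


def read_table(path: str | Path, schema: str) -> pd.DataFrame:
    """Read and validate one input CSV against a named schema."""
    if schema not in SCHEMAS:
        raise ValueError(f"unknown schema {schema!r}; known: {sorted(SCHEMAS)}")
    path = Path(path)
    spec = SCHEMAS[schema]
    df = pd.read_csv(path)
    for col in spec["columns"]:
        if col not in df.columns:
            raise SchemaError(path.name, col, None, "required column is missing")
    nullable = set(spec.get("nullable", ()))
    for col in spec["numeric"]:
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna()
        if bad.any():
            row = int(bad.idxmax()) + 1
            raise SchemaError(path.name, col, row, f"non-numeric value {df[col][bad.idxmax()]!r}")
        if col not in nullable and coerced.isna().any():
            row = int(coerced.isna().idxmax()) + 1
            raise SchemaError(path.name, col, row, "missing value in non-nullable column")
        df[col] = coerced
    return df
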