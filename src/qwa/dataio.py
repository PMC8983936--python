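"""Read and write the tabular formats used throughout the pipeline.

Three input dialects (all comma-separated, UTF-8, period decimal separator):

* vessels — ``site_id,tree_id,year,vessel_id,lumen_area_um2,rel_position[,group_id]``
  one row per measured vessel (lumen area in μm², relative radial position in
  [0, 1] with 0 at the ring's inner border, i.e. the earliest-formed wood);
* rings — ``site_id,tree_id,year,trw_um,xylem_area_um2`` one row per dated
  ring (ring width and analyzed xylem area);
* climate — ``year,month,tmean_c,prec_mm`` a complete monthly grid of mean
  temperature and precipitation sum.

Validation is strict: missing columns, non-numeric or out-of-range values,
duplicate keys and gaps in the climate grid all raise
:class:`~qwa.exceptions.ValidationError` naming the offending row.
"""

from __future__ import annotations

import pandas as pd

from .exceptions import ValidationError

VESSEL_COLUMNS = ["site_id", "tree_id", "year", "vessel_id", "lumen_area_um2", "rel_position"]
RING_COLUMNS = ["site_id", "tree_id", "year", "trw_um", "xylem_area_um2"]
CLIMATE_COLUMNS = ["year", "month", "tmean_c", "prec_mm"]


def _require_columns(df: pd.DataFrame, required: list[str], what: str) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValidationError(f"{what} table is missing column(s): {', '.join(missing)}")


def _numeric(df: pd.DataFrame, col: str, what: str) -> pd.Series:
    out = pd.to_numeric(df[col], errors="coerce")
    bad = out.isna() & df[col].notna()
    if bad.any():
        row = int(bad.idxmax()) + 1
        raise ValidationError(f"{what}: non-numeric value {df[col][bad.idxmax()]!r} in column {col!r}", row=row)
    if out.isna().any():
        row = int(out.isna().idxmax()) + 1
        raise ValidationError(f"{what}: missing value in column {col!r}", row=row)
    return out


def _check_duplicates(df: pd.DataFrame, keys: list[str], what: str) -> None:
    dup = df.duplicated(subset=keys)
    if dup.any():
        row = int(dup.idxmax()) + 1
        key = tuple(df.loc[dup.idxmax(), keys])
        raise ValidationError(f"{what}: duplicate key {key}", row=row)


def validate_vessels(df: pd.DataFrame) -> pd.DataFrame:
    """Validate a vessel table; returns a typed copy."""
    df = df.reset_index(drop=True).copy()
    _require_columns(df, VESSEL_COLUMNS, "vessel")
    df["year"] = _numeric(df, "year", "vessel").astype(int)
    df["lumen_area_um2"] = _numeric(df, "lumen_area_um2", "vessel")
    df["rel_position"] = _numeric(df, "rel_position", "vessel")
    bad = df["lumen_area_um2"] <= 0
    if bad.any():
        raise ValidationError("vessel: lumen_area_um2 must be > 0", row=int(bad.idxmax()) + 1)
    bad = (df["rel_position"] < 0) | (df["rel_position"] > 1)
    if bad.any():
        raise ValidationError("vessel: rel_position outside [0, 1]", row=int(bad.idxmax()) + 1)
    _check_duplicates(df, ["site_id", "tree_id", "year", "vessel_id"], "vessel")
    if "group_id" not in df.columns:
        df["group_id"] = pd.NA
    return df


def validate_rings(df: pd.DataFrame) -> pd.DataFrame:
    """Validate a ring table; returns a typed copy."""
    df = df.reset_index(drop=True).copy()
    _require_columns(df, RING_COLUMNS, "ring")
    df["year"] = _numeric(df, "year", "ring").astype(int)
    df["trw_um"] = _numeric(df, "trw_um", "ring")
    df["xylem_area_um2"] = _numeric(df, "xylem_area_um2", "ring")
    for col in ("trw_um", "xylem_area_um2"):
        bad = df[col] <= 0
        if bad.any():
            raise ValidationError(f"ring: {col} must be > 0", row=int(bad.idxmax()) + 1)
    _check_duplicates(df, ["site_id", "tree_id", "year"], "ring")
    return df


def validate_climate(df: pd.DataFrame) -> pd.DataFrame:
    """Validate a monthly climate table: complete grid, prec ≥ 0."""
    df = df.reset_index(drop=True).copy()
    _require_columns(df, CLIMATE_COLUMNS, "climate")
    df["year"] = _numeric(df, "year", "climate").astype(int)
    df["month"] = _numeric(df, "month", "climate").astype(int)
    df["tmean_c"] = _numeric(df, "tmean_c", "climate")
    df["prec_mm"] = _numeric(df, "prec_mm", "climate")
    bad = (df["month"] < 1) | (df["month"] > 12)
    if bad.any():
        raise ValidationError("climate: month outside 1..12", row=int(bad.idxmax()) + 1)
    bad = df["prec_mm"] < 0
    if bad.any():
        raise ValidationError("climate: prec_mm must be >= 0", row=int(bad.idxmax()) + 1)
    _check_duplicates(df, ["year", "month"], "climate")
    # complete monthly grid over the observed span
    have = set(zip(df["year"], df["month"]))
    missing = [
        f"{y}-{m:02d}"
        for y in range(int(df["year"].min()), int(df["year"].max()) + 1)
        for m in range(1, 13)
        if (y, m) not in have
    ]
    if missing:
        raise ValidationError(f"climate: monthly grid has gaps: {', '.join(missing[:12])}")
    return df.sort_values(["year", "month"]).reset_index(drop=True)


def read_table(path) -> pd.DataFrame:
    """Read any package CSV with exact (round-trip) float parsing."""
    return pd.read_csv(path, float_precision="round_trip")


def read_vessels(path) -> pd.DataFrame:
    return validate_vessels(read_table(path))


def read_rings(path) -> pd.DataFrame:
    return validate_rings(read_table(path))


def read_climate(path) -> pd.DataFrame:
    return validate_climate(read_table(path))


def write_table(df: pd.DataFrame, path) -> None:
    """Write any tidy result table as CSV with full float precision.

    Floats are written with 17 significant digits, which round-trips IEEE
    doubles exactly, so write→read is an identity on all numeric fields.
    """
    df.to_csv(path, index=False, float_format="%.17g")
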