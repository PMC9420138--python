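"""Input/output schemas for raw, flagged and harmonized tables.

Three tabular schemas flow through the pipeline, all held as pandas
DataFrames and interchanged as UTF-8, comma-delimited, RFC-4180 CSV:

* **raw** — one row per result as exported from a Water Quality Portal style
  download, with sample-level metadata (organization, site, coordinates,
  date/time, medium, activity type) and result-level metadata (nutrient name,
  concentration + units, detection code/limit, analytical method, fraction).
* **flagged** — every raw row augmented with per-step keep/drop/NA flags and
  audit counts; flagging never deletes rows.
* **harmonized** — the final dataset: one row per (site, date,
  nutrient_parameter) with concentration in mg/L as N or as P.

Absent data values serialize as empty strings; flag columns use the literal
string ``NA`` where a flag was not evaluated because the row was already
dropped at an earlier step — the two are semantically distinct.
"""

from __future__ import annotations

import warnings
from pathlib import Path
from typing import Union

import numpy as np
import pandas as pd

__all__ = [
    "SchemaError",
    "RAW_COLUMNS",
    "SNAPD_COLUMNS",
    "FLAGGED_COLUMNS",
    "read_raw_table",
    "write_raw_table",
    "write_outputs",
    "validate_harmonized",
    "validate_flagged",
]


class SchemaError(ValueError):
    """Raised when a table does not satisfy its schema or invariants."""


#: Raw input columns. ``record_id`` is assigned at read time in file order.
RAW_COLUMNS: list[str] = [
    "org_name_raw",
    "st_abbr",
    "st_name",
    "orig_MLI",
    "orig_x",
    "orig_y",
    "date",
    "time",
    "media",
    "activity_type",
    "result_type",
    "nutrient_handle",
    "analytical_method",
    "sample_fraction_raw",
    "orig_conc",
    "orig_conc_units",
    "DL_code",
    "DL_text",
    "orig_DL_val",
    "orig_DL_units",
    "provider",
]

_MANDATORY_RAW = ("orig_MLI", "nutrient_handle")
_NUMERIC_RAW = ("orig_x", "orig_y", "orig_DL_val")

#: Final harmonized dataset column order.
SNAPD_COLUMNS: list[str] = [
    "media",
    "st_abbr",
    "st_name",
    "org_name",
    "N_or_P",
    "nutrient_name",
    "sample_fraction",
    "nutrient_parameter",
    "year",
    "date",
    "MLI",
    "conc",
    "conc_units",
    "outlier_flag",
    "num_obs_per_date",
    "impute_flag",
    "DL",
    "DL_units",
    "x",
    "y",
]

#: Flagged audit dataset column order (every raw row, never deleted).
#: ``record_id`` is appended as internal plumbing for traceability.
FLAGGED_COLUMNS: list[str] = [
    "st_abbr",
    "st_name",
    "org_name",
    "N_or_P",
    "nutrient_parameter",
    "nutrient_handle",
    "new_MLI",
    "new_x",
    "new_y",
    "year",
    "date",
    "time",
    "chem_form_flag",
    "new_conc",
    "new_conc_units",
    "new_DL",
    "new_DL_units",
    "ND_flag",
    "impute_flag",
    "sample_fraction",
    "sample_fraction_flag",
    "result_type",
    "result_type_flag",
    "media",
    "media_flag",
    "activity_type",
    "activity_type_flag",
    "filt2unfilt_flag",
    "analytical_method",
    "provider",
    "orig_conc",
    "orig_conc_units",
    "conc_flag",
    "conc_unit_flag",
    "orig_DL_val",
    "orig_DL_units",
    "DL_code",
    "DL_text",
    "orig_MLI",
    "dup_MLI_flag",
    "num_MLIs_at_loc",
    "orig_x",
    "orig_y",
    "num_coords_at_loc",
    "dup_coords_flag",
    "combine_coords_flag",
    "pct1",
    "pct99",
    "outlier_flag",
    "num_obs_per_date",
    "num_orgs_per_obs",
    "num_nds_per_obs",
    "num_conc_per_time",
    "pct_ND",
    "date_flag",
    "record_id",
]

#: Columns whose absent value is written as the literal flag string "NA".
FLAG_VALUE_COLUMNS: frozenset[str] = frozenset(
    {
        "chem_form_flag",
        "ND_flag",
        "impute_flag",
        "sample_fraction_flag",
        "result_type_flag",
        "media_flag",
        "activity_type_flag",
        "filt2unfilt_flag",
        "conc_flag",
        "conc_unit_flag",
        "date_flag",
        "dup_MLI_flag",
        "dup_coords_flag",
        "combine_coords_flag",
        "outlier_flag",
    }
)


def read_raw_table(path: Union[str, Path]) -> pd.DataFrame:
    """Read a raw WQP-style CSV into the raw schema.

    ``record_id`` is assigned 0..n-1 in file order; empty strings become
    missing values; unknown columns are dropped with a warning; missing
    optional columns are created as all-missing.  Missing mandatory columns
    (``orig_MLI``, ``nutrient_handle``) raise :class:`SchemaError`.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in _MANDATORY_RAW if c not in df.columns]
    if missing:
        raise SchemaError(f"raw table is missing mandatory column(s): {missing}")
    unknown = [c for c in df.columns if c not in RAW_COLUMNS]
    if unknown:
        warnings.warn(f"ignoring unknown raw columns: {unknown}", stacklevel=2)
        df = df.drop(columns=unknown)
    for col in RAW_COLUMNS:
        if col not in df.columns:
            df[col] = ""
    df = df[RAW_COLUMNS]
    df = df.where(df != "", np.nan)
    for col in _NUMERIC_RAW:
        try:
            df[col] = pd.to_numeric(df[col])
        except (ValueError, TypeError) as exc:
            raise SchemaError(f"column {col!r} must be numeric where present: {exc}") from exc
    bad = df[["orig_x", "orig_y"]].apply(lambda s: np.isinf(s.astype(float)))
    if bad.to_numpy().any():
        raise SchemaError("orig_x/orig_y must be finite where present")
    df.insert(0, "record_id", np.arange(len(df), dtype=np.int64))
    return df


def _format_frame(df: pd.DataFrame, float_cols: set[str]) -> pd.DataFrame:
    out = df.copy()
    for col in out.columns:
        s = out[col]
        if col in FLAG_VALUE_COLUMNS:
            out[col] = s.astype(object).where(s.notna(), "NA")
        elif pd.api.types.is_datetime64_any_dtype(s):
            out[col] = s.dt.strftime("%Y-%m-%d").astype(object).where(s.notna(), "")
        elif pd.api.types.is_float_dtype(s) and col not in float_cols:
            # integer-valued counts stored as float because of missing values
            out[col] = s.map(lambda v: "" if pd.isna(v) else str(int(v)))
        else:
            out[col] = s.astype(object).where(s.notna(), "")
    return out


def write_raw_table(df: pd.DataFrame, path: Union[str, Path]) -> None:
    """Write a raw-schema frame (without ``record_id``) back to CSV."""
    out = df.drop(columns=["record_id"], errors="ignore")
    out = out[RAW_COLUMNS].copy()
    out = out.astype(object).where(out.notna(), "")
    out.to_csv(path, index=False)


def validate_harmonized(df: pd.DataFrame) -> None:
    """Check harmonized-table invariants; raise SchemaError naming the first offender."""
    dup = df.duplicated(subset=["MLI", "date", "nutrient_parameter"])
    if dup.any():
        row = df.index[dup][0]
        raise SchemaError(f"duplicate (MLI, date, nutrient_parameter) at row {row}")
    conc = pd.to_numeric(df["conc"], errors="coerce")
    neg = conc < 0
    if neg.any():
        raise SchemaError(f"negative concentration at row {df.index[neg][0]}")
    dl_no_imp = df["DL"].notna() & (df["impute_flag"] != "imputed")
    if dl_no_imp.any():
        raise SchemaError(
            f"DL present on non-imputed row {df.index[dl_no_imp][0]}"
        )
    # outlier_flag must be NA exactly when conc is absent
    flag = df["outlier_flag"].astype(object)
    mism = (flag.isna() | (flag == "NA")) != conc.isna()
    if mism.any():
        raise SchemaError(
            f"outlier_flag NA must coincide with missing conc (row {df.index[mism][0]})"
        )


def validate_flagged(df: pd.DataFrame) -> None:
    """Check flagged-table invariants."""
    if df["record_id"].duplicated().any():
        raise SchemaError("record_id must be unique in flagged output")


def write_outputs(
    harmonized: pd.DataFrame, flagged: pd.DataFrame, out_dir: Union[str, Path]
) -> tuple[Path, Path]:
    """Write ``snapd.csv`` and ``flagged.csv`` with exact column vocabularies.

    Dates serialize as YYYY-MM-DD, absent values as empty strings, and
    unevaluated flags as the literal string ``NA``.  Both tables are
    validated first; an invariant violation refuses the write.
    """
    validate_harmonized(harmonized)
    validate_flagged(flagged)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    h = harmonized[SNAPD_COLUMNS]
    f = flagged[FLAGGED_COLUMNS]
    h = _format_frame(h, float_cols={"conc", "DL", "x", "y"})
    f = _format_frame(
        f,
        float_cols={
            "new_conc", "new_DL", "orig_DL_val", "new_x", "new_y",
            "orig_x", "orig_y", "pct1", "pct99", "pct_ND",
        },
    )
    snapd_path = out_dir / "snapd.csv"
    flagged_path = out_dir / "flagged.csv"
    h.to_csv(snapd_path, index=False)
    f.to_csv(flagged_path, index=False)
    return snapd_path, flagged_path
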