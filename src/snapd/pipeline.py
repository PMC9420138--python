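"""End-to-end harmonization pipeline and run report.

``run_pipeline`` executes the whole harmonization sequence on a raw
WQP-style table — organization standardization, site resolution, the filter
cascade, chemical-form and unit conversion, nutrient renaming, non-detect
identification, detection-limit approximation, Bayesian imputation, outlier
flagging, duplicate resolution, fraction combination and the
filtered-vs-unfiltered consistency drop — and writes the harmonized table,
the flagged audit table, a per-step affected-row log and a harmonization
report.

``harmonize_frames`` is the in-memory core: raw frame in, (harmonized,
flagged, log) out.  All randomness is funnelled through the configuration's
``rng_seed``.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Optional, Union

import numpy as np
import pandas as pd

from . import chemistry, filters, finalize, io, nondetects, sites
from .config import HarmonizationConfig, normalize_text

__all__ = ["harmonize_frames", "run_pipeline", "harmonization_report"]

logger = logging.getLogger("snapd")


def _apply_conversions(df: pd.DataFrame, config: HarmonizationConfig) -> pd.DataFrame:
    """Convert kept records to mg/L on the elemental basis and rename them.

    Fills ``new_conc``, ``new_conc_units``, ``new_DL``, ``new_DL_units``,
    ``nutrient_name``, ``sample_fraction``, ``N_or_P``, ``nutrient_parameter``
    and ``year``.  Unit rescaling happens first, then the molecular-to-
    elemental factor (the order is mathematically immaterial; fixed for
    determinism).  Detection limits follow the same path; a DL whose units
    are missing or unconvertible is treated as not provided.
    """
    out = df.copy()
    for col in ("new_conc", "new_DL"):
        out[col] = np.nan
    for col in ("new_conc_units", "new_DL_units", "nutrient_name", "sample_fraction", "N_or_P", "nutrient_parameter"):
        out[col] = pd.Series(pd.NA, index=out.index, dtype=object)
    out["year"] = out["_date"].dt.year

    live = ~out["_dropped"]
    for idx in out.index[live]:
        row = out.loc[idx]
        spec = chemistry.lookup_nutrient(row["nutrient_handle"], config)
        units = row["orig_conc_units"] if isinstance(row["orig_conc_units"], str) else None
        method = row["analytical_method"] if isinstance(row["analytical_method"], str) else None
        form = chemistry.infer_chemical_form(row["nutrient_handle"], units, method, config)
        fraction = config.fraction_map[normalize_text(row["sample_fraction_raw"])]
        fields = chemistry.harmonize_nutrient_name(spec, fraction)
        for k, v in fields.items():
            out.loc[idx, k] = v
        out.loc[idx, "new_conc_units"] = f"mg/L as {spec.N_or_P}"

        if not pd.isna(row["_conc_val"]) and row["ND_flag"] != "ND":
            in_mgl = chemistry.convert_units(float(row["_conc_val"]), units, config)
            elemental = chemistry.convert_to_elemental(in_mgl, form, config)
            out.loc[idx, "new_conc"] = float(elemental)

        if not pd.isna(row["orig_DL_val"]):
            dl_units = row["orig_DL_units"] if isinstance(row["orig_DL_units"], str) else None
            dl_mgl = chemistry.convert_units(float(row["orig_DL_val"]), dl_units, config)
            if dl_mgl is not chemistry.UNCONVERTIBLE:
                dl_elem = chemistry.convert_to_elemental(dl_mgl, form, config)
                if dl_elem is not chemistry.UNCONVERTIBLE:
                    out.loc[idx, "new_DL"] = float(dl_elem)
                    out.loc[idx, "new_DL_units"] = f"mg/L as {spec.N_or_P}"
    return out


def _propagate_filt2unfilt(flagged: pd.DataFrame, daily_flagged: pd.DataFrame) -> pd.DataFrame:
    """Copy the daily filtered-vs-unfiltered QC verdicts back to raw rows."""
    out = flagged.copy()
    out["filt2unfilt_flag"] = "NA"
    verdicts = daily_flagged.loc[
        daily_flagged["filt2unfilt_flag"] != "NA",
        ["MLI", "x", "y", "date", "nutrient_parameter", "filt2unfilt_flag"],
    ]
    if verdicts.empty:
        return out
    lookup = {
        (r.MLI, r.x, r.y, r.date, r.nutrient_parameter): r.filt2unfilt_flag
        for r in verdicts.itertuples()
    }
    live = ~out["_dropped"]
    for idx in out.index[live]:
        row = out.loc[idx]
        key = (row["new_MLI"], row["new_x"], row["new_y"], row["_date"], row["nutrient_parameter"])
        if key in lookup:
            out.loc[idx, "filt2unfilt_flag"] = lookup[key]
    return out


def harmonize_frames(
    raw: pd.DataFrame, config: Optional[HarmonizationConfig] = None
) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Run the full harmonization on an in-memory raw table.

    Returns ``(harmonized, flagged, log)`` where ``log`` maps step names to
    affected-row counts in the style of the published processing summary.
    """
    config = config or HarmonizationConfig()
    log: dict[str, int] = {"step00_raw": len(raw)}

    df = raw.copy()
    # Step 1 — organization names (standardizes spellings, never drops)
    df["org_name"] = df["org_name_raw"].map(
        lambda v: filters.standardize_org_name(v, config.org_aliases)
    )
    changed = (df["org_name"].fillna("") != df["org_name_raw"].fillna("")).sum()
    log["step01_org_names_standardized"] = int(changed)

    # Step 2 — unique monitoring sites
    df = sites.resolve_sites(df, config)
    log["step02_multiple_coordinates"] = int((df["dup_coords_flag"] == "dup_coords").sum())
    log["step02_multiple_mlis"] = int((df["dup_MLI_flag"] == "dup_MLI").sum())

    # Steps 3-11 — the metadata filter cascade
    df = filters.apply_filter_cascade(df, config)
    log["step03_media_dropped"] = int((df["media_flag"] == "drop").sum())
    log["step04_date_dropped"] = int((df["date_flag"] == "drop").sum())
    log["step05_chem_form_dropped"] = int((df["chem_form_flag"] == "chem_form_unknown").sum())
    log["step06_conc_dropped"] = int((df["conc_flag"] == "drop").sum())
    log["step07_units_dropped"] = int((df["conc_unit_flag"] == "drop").sum())
    log["step08_detection_code_dropped"] = int((df["ND_flag"] == "drop").sum())
    log["step09_fraction_dropped"] = int((df["sample_fraction_flag"] == "drop").sum())
    log["step10_activity_dropped"] = int((df["activity_type_flag"] == "drop").sum())
    log["step11_result_type_dropped"] = int((df["result_type_flag"] == "drop").sum())

    # Steps 12-13 — conversions and nutrient renaming
    df = _apply_conversions(df, config)
    log["step12_converted"] = int((~df["_dropped"]).sum())

    # Step 14 — detection-limit approximation
    df = nondetects.approximate_detection_limits(df, config)
    log["step14_dl_approximated"] = int(df["_dl_approximated"].sum())
    unassignable = (
        ~df["_dropped"] & (df["ND_flag"] == "ND") & df["new_DL"].isna()
    ).sum()
    if unassignable:
        logger.warning(
            "%d non-detect(s) have no assignable detection limit and are "
            "excluded from imputation",
            unassignable,
        )

    # Step 15 — Bayesian multiple imputation of censored values
    df = nondetects.impute_nondetects(df, config)
    imputed_mask = (df["ND_flag"] == "ND") & (df["impute_flag"] == "impute")
    log["step15_imputed"] = int((imputed_mask & df["new_conc"].notna()).sum())
    log["step15_left_na"] = int(
        ((df["ND_flag"] == "ND") & (df["impute_flag"] == "dont_impute")).sum()
    )

    # Step 16 — outlier flagging on pre-averaging values
    df = finalize.flag_outliers(df, config.outlier_lower_pct, config.outlier_upper_pct)
    log["step16_outliers_flagged"] = int((df["outlier_flag"] == "potential_outlier").sum())

    # Step 17 — duplicate resolution to daily records
    df, daily = finalize.resolve_duplicates(df, config)
    log["step17_averaged_rows"] = int(
        (df["num_obs_per_date"] > 1).sum()
    )
    log["step17_cross_org_duplicates"] = int((df["num_orgs_per_obs"] > 1).sum())
    log["step17_mixed_detection_averages"] = int(
        ((df["num_nds_per_obs"] > 1) & (df["num_obs_per_date"] > 1)).sum()
    )

    # Step 18 — combine fractions into total nutrients
    n_before = len(daily)
    daily = finalize.combine_fractions(daily, config)
    log["step18_combined_added"] = len(daily) - n_before

    # Step 19 — filtered vs unfiltered consistency
    daily_flagged, surviving = finalize.qc_filtered_vs_unfiltered(daily)
    log["step19_qc_dropped"] = int(
        (daily_flagged["filt2unfilt_flag"] == "unfilt conc <= filt conc").sum()
    )
    df = _propagate_filt2unfilt(df, daily_flagged)

    harmonized = surviving.reset_index(drop=True)
    flagged = _finalize_flagged(df)
    log["final_harmonized_rows"] = len(harmonized)
    return harmonized, flagged, log


def _finalize_flagged(df: pd.DataFrame) -> pd.DataFrame:
    """Shape the working frame into the flagged output schema."""
    out = df.copy()
    out["date"] = out["_date"]
    helper = [c for c in out.columns if c.startswith("_")]
    return out.drop(columns=helper)


def run_pipeline(
    raw_path: Union[str, Path],
    config: Optional[HarmonizationConfig] = None,
    out_dir: Union[str, Path] = ".",
) -> dict:
    """Read a raw CSV, harmonize it and write all outputs.

    Writes ``snapd.csv``, ``flagged.csv``, ``report.json``, the Sankey-style
    unit-flow table ``report_unit_flows.csv`` and ``run_log.json`` into
    ``out_dir``.  Returns the per-step log.  Any schema or configuration
    error aborts before partial outputs are written.
    """
    config = config or HarmonizationConfig()
    out_dir = Path(out_dir)
    raw = io.read_raw_table(raw_path)
    harmonized, flagged, log = harmonize_frames(raw, config)
    report = harmonization_report(raw, flagged, harmonized, log)

    out_dir.mkdir(parents=True, exist_ok=True)
    io.write_outputs(harmonized, flagged, out_dir)
    report["unit_flows"].to_csv(out_dir / "report_unit_flows.csv", index=False)
    report["org_summaries"].to_csv(out_dir / "report_org_summaries.csv", index=False)
    with open(out_dir / "report.json", "w", encoding="utf-8") as fh:
        json.dump(
            {
                "standardized_pct": report["standardized_pct"],
                "step_counts": report["step_counts"],
            },
            fh,
            indent=2,
        )
    with open(out_dir / "run_log.json", "w", encoding="utf-8") as fh:
        json.dump({"rng_seed": config.rng_seed, **log}, fh, indent=2)
    for step, count in log.items():
        logger.info("%s: %s", step, count)
    return log


def harmonization_report(
    raw: pd.DataFrame,
    flagged: pd.DataFrame,
    harmonized: pd.DataFrame,
    log: Optional[dict] = None,
) -> dict:
    """Summarize the harmonization run.

    Returns a dict with:

    * ``unit_flows`` — raw-unit to harmonized-unit flow tallies per nutrient
      basis (input table for a Sankey diagram),
    * ``org_summaries`` — per-organization pre/post log-concentration mean,
      SD and count for total nitrogen and total phosphorus,
    * ``standardized_pct`` — share of raw observations per basis whose units
      and chemical form could be standardized to mg/L as N or P,
    * ``step_counts`` — per-step affected-row counts.
    """
    basis = flagged["N_or_P"]
    # basis for dropped rows is unfilled; recover it from the raw handle
    # vocabulary-independent fallback: nitrogen if the handle mentions N
    def _basis_fallback(handle) -> str:
        if not isinstance(handle, str):
            return "unknown"
        h = handle.lower()
        return "P" if "phosph" in h else "N"

    basis = basis.where(basis.notna(), flagged["nutrient_handle"].map(_basis_fallback))

    units_norm = flagged["orig_conc_units"].map(
        lambda u: normalize_text(u) if isinstance(u, str) else "(missing)"
    )
    standardized = flagged["new_conc_units"].notna()
    target = np.where(standardized, "mg/L as " + basis.astype(str), "dropped")
    flows = (
        pd.DataFrame({"basis": basis, "raw_unit": units_norm, "target": target})
        .groupby(["basis", "raw_unit", "target"])
        .size()
        .reset_index(name="count")
        .sort_values(["basis", "count"], ascending=[True, False])
        .reset_index(drop=True)
    )

    pct = {}
    for b in ("N", "P"):
        total = int((basis == b).sum())
        pct[b] = 100.0 * int((standardized & (basis == b)).sum()) / total if total else np.nan

    rows = []
    for nutrient in ("total nitrogen", "total phosphorus"):
        pre_mask = flagged["nutrient_name"] == nutrient
        pre_conc = pd.to_numeric(flagged.loc[pre_mask, "orig_conc"], errors="coerce")
        pre = np.log(pre_conc[pre_conc > 0])
        post_mask = harmonized["nutrient_name"] == nutrient
        post = np.log(harmonized.loc[post_mask & (harmonized["conc"] > 0), "conc"])
        for org, grp in flagged.loc[pre_mask].groupby("org_name"):
            vals = pd.to_numeric(grp["orig_conc"], errors="coerce")
            vals = np.log(vals[vals > 0])
            h_grp = harmonized.loc[post_mask & (harmonized["org_name"] == org), "conc"]
            h_vals = np.log(h_grp[h_grp > 0])
            rows.append(
                {
                    "nutrient": nutrient,
                    "org_name": org,
                    "pre_n": int(vals.size),
                    "pre_log_mean": float(vals.mean()) if vals.size else np.nan,
                    "pre_log_sd": float(vals.std(ddof=1)) if vals.size > 1 else np.nan,
                    "post_n": int(h_vals.size),
                    "post_log_mean": float(h_vals.mean()) if h_vals.size else np.nan,
                    "post_log_sd": float(h_vals.std(ddof=1)) if h_vals.size > 1 else np.nan,
                }
            )
    org_summaries = pd.DataFrame(
        rows,
        columns=[
            "nutrient", "org_name", "pre_n", "pre_log_mean", "pre_log_sd",
            "post_n", "post_log_mean", "post_log_sd",
        ],
    )
    return {
        "unit_flows": flows,
        "org_summaries": org_summaries,
        "standardized_pct": pct,
        "step_counts": dict(log or {}),
    }
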