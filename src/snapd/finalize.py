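"""Final harmonization stages: outliers, duplicates, combination, QC.

Four stages turn the flagged, converted, imputed record table into the
harmonized daily dataset:

1. **Outlier flagging** — per nutrient parameter, concentrations above the
   99th or below the 1st percentile (pooled over all years) are flagged as
   potential outliers but kept.
2. **Duplicate resolution** — cross-organization exact duplicates collapse
   to one organization; all remaining concentrations for the same site,
   date and nutrient parameter (detected and imputed together, whether or
   not timestamped) average into one daily value.
3. **Fraction combination** — where a filtered and a particulate component
   of a total nutrient exist on a site-date but the unfiltered total was
   not itself measured, their sum is added as a new record.
4. **Filtered-vs-unfiltered QC** — a filtered concentration at or above its
   unfiltered counterpart on the same site-date is physically impossible;
   both members of such a pair are dropped.
"""

from __future__ import annotations

from typing import Optional

import numpy as np
import pandas as pd

from .config import HarmonizationConfig

__all__ = [
    "flag_outliers",
    "resolve_duplicates",
    "combine_fractions",
    "qc_filtered_vs_unfiltered",
]

#: Columns of the daily (post-duplicate-resolution) table.
DAILY_COLUMNS: list[str] = [
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


def flag_outliers(
    df: pd.DataFrame,
    lower_pct: float = 1.0,
    upper_pct: float = 99.0,
) -> pd.DataFrame:
    """Flag concentrations outside the per-nutrient percentile band.

    Percentiles are computed per ``nutrient_parameter`` over all years
    pooled, with linear interpolation between order statistics, and written
    to ``pct1``/``pct99``.  Rows with a missing concentration get flag NA;
    dropped rows are untouched (NA).  Groups smaller than three present
    concentrations are degenerate and nothing in them is flagged.
    """
    out = df.copy()
    out["outlier_flag"] = "NA"
    out["pct1"] = np.nan
    out["pct99"] = np.nan

    live = ~out["_dropped"]
    for _param, grp in out.loc[live].groupby("nutrient_parameter", dropna=True):
        vals = grp["new_conc"]
        present = vals.dropna()
        if len(present) < 3:
            out.loc[grp.index, "outlier_flag"] = np.where(
                vals.notna(), "not_flagged_as_outlier", "NA"
            )
            continue
        p_lo, p_hi = np.percentile(present.to_numpy(dtype=float), [lower_pct, upper_pct])
        out.loc[grp.index, "pct1"] = p_lo
        out.loc[grp.index, "pct99"] = p_hi
        flags = np.where(
            vals.isna(),
            "NA",
            np.where((vals < p_lo) | (vals > p_hi), "potential_outlier", "not_flagged_as_outlier"),
        )
        out.loc[grp.index, "outlier_flag"] = flags
    return out


_SITE_DAY_KEY = ["new_MLI", "new_x", "new_y", "_date", "nutrient_parameter"]


def resolve_duplicates(
    df: pd.DataFrame, config: Optional[HarmonizationConfig] = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Collapse sub-daily and cross-organization duplicates to daily records.

    Returns ``(flagged, daily)``: the input frame with the per-record audit
    counts (``num_obs_per_date``, ``num_orgs_per_obs``, ``num_nds_per_obs``,
    ``num_conc_per_time``) filled in, and the daily table with one row per
    site, date and nutrient parameter.

    Within a site-date-parameter group: records identical except for the
    reporting organization count once (the lexicographically first canonical
    organization name is kept); the surviving detected and imputed
    concentrations average arithmetically into the daily value, regardless
    of timestamps.  A group whose members are all unimputed non-detects
    yields one row with a missing concentration.  The daily row inherits
    ``potential_outlier`` if any member was flagged, and ``impute_flag``
    ``imputed`` if any member was a non-detect.
    """
    out = df.copy()
    for col in ("num_obs_per_date", "num_orgs_per_obs", "num_nds_per_obs", "num_conc_per_time"):
        out[col] = np.nan

    live = ~out["_dropped"]
    sub = out.loc[live]

    # observations per exact timestamp (sub-daily duplicate audit)
    time_key = ["new_MLI", "new_x", "new_y", "_date", "time", "nutrient_parameter"]
    out.loc[live, "num_conc_per_time"] = sub.groupby(
        time_key, dropna=False
    )["record_id"].transform("size")

    daily_rows = []
    for key, grp in sub.groupby(_SITE_DAY_KEY, dropna=False, sort=True):
        mli, x, y, date, param = key

        # collapse records identical but for the reporting organization
        dup_key = ["time", "new_conc", "ND_flag"]
        n_orgs = grp.groupby(dup_key, dropna=False)["org_name"].transform("nunique")
        out.loc[grp.index, "num_orgs_per_obs"] = n_orgs
        rank = grp.sort_values("org_name", kind="stable").groupby(
            dup_key, dropna=False
        ).cumcount()
        rank = rank.reindex(grp.index)
        members = grp.loc[rank == 0]

        n_nd_status = grp["ND_flag"].map(lambda v: "ND" if v == "ND" else "obs").nunique()
        out.loc[grp.index, "num_nds_per_obs"] = n_nd_status

        concs = members["new_conc"].dropna()
        n_avg = len(concs) if len(concs) else len(members)
        out.loc[grp.index, "num_obs_per_date"] = n_avg

        any_nd = bool((members["ND_flag"] == "ND").any())
        conc = float(concs.mean()) if len(concs) else np.nan
        nd_dls = members.loc[members["ND_flag"] == "ND", "new_DL"].dropna()
        dl = float(nd_dls.max()) if any_nd and len(nd_dls) else np.nan
        basis = members["N_or_P"].iloc[0]
        outlier = (
            "NA"
            if np.isnan(conc)
            else (
                "potential_outlier"
                if (members["outlier_flag"] == "potential_outlier").any()
                else "not_flagged_as_outlier"
            )
        )
        first = members.sort_values("org_name", kind="stable").iloc[0]
        daily_rows.append(
            {
                "media": first["media"],
                "st_abbr": first["st_abbr"],
                "st_name": first["st_name"],
                "org_name": first["org_name"],
                "N_or_P": basis,
                "nutrient_name": first["nutrient_name"],
                "sample_fraction": first["sample_fraction"],
                "nutrient_parameter": param,
                "year": first["year"],
                "date": date,
                "MLI": mli,
                "conc": conc,
                "conc_units": f"mg/L as {basis}",
                "outlier_flag": outlier,
                "num_obs_per_date": n_avg,
                "impute_flag": "imputed" if any_nd else "detected",
                "DL": dl,
                "DL_units": f"mg/L as {basis}" if not np.isnan(dl) else np.nan,
                "x": x,
                "y": y,
            }
        )
    daily = pd.DataFrame(daily_rows, columns=DAILY_COLUMNS)
    return out, daily


def combine_fractions(
    daily: pd.DataFrame, config: HarmonizationConfig
) -> pd.DataFrame:
    """Add combined total-nutrient records from fraction components.

    For each site-date where both components of a combination rule exist
    with present concentrations and the target parameter was not itself
    measured, a new record with the summed concentration is appended,
    flagged ``calculated_by_combining``.  Metadata (organization, state,
    medium) come from the first component.
    """
    if daily.empty or not config.combination_rules:
        return daily
    new_rows = []
    for (_mli, _x, _y, _date), grp in daily.groupby(
        ["MLI", "x", "y", "date"], dropna=False
    ):
        params = dict(zip(grp["nutrient_parameter"], grp.index))
        for comp_a, comp_b, target in config.combination_rules:
            if target in params or comp_a not in params or comp_b not in params:
                continue
            a = daily.loc[params[comp_a]]
            b = daily.loc[params[comp_b]]
            if pd.isna(a["conc"]) or pd.isna(b["conc"]):
                continue
            name, fraction = target.rsplit("_", 1)
            row = a.to_dict()
            row.update(
                {
                    "nutrient_name": name,
                    "sample_fraction": fraction,
                    "nutrient_parameter": target,
                    "conc": float(a["conc"]) + float(b["conc"]),
                    "outlier_flag": "not_flagged_as_outlier",
                    "num_obs_per_date": 1,
                    "impute_flag": "calculated_by_combining",
                    "DL": np.nan,
                    "DL_units": np.nan,
                }
            )
            new_rows.append(row)
    if not new_rows:
        return daily
    return pd.concat([daily, pd.DataFrame(new_rows)], ignore_index=True)


def qc_filtered_vs_unfiltered(daily: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Drop physically inconsistent filtered/unfiltered pairs.

    For each site-date-nutrient with both a filtered and an unfiltered
    record (concentrations present), a filtered value greater than or equal
    to the unfiltered one marks both rows ``unfilt conc <= filt conc`` and
    removes them from the harmonized output.  Consistent pairs are flagged
    ``keep``; records without a counterpart get NA and are kept.

    Returns ``(daily_with_flags, surviving_daily)``.
    """
    out = daily.copy()
    out["filt2unfilt_flag"] = "NA"
    if out.empty:
        return out, out.drop(columns=["filt2unfilt_flag"])
    for _key, grp in out.groupby(["MLI", "x", "y", "date", "nutrient_name"], dropna=False):
        filt = grp.loc[(grp["sample_fraction"] == "filtered") & grp["conc"].notna()]
        unfilt = grp.loc[(grp["sample_fraction"] == "unfiltered") & grp["conc"].notna()]
        if filt.empty or unfilt.empty:
            continue
        idx = filt.index.union(unfilt.index)
        if filt["conc"].iloc[0] >= unfilt["conc"].iloc[0]:
            out.loc[idx, "filt2unfilt_flag"] = "unfilt conc <= filt conc"
        else:
            out.loc[idx, "filt2unfilt_flag"] = "keep"
    surviving = out.loc[out["filt2unfilt_flag"] != "unfilt conc <= filt conc"].drop(
        columns=["filt2unfilt_flag"]
    )
    return out, surviving
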