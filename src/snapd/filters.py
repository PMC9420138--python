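"""Organization-name standardization and the metadata filter cascade.

The cascade evaluates one predicate per harmonization step, in ascending
step order, and writes a keep/drop flag per record.  Once any step drops a
record, every later flag on that record is the literal ``NA``: the record
was never evaluated further.  Flagging never deletes rows; the drop is
applied only when the final harmonized table is assembled.

Steps covered here (with the flag each writes):

* medium          -> ``media_flag``       (keep only water samples)
* date            -> ``date_flag``        (keep only dated samples)
* chemical form   -> ``chem_form_flag``   (elemental vs molecular resolvable)
* concentration   -> ``conc_flag``        (numeric, positive, or a non-detect)
* units           -> ``conc_unit_flag``   (convertible to mg/L)
* detection code  -> ``ND_flag`` drop arm (contaminated / QC failures)
* sample fraction -> ``sample_fraction_flag``
* activity type   -> ``activity_type_flag`` (drop laboratory QC activities)
* result type     -> ``result_type_flag`` (drop approximations/guesses)

``media_flag`` and ``date_flag`` sit before everything else and are always
evaluated, so they have no NA arm.
"""

from __future__ import annotations

import re
from typing import Mapping, Optional

import numpy as np
import pandas as pd

from .chemistry import infer_chemical_form, lookup_nutrient
from .config import HarmonizationConfig, normalize_text
from .nondetects import nd_category

__all__ = [
    "standardize_org_name",
    "apply_filter_cascade",
    "parse_concentration",
    "parse_date",
    "CASCADE_FLAGS",
]

#: Cascade flag columns in step order.
CASCADE_FLAGS: list[str] = [
    "media_flag",
    "date_flag",
    "chem_form_flag",
    "conc_flag",
    "conc_unit_flag",
    "ND_flag",
    "sample_fraction_flag",
    "activity_type_flag",
    "result_type_flag",
]

_MINUS = "−"  # unicode minus occasionally found in exports


def parse_concentration(raw) -> Optional[float]:
    """Parse a reported concentration; None when non-numeric or absent."""
    if raw is None or (isinstance(raw, float) and np.isnan(raw)):
        return None
    if isinstance(raw, (int, float)):
        return float(raw)
    text = str(raw).strip().replace(_MINUS, "-")
    try:
        return float(text)
    except ValueError:
        return None


def parse_date(raw) -> Optional[pd.Timestamp]:
    """Parse a sample date (YYYY-MM-DD, or MM/DD/YYYY); None when absent/bad."""
    if raw is None or (isinstance(raw, float) and np.isnan(raw)):
        return None
    text = str(raw).strip()
    for fmt in ("%Y-%m-%d", "%m/%d/%Y"):
        try:
            return pd.Timestamp(pd.to_datetime(text, format=fmt))
        except (ValueError, TypeError):
            continue
    return None


def standardize_org_name(raw: Optional[str], alias_table: Mapping[str, str]) -> Optional[str]:
    """Map an organization-name spelling variant to its canonical form.

    Lookup is whitespace-collapsed and case-insensitive; names without an
    alias entry are returned trimmed but otherwise untouched.
    """
    if raw is None or (isinstance(raw, float) and np.isnan(raw)):
        return None
    trimmed = re.sub(r"\s+", " ", str(raw).strip())
    return alias_table.get(trimmed.lower(), trimmed)


def _is_qc_activity(activity: Optional[str], config: HarmonizationConfig) -> bool:
    if activity is None:
        return False
    norm = normalize_text(activity)
    return norm in config.qc_activity_types or norm.startswith("quality control")


def apply_filter_cascade(df: pd.DataFrame, config: HarmonizationConfig) -> pd.DataFrame:
    """Evaluate the keep/drop cascade; returns the frame with flag columns.

    Also materializes the parsing by-products later stages need:
    ``_date`` (parsed timestamp), ``_conc_val`` (parsed numeric
    concentration), ``_is_nd`` (non-detect indicator) and ``_dropped``
    (any drop so far).
    """
    out = df.copy()
    n = len(out)

    dates = out["date"].map(parse_date)
    out["_date"] = pd.to_datetime(pd.Series(dates, index=out.index))
    conc_vals = out["orig_conc"].map(parse_concentration)
    out["_conc_val"] = pd.to_numeric(pd.Series(conc_vals, index=out.index))

    # Step: medium — keep only water samples (always evaluated, no NA arm)
    media_keep = out["media"].map(
        lambda m: isinstance(m, str) and normalize_text(m) in config.media_whitelist
    )
    out["media_flag"] = np.where(media_keep, "keep", "drop")

    # Step: date — keep only dated samples (always evaluated, no NA arm)
    out["date_flag"] = np.where(out["_date"].notna(), "keep", "drop")

    dropped = (out["media_flag"] == "drop") | (out["date_flag"] == "drop")

    # Step: chemical form — the name/units/method must reveal elemental vs
    # molecular reporting, and a molecular form must have a conversion factor
    def _chem_known(row) -> bool:
        spec = lookup_nutrient(row["nutrient_handle"], config) if isinstance(row["nutrient_handle"], str) else None
        if spec is None:
            return False
        units = row["orig_conc_units"] if isinstance(row["orig_conc_units"], str) else None
        method = row["analytical_method"] if isinstance(row["analytical_method"], str) else None
        form = infer_chemical_form(row["nutrient_handle"], units, method, config)
        if form == "unknown":
            return False
        if form.startswith("molecular:"):
            return config.conversion_factor(form.split(":", 1)[1]) is not None
        return True

    chem_known = out.apply(_chem_known, axis=1) if n else pd.Series(dtype=bool)
    out["chem_form_flag"] = _cascade_flag(
        dropped, keep=chem_known, keep_value="chem_form_known", drop_value="chem_form_unknown"
    )
    dropped |= out["chem_form_flag"] == "chem_form_unknown"

    # Non-detect indication feeds both the concentration and detection steps:
    # a record is a non-detect when the value is zero/negative/missing AND
    # the detection code/text metadata say so.
    nd_cat = out.apply(
        lambda r: nd_category(r["DL_code"], r["DL_text"], config), axis=1
    ) if n else pd.Series(dtype=object)
    cond_value = out["_conc_val"].le(0) | (
        out["orig_conc"].isna() & out["_conc_val"].isna()
    )
    out["_is_nd"] = cond_value & (nd_cat == "nondetect")

    # Step: concentration value — numeric and positive, unless a non-detect
    conc_bad = (out["_conc_val"].isna() | out["_conc_val"].le(0)) & ~out["_is_nd"]
    out["conc_flag"] = _cascade_flag(dropped, keep=~conc_bad)
    dropped |= out["conc_flag"] == "drop"

    # Step: concentration units — must be convertible to mg/L
    unit_ok = out["orig_conc_units"].map(
        lambda u: isinstance(u, str)
        and config.unit_registry.get(normalize_text(u)) is not None
    )
    out["conc_unit_flag"] = _cascade_flag(dropped, keep=unit_ok)
    dropped |= out["conc_unit_flag"] == "drop"

    # Step: detection code/text — drop contaminated/QC-failure results,
    # mark censored observations as ND
    nd_flag = pd.Series("keep", index=out.index, dtype=object)
    nd_flag[out["_is_nd"]] = "ND"
    nd_flag[nd_cat == "contaminated_drop"] = "drop"
    nd_flag[dropped] = "NA"
    out["ND_flag"] = nd_flag
    dropped |= out["ND_flag"] == "drop"

    # Step: sample fraction — must map to a harmonized fraction
    frac_ok = out["sample_fraction_raw"].map(
        lambda f: isinstance(f, str) and normalize_text(f) in config.fraction_map
    )
    out["sample_fraction_flag"] = _cascade_flag(dropped, keep=frac_ok)
    dropped |= out["sample_fraction_flag"] == "drop"

    # Step: activity type — drop laboratory quality-control activities
    qc = out["activity_type"].map(lambda a: _is_qc_activity(a if isinstance(a, str) else None, config))
    out["activity_type_flag"] = _cascade_flag(dropped, keep=~qc)
    dropped |= out["activity_type_flag"] == "drop"

    # Step: result type — drop estimated values (approximation / educated guess)
    def _result_bad(rt) -> bool:
        if not isinstance(rt, str):
            return False
        norm = normalize_text(rt)
        return any(term in norm for term in config.result_type_drop_terms)

    result_bad = out["result_type"].map(_result_bad)
    out["result_type_flag"] = _cascade_flag(dropped, keep=~result_bad)
    dropped |= out["result_type_flag"] == "drop"

    out["_dropped"] = dropped
    return out


def _cascade_flag(
    dropped: pd.Series,
    keep: pd.Series,
    keep_value: str = "keep",
    drop_value: str = "drop",
) -> pd.Series:
    flag = pd.Series(
        np.where(keep.astype(bool), keep_value, drop_value),
        index=dropped.index,
        dtype=object,
    )
    flag[dropped] = "NA"
    return flag
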