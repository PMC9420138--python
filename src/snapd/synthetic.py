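"""Synthetic raw-record generator with a known-truth sidecar.

Emulates the messiness of a multi-organization water-quality export so the
whole harmonization pipeline is testable without any download: spelling
variants of organization names, duplicate coordinates and duplicate MLIs,
elemental vs molecular nutrient reporting, unit dialects, censored
non-detects (encoded as zero, negative or missing values) with and without
detection limits, laboratory QC activity types, estimated result types,
sub-daily duplicate measurements and filtered/unfiltered sample pairs.

Every generated raw record is paired with a :class:`TruthRecord` carrying
the latent elemental concentration, the canonical site, and the *expected
fate* of the record under the harmonization cascade — the oracle used by
the end-to-end tests.

Each record occupies its own calendar day within its site-year (sampled
without replacement) except for deliberately injected sub-daily duplicates
and filtered/unfiltered or fraction-combination partners, which share the
day of their base record.  This makes every duplicate-resolution and
consistency decision of the pipeline predictable from the injected
corruption alone.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Mapping, Optional

import numpy as np
import pandas as pd
from scipy.special import ndtri

from .config import ConversionEntry, HarmonizationConfig, normalize_text
from .io import RAW_COLUMNS

__all__ = ["GeneratorSpec", "generate_dataset", "generate_molecular_report", "TRUTH_COLUMNS"]

TRUTH_COLUMNS = [
    "record_id",
    "true_conc_mgL",
    "latent_site",
    "expected_fate",
    "injected_anomaly",
]

#: (nutrient, fraction) sampling panel with weights.
_PANEL: list[tuple[str, str, float]] = [
    ("ammonia", "filtered", 0.10),
    ("ammonia", "unfiltered", 0.12),
    ("nitrate", "filtered", 0.10),
    ("kjeldahl nitrogen", "unfiltered", 0.12),
    ("total nitrogen", "filtered", 0.08),
    ("total nitrogen", "particulate", 0.03),
    ("total nitrogen", "unfiltered", 0.12),
    ("orthophosphate", "filtered", 0.10),
    ("total phosphorus", "filtered", 0.08),
    ("total phosphorus", "particulate", 0.03),
    ("total phosphorus", "unfiltered", 0.12),
]

_BASIS = {
    "ammonia": "N",
    "nitrate": "N",
    "kjeldahl nitrogen": "N",
    "total nitrogen": "N",
    "organic nitrogen": "N",
    "inorganic nitrogen": "N",
    "orthophosphate": "P",
    "total phosphorus": "P",
    "organic phosphorus": "P",
}

#: Raw handles whose name states the elemental form.
_ELEMENTAL_HANDLES = {
    "ammonia": "Ammonia N as N",
    "nitrate": "Nitrate as N",
    "kjeldahl nitrogen": "Kjeldahl N",
    "total nitrogen": "Total Nitrogen, mixed forms",
    "orthophosphate": "Orthophosphate as P",
    "organic nitrogen": "Organic Nitrogen",
    "inorganic nitrogen": "Nitrogen nutrient",
    "organic phosphorus": "Organic Phosphorus",
}

#: Raw handles whose name hides the form (needs units or a method to resolve).
_UNKNOWN_HANDLES = {
    "ammonia": "Ammonia",
    "nitrate": "Nitrate",
    "orthophosphate": "Phosphate",
    "total phosphorus": "Phosphorus",
}

#: Analytical methods that pin the elemental form for unknown-named handles.
_METHODS = {
    "ammonia": "350.1",
    "nitrate": "353.2",
    "orthophosphate": "365.1",
    "total phosphorus": "365.1",
}

#: Molecular reporting variants: nutrient -> (handle or None, form code).
#: Nitrate has no molecular-named handle; the units carry the form instead.
_MOLECULAR_VARIANTS: dict[str, list[tuple[Optional[str], str]]] = {
    "ammonia": [("Ammonia as NH3", "NH3"), ("Ammonium as NH4", "NH4")],
    "nitrate": [(None, "NO3")],
    "orthophosphate": [("Orthophosphate as PO4", "PO4")],
}

_STATES = [
    ("IL", "Illinois"),
    ("IA", "Iowa"),
    ("MO", "Missouri"),
    ("MN", "Minnesota"),
    ("OH", "Ohio"),
    ("TN", "Tennessee"),
]

_ORG_POOL = [
    "USGS",
    "EPA",
    "Illinois EPA",
    "Iowa DNR",
    "Missouri DNR",
    "Minnesota PCA",
    "Ohio River Sanitation Commission",
    "Prairie Rivers Water Authority",
]

_ORG_TABLE_VARIANTS = {
    "USGS": ["U.S. Geological Survey", "US Geological Survey", "usgs"],
    "EPA": ["U.S. Environmental Protection Agency", "Environmental Protection Agency"],
}

_ND_CODES = ["U", "nd", "Not Detected"]
_QC_ACTIVITIES = [
    "Quality Control Sample-Field Blank",
    "Quality Control Sample-Lab Blank",
    "Quality Control Sample-Lab Duplicate",
]
_ESTIMATED_RESULTS = ["Calculated - Approximation", "Educated Guess"]
_BAD_MEDIA = ["Soil", "Air", "Sediment"]

#: Default lognormal parameters (mu, sigma) of the latent elemental
#: concentration, in log mg/L — typical stream nutrient levels.
_DEFAULT_LOGNORMAL: dict[str, tuple[float, float]] = {
    "ammonia": (-1.6, 1.0),
    "nitrate": (0.0, 1.0),
    "kjeldahl nitrogen": (-0.3, 0.9),
    "total nitrogen": (0.3, 1.0),
    "organic nitrogen": (-0.7, 0.9),
    "inorganic nitrogen": (-0.5, 1.0),
    "orthophosphate": (-3.0, 1.0),
    "total phosphorus": (-2.3, 1.0),
    "organic phosphorus": (-3.2, 1.0),
}

#: Default concentration-unit dialect weights.  "mg/l as elem" becomes
#: "mg/l as n" or "mg/l as p"; "% recovery" and "mg/kg" are unconvertible.
_DEFAULT_UNIT_WEIGHTS: dict[str, float] = {
    "mg/l as elem": 0.35,
    "mg/l": 0.30,
    "ug/l": 0.15,
    "ppm": 0.06,
    "ppb": 0.04,
    "% recovery": 0.05,
    "mg/kg": 0.05,
}

_UNIT_SCALE = {"mg/l as elem": 1.0, "mg/l": 1.0, "ug/l": 1000.0, "ppm": 1.0, "ppb": 1000.0}

_FRACTION_TEXT = {
    "filtered": ["Filtered", "Dissolved"],
    "unfiltered": ["Unfiltered", "Total"],
    "particulate": ["Particulate", "Suspended"],
    "inorganic": ["Inorganic"],
    "organic": ["Organic"],
}

_CASCADE_FATES = [
    "dropped_step3",
    "dropped_step4",
    "dropped_step5",
    "dropped_step7",
    "dropped_step10",
    "dropped_step11",
]


@dataclass
class GeneratorSpec:
    """Parameters of the synthetic raw-record generator.

    All ``*_rate`` values are probabilities in [0, 1].  The defaults are the
    generator's study conditions: a handful of organizations sampling a few
    dozen sites roughly monthly over several years, with corruption rates
    at levels typical of multi-organization compilations.
    """

    n_orgs: int = 6
    n_sites: int = 30
    n_years: int = 5
    start_year: int = 2000
    records_per_site_year: float = 12.0  # Poisson mean
    nd_rate: float = 0.15
    nd_missing_dl_rate: float = 0.30
    dup_coord_rate: float = 0.05
    dup_mli_rate: float = 0.05
    sub_daily_dup_rate: float = 0.03
    unit_dialect_weights: Mapping[str, float] = field(
        default_factory=lambda: dict(_DEFAULT_UNIT_WEIGHTS)
    )
    molecular_report_rate: float = 0.25
    unknown_form_rate: float = 0.02
    qc_activity_rate: float = 0.04
    estimated_result_rate: float = 0.015
    bad_media_rate: float = 0.02
    missing_date_rate: float = 0.002
    org_alias_rate: float = 0.10
    filtered_pair_rate: float = 0.10
    fraction_combo_rate: float = 0.05
    inconsistency_rate: float = 0.05  # given a filtered/unfiltered pair
    lognormal_params: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: dict(_DEFAULT_LOGNORMAL)
    )
    heavy_tails: bool = False  # Student-t(3) log-concentrations instead
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_sites <= 0 or self.n_years <= 0:
            raise ValueError("n_sites and n_years must be positive")
        if not (1980 <= self.start_year and self.start_year + self.n_years - 1 <= 2018):
            raise ValueError("years must lie within 1980-2018")
        for name in (
            "nd_rate", "nd_missing_dl_rate", "dup_coord_rate", "dup_mli_rate",
            "sub_daily_dup_rate", "molecular_report_rate", "unknown_form_rate",
            "qc_activity_rate", "estimated_result_rate", "bad_media_rate",
            "missing_date_rate", "org_alias_rate", "filtered_pair_rate",
            "fraction_combo_rate", "inconsistency_rate",
        ):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0, 1], got {v}")

    @classmethod
    def clean(cls, **overrides) -> "GeneratorSpec":
        """A corruption-free spec: every record clean, elemental, mg/L."""
        base = dict(
            nd_rate=0.0,
            nd_missing_dl_rate=0.0,
            dup_coord_rate=0.0,
            dup_mli_rate=0.0,
            sub_daily_dup_rate=0.0,
            unit_dialect_weights={"mg/l as elem": 1.0},
            molecular_report_rate=0.0,
            unknown_form_rate=0.0,
            qc_activity_rate=0.0,
            estimated_result_rate=0.0,
            bad_media_rate=0.0,
            missing_date_rate=0.0,
            org_alias_rate=0.0,
            filtered_pair_rate=0.0,
            fraction_combo_rate=0.0,
            inconsistency_rate=0.0,
        )
        base.update(overrides)
        return cls(**base)


def generate_molecular_report(true_conc: float, entry: ConversionEntry) -> float:
    """Report an elemental concentration on the molecular basis.

    The inverse of the harmonization conversion: downstream multiplication
    by the entry's factor recovers the elemental value exactly.
    """
    if entry.factor <= 0:
        raise ValueError("conversion factor must be positive")
    return true_conc / entry.factor


def _fmt(x: float) -> str:
    return repr(float(x))


class _Generator:
    def __init__(self, spec: GeneratorSpec):
        self.spec = spec
        self.rng = np.random.default_rng(spec.seed)
        self.config = HarmonizationConfig()
        self.rows: list[dict] = []
        self.truth: list[dict] = []

    # -- site/org scaffolding -------------------------------------------------

    def _build_sites(self) -> list[dict]:
        spec, rng = self.spec, self.rng
        orgs = [_ORG_POOL[i % len(_ORG_POOL)] for i in range(spec.n_orgs)]
        sites = []
        for i in range(spec.n_sites):
            state = _STATES[int(rng.integers(len(_STATES)))]
            x = float(rng.uniform(0.0, 500_000.0))
            y = float(rng.uniform(0.0, 500_000.0))
            site = {
                "mli": f"SITE-{i:04d}",
                "x": x,
                "y": y,
                "org": orgs[int(rng.integers(len(orgs)))],
                "state": state,
                "alt_coord": None,
                "alt_mli": None,
            }
            if rng.random() < spec.dup_coord_rate:
                # offset drawn up to twice the merge threshold so both the
                # combine and keep-separate branches occur
                r = rng.uniform(0.0, 2.0 * self.config.coord_merge_threshold_m)
                theta = rng.uniform(0.0, 2.0 * np.pi)
                site["alt_coord"] = (x + r * np.cos(theta), y + r * np.sin(theta))
            if rng.random() < spec.dup_mli_rate:
                site["alt_mli"] = f"{site['mli']}-ALT"
            sites.append(site)
        return sites

    def _org_spelling(self, canonical: str) -> str:
        rng = self.rng
        if rng.random() >= self.spec.org_alias_rate:
            return canonical
        variants = _ORG_TABLE_VARIANTS.get(canonical)
        if variants:
            return variants[int(rng.integers(len(variants)))]
        return f"  {canonical} "  # whitespace mangling only; trimming recovers it

    # -- one record -----------------------------------------------------------

    def _latent_conc(self, nutrient: str) -> float:
        mu, sigma = self.spec.lognormal_params[nutrient]
        if self.spec.heavy_tails:
            z = self.rng.standard_t(3)
        else:
            z = self.rng.standard_normal()
        return float(np.exp(mu + sigma * z))

    def _detection_limit(self, nutrient: str) -> float:
        # per-nutrient DL at the nd_rate quantile of the latent lognormal, so
        # each record is censored independently with probability nd_rate
        mu, sigma = self.spec.lognormal_params[nutrient]
        return float(np.exp(mu + sigma * ndtri(self.spec.nd_rate)))

    def _emit(
        self,
        site: dict,
        nutrient: str,
        fraction: str,
        date: Optional[pd.Timestamp],
        time: Optional[str],
        true_conc: float,
        censorable: bool,
        base_tag: Optional[str] = None,
        conc_override: Optional[float] = None,
    ) -> int:
        """Generate one raw record; returns its index in self.rows."""
        spec, rng = self.spec, self.rng
        basis = _BASIS[nutrient]
        anomalies: list[str] = []

        # chemical-form / handle choice
        handle = _ELEMENTAL_HANDLES.get(nutrient)
        mol_factor: Optional[float] = None
        forced_units: Optional[str] = None
        method: Optional[str] = None
        unknown_form = False
        if (
            nutrient in _MOLECULAR_VARIANTS
            and rng.random() < spec.molecular_report_rate
        ):
            mol_handle, form = _MOLECULAR_VARIANTS[nutrient][
                int(rng.integers(len(_MOLECULAR_VARIANTS[nutrient])))
            ]
            mol_factor = self.config.conversion_factor(form)
            if mol_handle is None:
                handle = _UNKNOWN_HANDLES[nutrient]
                forced_units = f"mg/l as {form.lower()}"
            else:
                handle = mol_handle
            anomalies.append("molecular_form")
        elif nutrient in _UNKNOWN_HANDLES and rng.random() < spec.unknown_form_rate:
            handle = _UNKNOWN_HANDLES[nutrient]
            forced_units = "mg/l"
            unknown_form = True
            anomalies.append("unknown_form")
        elif handle is None:
            # nutrients with no elemental-named handle (total phosphorus):
            # the name hides the form, a method pins it down
            handle = _UNKNOWN_HANDLES[nutrient]
            method = _METHODS[nutrient]

        # units
        if forced_units is not None:
            units = forced_units
            unit_scale: Optional[float] = 1.0 if not unknown_form else 1.0
        else:
            tokens = list(spec.unit_dialect_weights)
            weights = np.array([spec.unit_dialect_weights[t] for t in tokens], dtype=float)
            token = tokens[int(rng.choice(len(tokens), p=weights / weights.sum()))]
            if token == "mg/l as elem":
                units = f"mg/l as {basis.lower()}"
            else:
                units = token
            unit_scale = _UNIT_SCALE.get(token)
            if unit_scale is None:
                anomalies.append("unconvertible_unit")
        # an unknown-named handle with units that do not reveal the form
        # needs an analytical method to stay interpretable
        if (
            method is None
            and not unknown_form
            and mol_factor is None
            and _ELEMENTAL_HANDLES.get(nutrient) is None
        ):
            method = _METHODS[nutrient]

        # censoring
        is_nd = False
        dl_elem: Optional[float] = None
        nd_missing_dl = False
        if censorable and spec.nd_rate > 0:
            dl = self._detection_limit(nutrient)
            if true_conc < dl:
                is_nd = True
                dl_elem = dl
                nd_missing_dl = rng.random() < spec.nd_missing_dl_rate
                anomalies.append("nondetect")

        # reported value on the reporting basis
        reported = true_conc if conc_override is None else conc_override
        if mol_factor is not None:
            reported = reported / mol_factor
        if unit_scale is not None:
            reported = reported * unit_scale

        orig_conc: Optional[str]
        dl_code = None
        dl_val = None
        dl_units = None
        if is_nd:
            style = int(rng.integers(3))
            orig_conc = {0: "0", 1: _fmt(-1.0), 2: None}[style]
            dl_code = _ND_CODES[int(rng.integers(len(_ND_CODES)))]
            if not nd_missing_dl:
                rep_dl = dl_elem
                if mol_factor is not None:
                    rep_dl = rep_dl / mol_factor
                if unit_scale is not None:
                    rep_dl = rep_dl * unit_scale
                dl_val = rep_dl
                dl_units = units
        else:
            orig_conc = _fmt(reported)

        # metadata corruption
        media = ["Water", "water", "Surface Water"][int(rng.integers(3))]
        bad_media = rng.random() < spec.bad_media_rate
        if bad_media:
            media = _BAD_MEDIA[int(rng.integers(len(_BAD_MEDIA)))]
            anomalies.append("bad_media")
        missing_date = rng.random() < spec.missing_date_rate
        if missing_date:
            anomalies.append("missing_date")
        activity = ["Sample-Routine", "Field Msr/Obs"][int(rng.integers(2))]
        if rng.random() < spec.qc_activity_rate:
            activity = _QC_ACTIVITIES[int(rng.integers(len(_QC_ACTIVITIES)))]
            anomalies.append("qc_activity")
        result_type = "Actual"
        if rng.random() < spec.estimated_result_rate:
            result_type = _ESTIMATED_RESULTS[int(rng.integers(len(_ESTIMATED_RESULTS)))]
            anomalies.append("estimated_result")

        org_spelling = self._org_spelling(site["org"])
        if org_spelling != site["org"]:
            anomalies.append("org_alias")
        mli = site["mli"]
        x, y = site["x"], site["y"]
        if site["alt_mli"] is not None and rng.random() < 0.5:
            mli = site["alt_mli"]
            anomalies.append("dup_mli")
        if site["alt_coord"] is not None and date is not None and date.month >= 7:
            # the site "moved" mid-record: later samples use the second pair
            x, y = site["alt_coord"]
            anomalies.append("dup_coords")

        frac_texts = _FRACTION_TEXT[fraction]
        row = {
            "org_name_raw": org_spelling,
            "st_abbr": site["state"][0],
            "st_name": site["state"][1],
            "orig_MLI": mli,
            "orig_x": x,
            "orig_y": y,
            "date": None if missing_date else date.strftime("%Y-%m-%d"),
            "time": time,
            "media": media,
            "activity_type": activity,
            "result_type": result_type,
            "nutrient_handle": handle,
            "analytical_method": method,
            "sample_fraction_raw": frac_texts[int(rng.integers(len(frac_texts)))],
            "orig_conc": orig_conc,
            "orig_conc_units": units,
            "DL_code": dl_code,
            "DL_text": None,
            "orig_DL_val": dl_val,
            "orig_DL_units": dl_units,
            "provider": "STORET",
        }

        # expected fate under the cascade, in ascending step order
        if bad_media:
            fate = "dropped_step3"
        elif missing_date:
            fate = "dropped_step4"
        elif unknown_form:
            fate = "dropped_step5"
        elif unit_scale is None:
            fate = "dropped_step7"
        elif "qc_activity" in anomalies:
            fate = "dropped_step10"
        elif "estimated_result" in anomalies:
            fate = "dropped_step11"
        elif base_tag is not None:
            fate = base_tag  # pair/combo/sub-daily role, refined later
        elif is_nd:
            fate = "imputed"  # may flip to kept when the group is >=80 % ND
        else:
            fate = "kept"

        self.rows.append(row)
        self.truth.append(
            {
                "true_conc_mgL": true_conc,
                "latent_site": site["mli"],
                "nutrient": nutrient,
                "fraction": fraction,
                "year": None if date is None else date.year,
                "expected_fate": fate,
                "is_nd": is_nd,
                "injected_anomaly": ";".join(anomalies) if anomalies else None,
            }
        )
        return len(self.rows) - 1

    # -- whole dataset --------------------------------------------------------

    def run(self) -> tuple[pd.DataFrame, pd.DataFrame]:
        spec, rng = self.spec, self.rng
        sites = self._build_sites()
        panel_w = np.array([w for _, _, w in _PANEL])
        panel_w = panel_w / panel_w.sum()

        for site in sites:
            for year in range(spec.start_year, spec.start_year + spec.n_years):
                n = int(rng.poisson(spec.records_per_site_year))
                n = min(n, 300)
                if n == 0:
                    continue
                days = rng.choice(365, size=n, replace=False)
                for day in days:
                    date = pd.Timestamp(year, 1, 1) + pd.Timedelta(int(day), "D")
                    hh = int(rng.integers(6, 18))
                    time = f"{hh:02d}:00:00"
                    k = int(rng.choice(len(_PANEL), p=panel_w))
                    nutrient, fraction, _ = _PANEL[k]
                    true_conc = self._latent_conc(nutrient)

                    is_pair = (
                        fraction == "unfiltered"
                        and nutrient in ("total nitrogen", "total phosphorus")
                        and rng.random() < spec.filtered_pair_rate
                    )
                    is_combo = (
                        fraction == "filtered"
                        and nutrient in ("total nitrogen", "total phosphorus")
                        and rng.random() < spec.fraction_combo_rate
                    )
                    if is_pair:
                        inconsistent = rng.random() < spec.inconsistency_rate
                        if inconsistent:
                            filt_conc = true_conc * float(rng.uniform(1.0, 1.2))
                            tag = "pair_inconsistent"
                        else:
                            filt_conc = true_conc * float(rng.uniform(0.3, 0.9))
                            tag = "pair_consistent"
                        i_unfilt = self._emit(
                            site, nutrient, "unfiltered", date, time, true_conc,
                            censorable=False, base_tag=tag,
                        )
                        i_filt = self._emit(
                            site, nutrient, "filtered", date, time, filt_conc,
                            censorable=False, base_tag=tag,
                        )
                        self._resolve_pair(i_unfilt, i_filt, inconsistent)
                    elif is_combo:
                        part_conc = self._latent_conc(nutrient) * 0.3
                        i_filt = self._emit(
                            site, nutrient, "filtered", date, time, true_conc,
                            censorable=False, base_tag="combo",
                        )
                        i_part = self._emit(
                            site, nutrient, "particulate", date, time, part_conc,
                            censorable=False, base_tag="combo",
                        )
                        self._resolve_combo(i_filt, i_part)
                    else:
                        idx = self._emit(
                            site, nutrient, fraction, date, time, true_conc,
                            censorable=True,
                        )
                        if rng.random() < spec.sub_daily_dup_rate:
                            t2 = f"{min(hh + 2, 23):02d}:00:00"
                            dup_conc = self._latent_conc(nutrient)
                            j = self._emit(
                                site, nutrient, fraction, date, t2, dup_conc,
                                censorable=True, base_tag="averaged",
                            )
                            if self.truth[idx]["expected_fate"] == "kept":
                                self.truth[idx]["expected_fate"] = "averaged"
                            if self.truth[j]["expected_fate"] == "averaged" and (
                                self.truth[j]["is_nd"]
                            ):
                                self.truth[j]["expected_fate"] = "imputed"

        self._finalize_nd_fates()

        raw = pd.DataFrame(self.rows, columns=RAW_COLUMNS)
        raw.insert(0, "record_id", np.arange(len(raw), dtype=np.int64))
        truth = pd.DataFrame(self.truth)
        truth.insert(0, "record_id", np.arange(len(truth), dtype=np.int64))
        truth = truth[TRUTH_COLUMNS + ["nutrient", "fraction", "year", "is_nd"]]
        return raw, truth

    def _resolve_pair(self, i_unfilt: int, i_filt: int, inconsistent: bool) -> None:
        fu = self.truth[i_unfilt]["expected_fate"]
        ff = self.truth[i_filt]["expected_fate"]
        both_survive = not fu.startswith("dropped") and not ff.startswith("dropped")
        if both_survive:
            final = "dropped_step19" if inconsistent else "kept"
            self.truth[i_unfilt]["expected_fate"] = final
            self.truth[i_filt]["expected_fate"] = final
        else:
            for i in (i_unfilt, i_filt):
                if not self.truth[i]["expected_fate"].startswith("dropped"):
                    self.truth[i]["expected_fate"] = "kept"

    def _resolve_combo(self, i_filt: int, i_part: int) -> None:
        ff = self.truth[i_filt]["expected_fate"]
        fp = self.truth[i_part]["expected_fate"]
        both_survive = not ff.startswith("dropped") and not fp.startswith("dropped")
        if both_survive:
            self.truth[i_filt]["expected_fate"] = "combined_source"
            self.truth[i_part]["expected_fate"] = "combined_source"
        else:
            for i in (i_filt, i_part):
                if not self.truth[i]["expected_fate"].startswith("dropped"):
                    self.truth[i]["expected_fate"] = "kept"

    def _finalize_nd_fates(self) -> None:
        """Flip ND fates to plain kept where the group reaches the 80 % cutoff."""
        share = self.config.nd_impute_max_share
        groups: dict[tuple, list[int]] = {}
        for i, t in enumerate(self.truth):
            if t["expected_fate"].startswith("dropped") or t["year"] is None:
                continue
            key = (t["latent_site"], t["nutrient"], t["fraction"], t["year"])
            groups.setdefault(key, []).append(i)
        for members in groups.values():
            n_nd = sum(self.truth[i]["is_nd"] for i in members)
            if n_nd and 100.0 * n_nd / len(members) >= 100.0 * share:
                for i in members:
                    if self.truth[i]["is_nd"]:
                        self.truth[i]["expected_fate"] = "kept"
                        tag = self.truth[i]["injected_anomaly"] or ""
                        self.truth[i]["injected_anomaly"] = (
                            tag + ";nd_not_imputed" if tag else "nd_not_imputed"
                        )


def generate_dataset(spec: GeneratorSpec) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate a raw record table and its truth sidecar.

    Returns ``(raw, truth)``: the raw frame follows the raw input schema
    (with ``record_id``), and each truth row carries the latent elemental
    concentration in mg/L, the canonical site, the expected fate of the
    record under harmonization, and tags for every injected anomaly.
    The same spec (including seed) always yields byte-identical output.
    """
    return _Generator(spec).run()
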