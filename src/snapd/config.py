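"""Configuration for the nutrient water-quality harmonization pipeline.

Every fixed constant, registry and controlled vocabulary the pipeline uses
lives in one :class:`HarmonizationConfig` object: the 400 m coordinate-merge
threshold, the 80 % non-detect imputation cutoff, the number of imputed
datasets (K = 10), the 1st/99th outlier percentiles, the molecular-to-
elemental conversion factors, the concentration-unit registry, the raw
nutrient-name vocabulary, and the keep/drop vocabularies for media, sample
fraction, activity type, result type and detection codes.

All string vocabularies are data, not code: the raw Water Quality Portal
dialect is not standardized, so users can override any registry from a YAML
document passed to :func:`load_config`.
"""

from __future__ import annotations

import dataclasses
import re
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import yaml

__all__ = [
    "ConfigError",
    "ConversionEntry",
    "NutrientSpec",
    "HarmonizationConfig",
    "load_config",
    "normalize_text",
    "normalize_handle",
]


class ConfigError(ValueError):
    """Raised when a configuration document is malformed; names the key."""


_WS = re.compile(r"\s+")


def normalize_text(s: str) -> str:
    """Trim, collapse internal whitespace and case-fold for vocabulary lookup."""
    return _WS.sub(" ", s.strip()).lower()


def normalize_handle(s: str) -> str:
    """Normalize a raw nutrient name for vocabulary lookup.

    Underscores are treated as spaces (WQP exports use both ``Ammonia N as N``
    and ``ammonia_N_as_N``) and chemical-formula digit groups are re-attached
    (``NH_3_`` -> ``nh3``).
    """
    s = normalize_text(s.replace("_", " "))
    return re.sub(r"\b(nh|no|po)\s+(\d)", r"\1\2", s)


@dataclass(frozen=True)
class ConversionEntry:
    """One molecular-to-elemental conversion: conc_reported * factor = conc_elemental."""

    nutrient: str
    reported_form: str  # e.g. "NO3"
    factor: float
    target_form: str  # "as N" or "as P"


#: Molecular -> elemental conversion factors (mass ratio of the nutrient
#: element to the reported compound, as published by the WQX guidance).
DEFAULT_CONVERSION_TABLE: tuple[ConversionEntry, ...] = (
    ConversionEntry("ammonia", "NH3", 0.822, "as N"),
    ConversionEntry("ammonia", "NH4", 0.776, "as N"),
    ConversionEntry("nitrate", "NO3", 0.225, "as N"),
    ConversionEntry("orthophosphate", "PO4", 0.326, "as P"),
)


@dataclass(frozen=True)
class NutrientSpec:
    """How one raw nutrient name maps into the harmonized vocabulary."""

    raw_handle: str
    harmonized_name: str
    N_or_P: str  # "N" or "P"
    form_status: str  # "elemental", "molecular:<FORM>", or "unknown"


#: The harmonized nutrient-name vocabulary of the output dataset.
HARMONIZED_NUTRIENT_NAMES: frozenset[str] = frozenset(
    {
        "ammonia",
        "nitrate",
        "organic nitrogen",
        "kjeldahl nitrogen",
        "total nitrogen",
        "inorganic nitrogen",
        "organic phosphorus",
        "orthophosphate",
        "total phosphorus",
    }
)


def _nv(handle: str, name: str, basis: str, form: str) -> tuple[str, NutrientSpec]:
    return normalize_handle(handle), NutrientSpec(handle, name, basis, form)


#: Raw nutrient name -> harmonized name, nutrient basis, chemical-form status.
#: "unknown" means the name alone does not reveal elemental vs molecular
#: reporting; those records need clarifying units or an analytical method.
DEFAULT_NUTRIENT_VOCABULARY: dict[str, NutrientSpec] = dict(
    [
        # nitrogen-based compounds
        _nv("Ammonia", "ammonia", "N", "unknown"),
        _nv("Ammonia as NH3", "ammonia", "N", "molecular:NH3"),
        _nv("Ammonia N", "ammonia", "N", "unknown"),
        _nv("Ammonia N as N", "ammonia", "N", "elemental"),
        _nv("Ammonium as NH4", "ammonia", "N", "molecular:NH4"),
        _nv("Kjeldahl N", "kjeldahl nitrogen", "N", "elemental"),
        _nv("Nitrate", "nitrate", "N", "unknown"),
        _nv("Nitrate as N", "nitrate", "N", "elemental"),
        _nv("Nitrogen", "total nitrogen", "N", "elemental"),
        _nv("Nitrogen, mixed forms", "total nitrogen", "N", "elemental"),
        _nv("Nitrogen nutrient", "inorganic nitrogen", "N", "elemental"),
        _nv("Organic Nitrogen", "organic nitrogen", "N", "elemental"),
        _nv("Total Ammonia", "ammonia", "N", "unknown"),
        _nv("Total Kjeldahl N", "kjeldahl nitrogen", "N", "elemental"),
        _nv(
            "Total Kjeldahl N (Organic N plus Nitrate)",
            "kjeldahl nitrogen",
            "N",
            "elemental",
        ),
        _nv("Total Nitrogen, mixed forms", "total nitrogen", "N", "elemental"),
        # phosphorus-based compounds
        _nv("Organic Phosphorus", "organic phosphorus", "P", "elemental"),
        _nv("Organic Phosphorus, particulate", "organic phosphorus", "P", "elemental"),
        _nv("Orthophosphate", "orthophosphate", "P", "unknown"),
        _nv("Orthophosphate as P", "orthophosphate", "P", "elemental"),
        _nv("Orthophosphate as PO4", "orthophosphate", "P", "molecular:PO4"),
        _nv("Phosphate", "orthophosphate", "P", "unknown"),
        _nv("Phosphate as P", "orthophosphate", "P", "elemental"),
        _nv("Phosphate as PO4", "orthophosphate", "P", "molecular:PO4"),
        _nv("Phosphate Phosphorus", "orthophosphate", "P", "unknown"),
        _nv("Phosphate Phosphorus as P", "orthophosphate", "P", "elemental"),
        _nv("Phosphate Phosphorus as PO4", "orthophosphate", "P", "molecular:PO4"),
        _nv("Phosphorus", "total phosphorus", "P", "unknown"),
        _nv("Phosphorus, hydrolyzable", "total phosphorus", "P", "unknown"),
        _nv("Soluble Reactive Phosphorus", "orthophosphate", "P", "unknown"),
        _nv("Total Phosphorus, mixed forms", "total phosphorus", "P", "unknown"),
    ]
)

#: Concentration-unit registry: normalized unit text -> factor to mg/L, or
#: None when the unit carries no mass-per-volume meaning and the record must
#: be dropped.  Units mentioning a molecular form ("mg/l as no3") convert at
#: the mass scale here; the molecular->elemental factor is applied separately.
DEFAULT_UNIT_REGISTRY: dict[str, Optional[float]] = {
    "mg/l": 1.0,
    "mg/l as n": 1.0,
    "mg/l as p": 1.0,
    "mg/l as nh3": 1.0,
    "mg/l as nh4": 1.0,
    "mg/l as no3": 1.0,
    "mg/l as po4": 1.0,
    "mg n/l": 1.0,
    "mg p/l": 1.0,
    "ppm": 1.0,
    "ug/l": 0.001,
    "ug/l as n": 0.001,
    "ug/l as p": 0.001,
    "ug/l as no3": 0.001,
    "ppb": 0.001,
    # no mass-per-volume meaning -> unconvertible
    "%": None,
    "% by vol": None,
    "% by wt": None,
    "% recovery": None,
    "#/100 ml": None,
    "cfu/100 ml": None,
    "cm3/g": None,
    "cm3/g @stp": None,
    "cm3/g stp": None,
    "g/kg": None,
    "g/m2": None,
    "lb/day": None,
    "mg/g": None,
    "mg/kg": None,
    "mg/kg as n": None,
    "mg/kg as p": None,
    "mg/kg po4": None,
    "mg/m2 nh4": None,
    "mgd": None,
    "ml/l": None,
    "mpn": None,
    "mpn/100 ml": None,
    "mv": None,
    "none": None,
    "ntu": None,
    "pci/l": None,
    "ueq/l": None,
    "ug/kg": None,
    # chemically convertible only with a known molar mass; routed to drop
    "umol/l": None,
}

#: Analytical-method code -> chemical form ("elemental" or "molecular:<FORM>").
#: Small static table of common EPA / Standard Methods codes that report the
#: elemental basis; extendable through configuration.
DEFAULT_METHOD_REGISTRY: dict[str, str] = {
    "4500-no3-e": "elemental",
    "4500-no3-f": "elemental",
    "4500-nh3-g": "elemental",
    "4500-norg-b": "elemental",
    "4500-p-e": "elemental",
    "4500-p-f": "elemental",
    "350.1": "elemental",
    "351.2": "elemental",
    "353.2": "elemental",
    "365.1": "elemental",
    "365.3": "elemental",
}

#: Detection code/text token -> category.  "nondetect" marks censored
#: observations; "contaminated_drop" marks QC failures that must be dropped.
DEFAULT_ND_CODE_VOCABULARY: dict[str, str] = {
    "u": "nondetect",
    "nd": "nondetect",
    "non-detect": "nondetect",
    "not detected": "nondetect",
    "below detection limit": "nondetect",
    "below method detection limit": "nondetect",
    "bdl": "nondetect",
    "bpql": "nondetect",
    "<": "nondetect",
    "contaminated": "contaminated_drop",
    "sample contaminated": "contaminated_drop",
    "rejected": "contaminated_drop",
    "analysis lost": "contaminated_drop",
    "invalid": "contaminated_drop",
    "qc fail": "contaminated_drop",
}

DEFAULT_MEDIA_WHITELIST: frozenset[str] = frozenset(
    {"water", "surface water", "ground water", "groundwater"}
)

#: Activity types that do not correspond to a field sample at a monitoring
#: site (laboratory QC and similar); matched exactly after normalization, and
#: any activity type starting with "quality control" is also dropped.
DEFAULT_QC_ACTIVITY_TYPES: frozenset[str] = frozenset(
    {
        "quality control sample-field blank",
        "quality control sample-lab blank",
        "quality control sample-equipment blank",
        "quality control sample-lab duplicate",
        "quality control sample-lab spike",
        "quality control sample-field replicate",
        "quality control field replicate msr/obs",
        "quality control sample-trip blank",
    }
)

DEFAULT_RESULT_TYPE_DROP_TERMS: frozenset[str] = frozenset(
    {"approximation", "educated guess"}
)

#: Raw sample-fraction text -> harmonized fraction.  Anything unmapped
#: (e.g. "Bed Sediment", missing) is ambiguous and dropped.
DEFAULT_FRACTION_MAP: dict[str, str] = {
    "filtered": "filtered",
    "dissolved": "filtered",
    "filtered, lab": "filtered",
    "filtered, field": "filtered",
    "unfiltered": "unfiltered",
    "total": "unfiltered",
    "total recoverable": "unfiltered",
    "particulate": "particulate",
    "suspended": "particulate",
    "non-filterable": "particulate",
    "inorganic": "inorganic",
    "organic": "organic",
}

#: Organization-name alias table: normalized variant -> canonical name.
DEFAULT_ORG_ALIASES: dict[str, str] = {
    "usgs": "USGS",
    "u.s. geological survey": "USGS",
    "us geological survey": "USGS",
    "united states geological survey": "USGS",
    "epa": "EPA",
    "u.s. environmental protection agency": "EPA",
    "us environmental protection agency": "EPA",
    "environmental protection agency": "EPA",
}

#: Sample-fraction combination rules: (component_a, component_b) -> target,
#: applied per site-date when the target parameter was not itself measured.
DEFAULT_COMBINATION_RULES: tuple[tuple[str, str, str], ...] = (
    ("total nitrogen_filtered", "total nitrogen_particulate", "total nitrogen_unfiltered"),
    ("total phosphorus_filtered", "total phosphorus_particulate", "total phosphorus_unfiltered"),
)


@dataclass
class HarmonizationConfig:
    """All thresholds and registries driving the harmonization pipeline."""

    coord_merge_threshold_m: float = 400.0
    nd_impute_max_share: float = 0.80
    n_imputations: int = 10  # K imputed datasets averaged per censored value
    outlier_lower_pct: float = 1.0
    outlier_upper_pct: float = 99.0
    burn_in: int = 1000
    thin: int = 10
    rng_seed: int = 0
    conversion_table: tuple[ConversionEntry, ...] = DEFAULT_CONVERSION_TABLE
    unit_registry: Mapping[str, Optional[float]] = field(
        default_factory=lambda: dict(DEFAULT_UNIT_REGISTRY)
    )
    nutrient_vocabulary: Mapping[str, NutrientSpec] = field(
        default_factory=lambda: dict(DEFAULT_NUTRIENT_VOCABULARY)
    )
    method_registry: Mapping[str, str] = field(
        default_factory=lambda: dict(DEFAULT_METHOD_REGISTRY)
    )
    nd_code_vocabulary: Mapping[str, str] = field(
        default_factory=lambda: dict(DEFAULT_ND_CODE_VOCABULARY)
    )
    media_whitelist: frozenset[str] = DEFAULT_MEDIA_WHITELIST
    qc_activity_types: frozenset[str] = DEFAULT_QC_ACTIVITY_TYPES
    result_type_drop_terms: frozenset[str] = DEFAULT_RESULT_TYPE_DROP_TERMS
    fraction_map: Mapping[str, str] = field(
        default_factory=lambda: dict(DEFAULT_FRACTION_MAP)
    )
    org_aliases: Mapping[str, str] = field(
        default_factory=lambda: dict(DEFAULT_ORG_ALIASES)
    )
    combination_rules: tuple[tuple[str, str, str], ...] = DEFAULT_COMBINATION_RULES

    def __post_init__(self) -> None:
        if not (0 < self.nd_impute_max_share <= 1):
            raise ConfigError(
                f"nd_impute_max_share must be in (0, 1], got {self.nd_impute_max_share}"
            )
        if self.n_imputations <= 0:
            raise ConfigError(f"n_imputations must be positive, got {self.n_imputations}")
        if not self.outlier_lower_pct < self.outlier_upper_pct:
            raise ConfigError(
                "outlier_lower_pct must be below outlier_upper_pct "
                f"({self.outlier_lower_pct} >= {self.outlier_upper_pct})"
            )
        if self.coord_merge_threshold_m <= 0:
            raise ConfigError(
                f"coord_merge_threshold_m must be positive, got {self.coord_merge_threshold_m}"
            )
        if self.burn_in < 0 or self.thin <= 0:
            raise ConfigError("burn_in must be >= 0 and thin > 0")

    def conversion_factor(self, form: str) -> Optional[float]:
        """Factor for a molecular form code like ``NO3``; None if unlisted."""
        for entry in self.conversion_table:
            if entry.reported_form.upper() == form.upper():
                return entry.factor
        return None


_SCALAR_KEYS = {
    "coord_merge_threshold_m": float,
    "nd_impute_max_share": float,
    "n_imputations": int,
    "outlier_lower_pct": float,
    "outlier_upper_pct": float,
    "burn_in": int,
    "thin": int,
    "rng_seed": int,
}
_MAPPING_KEYS = {
    "unit_registry",
    "method_registry",
    "nd_code_vocabulary",
    "fraction_map",
    "org_aliases",
}
_SET_KEYS = {"media_whitelist", "qc_activity_types", "result_type_drop_terms"}


def load_config(path: Optional[str] = None) -> HarmonizationConfig:
    """Build a :class:`HarmonizationConfig`, optionally overridden from YAML.

    Unspecified keys keep their defaults.  Mapping-valued keys merge into the
    default registry (an explicit ``null`` value removes an entry); set-valued
    keys replace the default set.
    """
    if path is None:
        return HarmonizationConfig()
    try:
        with open(path, "r", encoding="utf-8") as fh:
            doc = yaml.safe_load(fh)
    except yaml.YAMLError as exc:
        raise ConfigError(f"configuration file does not parse: {exc}") from exc
    if doc is None:
        return HarmonizationConfig()
    if not isinstance(doc, dict):
        raise ConfigError("configuration document must be a mapping")

    kwargs: dict = {}
    for key, value in doc.items():
        if key in _SCALAR_KEYS:
            try:
                kwargs[key] = _SCALAR_KEYS[key](value)
            except (TypeError, ValueError) as exc:
                raise ConfigError(f"key {key!r}: not a {_SCALAR_KEYS[key].__name__}") from exc
        elif key in _MAPPING_KEYS:
            if not isinstance(value, dict):
                raise ConfigError(f"key {key!r}: expected a mapping")
            merged = dict(getattr(HarmonizationConfig(), key))
            for k, v in value.items():
                nk = normalize_text(str(k))
                if v is None and key != "unit_registry":
                    merged.pop(nk, None)
                else:
                    merged[nk] = v
            kwargs[key] = merged
        elif key in _SET_KEYS:
            if not isinstance(value, (list, tuple)):
                raise ConfigError(f"key {key!r}: expected a list")
            kwargs[key] = frozenset(normalize_text(str(v)) for v in value)
        elif key == "conversion_table":
            entries = []
            try:
                for row in value:
                    entries.append(
                        ConversionEntry(
                            str(row["nutrient"]),
                            str(row["reported_form"]),
                            float(row["factor"]),
                            str(row["target_form"]),
                        )
                    )
            except (TypeError, KeyError, ValueError) as exc:
                raise ConfigError(f"key 'conversion_table': {exc}") from exc
            kwargs[key] = tuple(entries)
        elif key == "combination_rules":
            try:
                kwargs[key] = tuple((str(a), str(b), str(t)) for a, b, t in value)
            except (TypeError, ValueError) as exc:
                raise ConfigError(f"key 'combination_rules': {exc}") from exc
        else:
            raise ConfigError(f"unknown configuration key {key!r}")
    try:
        return HarmonizationConfig(**kwargs)
    except ConfigError:
        raise
    except (TypeError, ValueError) as exc:
        raise ConfigError(str(exc)) from exc


def config_to_dict(config: HarmonizationConfig) -> dict:
    """Plain-dict view of the active configuration (for ``--dump-registries``)."""
    out = dataclasses.asdict(config)
    out["conversion_table"] = [dataclasses.asdict(e) for e in config.conversion_table]
    for k in _SET_KEYS:
        out[k] = sorted(getattr(config, k))
    return out
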