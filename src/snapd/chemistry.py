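"""Chemical-form inference, unit conversion and nutrient renaming.

A raw nutrient result can report either the mass of the nutrient element
alone ("as N", "as P") or the mass of the whole compound ("as NO3",
"as NH3", ...).  The two differ by a fixed mass ratio, so harmonization
requires (1) inferring which form a record reports, (2) converting molecular
reports to the elemental basis, and (3) converting whatever concentration
unit was used to mg/L.  Records whose form cannot be inferred from name,
units or analytical method are uninterpretable and dropped upstream.
"""

from __future__ import annotations

import re
from typing import Optional, Union

from .config import (
    HARMONIZED_NUTRIENT_NAMES,
    HarmonizationConfig,
    NutrientSpec,
    normalize_handle,
    normalize_text,
)

__all__ = [
    "UNCONVERTIBLE",
    "infer_chemical_form",
    "convert_to_elemental",
    "convert_units",
    "harmonize_nutrient_name",
    "lookup_nutrient",
]

#: Sentinel returned by :func:`convert_units` for units with no mg/L meaning.
UNCONVERTIBLE = object()

_FORM_IN_TEXT = re.compile(r"\bas\s+(n|p|no3|nh3|nh4|po4)\b")


def lookup_nutrient(handle: str, config: HarmonizationConfig) -> Optional[NutrientSpec]:
    """Resolve a raw nutrient name against the vocabulary; None if unlisted."""
    return config.nutrient_vocabulary.get(normalize_handle(handle))


def _form_from_text(text: str) -> Optional[str]:
    m = _FORM_IN_TEXT.search(normalize_handle(text))
    if m is None:
        return None
    token = m.group(1)
    if token in ("n", "p"):
        return "elemental"
    return f"molecular:{token.upper()}"


def infer_chemical_form(
    handle: str,
    units: Optional[str],
    method: Optional[str],
    config: HarmonizationConfig,
) -> str:
    """Infer how a record reports its concentration.

    Returns ``"elemental"``, ``"molecular:<FORM>"`` or ``"unknown"``.
    Precedence: (1) the nutrient name itself ("Nitrate as N" is elemental,
    "Ammonia as NH3" is molecular); (2) an ``as N`` / ``as NO3`` qualifier in
    the concentration units; (3) the analytical-method registry (a method
    like 4500-NO3-E reports mg/L as N).  Otherwise unknown.
    """
    spec = lookup_nutrient(handle, config)
    if spec is not None and spec.form_status != "unknown":
        return spec.form_status
    name_form = _form_from_text(handle)
    if name_form is not None:
        return name_form
    if units is not None:
        unit_form = _form_from_text(units)
        if unit_form is not None:
            return unit_form
    if method is not None:
        reg = config.method_registry.get(normalize_text(method))
        if reg is not None:
            return reg
    return "unknown"


def convert_to_elemental(
    conc: float, form: str, config: HarmonizationConfig
) -> Union[float, object]:
    """Convert a concentration on a molecular basis to the elemental basis.

    ``form`` is ``"elemental"`` (identity) or ``"molecular:<FORM>"``; an
    unlisted molecular form returns :data:`UNCONVERTIBLE`, which upstream
    turns into a chem_form_unknown drop.
    """
    if form == "elemental":
        return conc
    if form.startswith("molecular:"):
        factor = config.conversion_factor(form.split(":", 1)[1])
        if factor is None:
            return UNCONVERTIBLE
        return conc * factor
    return UNCONVERTIBLE


def convert_units(
    conc: float, units: Optional[str], config: HarmonizationConfig
) -> Union[float, object]:
    """Rescale a concentration to mg/L, or :data:`UNCONVERTIBLE`.

    The registry maps normalized unit text to a multiplicative factor
    (``ug/l`` -> 1e-3) or to None for units that carry no mass-per-volume
    meaning (``% recovery``, ``cm3/g``, counts, ...).  Unknown or missing
    units are unconvertible.  Molar units (umol/l) are deliberately routed to
    unconvertible: the conversion would need the molar mass of an often
    unknown chemical form.
    """
    if units is None:
        return UNCONVERTIBLE
    factor = config.unit_registry.get(normalize_text(units))
    if factor is None:
        return UNCONVERTIBLE
    return conc * factor


def harmonize_nutrient_name(spec: NutrientSpec, fraction: str) -> dict[str, str]:
    """Build the harmonized parameter fields for a record.

    Returns ``nutrient_name``, ``sample_fraction``, ``N_or_P`` and the
    underscore-joined ``nutrient_parameter`` (e.g. ``ammonia_filtered``)
    that defines the comparability class of the observation.
    """
    name = spec.harmonized_name.lower()
    if name not in HARMONIZED_NUTRIENT_NAMES:
        raise ValueError(f"unknown harmonized nutrient name: {spec.harmonized_name!r}")
    if fraction not in ("filtered", "unfiltered", "inorganic", "organic", "particulate"):
        raise ValueError(f"unknown sample fraction: {fraction!r}")
    return {
        "nutrient_name": name,
        "sample_fraction": fraction,
        "N_or_P": spec.N_or_P,
        "nutrient_parameter": f"{name}_{fraction}",
    }
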