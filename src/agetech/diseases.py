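"""Canonical chronic-disease identifiers.

The Australian National Health Survey tabulates multimorbidity among people
aged 65+ over eight chronic conditions. Every module in this package refers
to them by these short ids, in this fixed order.
"""

from __future__ import annotations

DISEASES: tuple[str, ...] = (
    "arthritis",
    "asthma",
    "back",
    "cancer",
    "copd",
    "diabetes",
    "cvd",
    "mental",
)

DISEASE_NAMES: dict[str, str] = {
    "arthritis": "Arthritis",
    "asthma": "Asthma",
    "back": "Back problems (dorsopathies)",
    "cancer": "Cancer (malignant neoplasms)",
    "copd": "Chronic obstructive pulmonary disease (COPD)",
    "diabetes": "Diabetes mellitus",
    "cvd": "Diseases of the circulatory system (CVD)",
    "mental": "Mental and behavioural problems",
}


def check_disease(disease: str) -> str:
    """Validate a disease id, returning it unchanged."""
    if disease not in DISEASES:
        raise ValueError(
            f"unknown disease id {disease!r}; expected one of {', '.join(DISEASES)}"
        )
    return disease


def canonical_combination(diseases) -> tuple[str, ...]:
    """Canonicalize a disease subset: validated, de-duplicated, fixed order."""
    seen = set()
    for d in diseases:
        check_disease(d)
        seen.add(d)
    return tuple(d for d in DISEASES if d in seen)
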