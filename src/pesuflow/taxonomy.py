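"""Shared vocabulary for the ED/PESU patient-flow model.

Visit *categories* follow the ICD-10 grouping used for mental-health-and-
addiction (MHA) surveillance: all non-MHA visits form one class (``NMHA``)
and MHA visits split into substance abuse, schizophrenia, mood, anxiety and
a residual "others" group.  Because the simulation differentiates arrival
streams at the substance-subgroup level, the engine works with ten *patient
classes*: NMHA, the five substance subgroups, and the four non-substance
MHA categories.
"""

from __future__ import annotations

#: ICD-derived visit categories.
CATEGORIES = ("NMHA", "substance", "schizophrenia", "mood", "anxiety", "others")

#: Substance-abuse subgroups ("other" covers F13-F18 plus F55).
SUBSTANCE_SUBGROUPS = ("alcohol", "opioid", "cannabis", "multiple", "other")

#: Arrival streams simulated independently.
PATIENT_CLASSES = (
    "NMHA",
    "alcohol",
    "opioid",
    "cannabis",
    "multiple",
    "other",
    "schizophrenia",
    "mood",
    "anxiety",
    "others",
)

#: MHA patient classes (everything except NMHA).
MHA_CLASSES = PATIENT_CLASSES[1:]

#: Discharge dispositions, in the fixed order used by proportion vectors.
DISPOSITIONS = (
    "discharged",
    "admitted",
    "internal_transfer",
    "external_transfer",
    "left_or_death",
)

#: Canadian Triage and Acuity Scale levels (1 = most critical).
CTAS_LEVELS = (1, 2, 3, 4, 5)

#: Fiscal-year labels covered by the historical extract; label Y spans
#: April 1st of calendar year Y to March 31st of Y+1.
FISCAL_YEARS = ("2012", "2013", "2014", "2015", "2016")

#: Fiscal years are modeled as exactly one replication year.
HOURS_PER_YEAR = 8760.0

#: Column order of a visit-history table.
VISIT_COLUMNS = (
    "arrival_time",
    "fiscal_year",
    "icd_code",
    "category",
    "substance_subgroup",
    "ctas",
    "disposition",
    "los_hours",
)


def patient_class_of(category: str, substance_subgroup: str = "none") -> str:
    """Map a (category, subgroup) pair onto the simulated patient class."""
    if category == "substance":
        if substance_subgroup not in SUBSTANCE_SUBGROUPS:
            raise ValueError(
                f"substance visits need a subgroup, got {substance_subgroup!r}"
            )
        return substance_subgroup
    if substance_subgroup != "none":
        raise ValueError(f"{category!r} visits cannot carry a substance subgroup")
    return category


def category_of(patient_class: str) -> tuple[str, str]:
    """Inverse of :func:`patient_class_of`: class -> (category, subgroup)."""
    if patient_class in SUBSTANCE_SUBGROUPS:
        return "substance", patient_class
    if patient_class in CATEGORIES:
        return patient_class, "none"
    raise ValueError(f"unknown patient class {patient_class!r}")
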