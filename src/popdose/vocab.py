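"""Controlled vocabularies: imaging modalities, CT anatomical regions, facility strata.

The modality labels are the row labels of the national survey's contribution
table; the CT region labels are the rows of its CT frequency/dose table. Both
sets are closed: code maps and dose tables must draw from them.
"""
from __future__ import annotations

RADIOGRAPHY = "Conventional radiography"
DIAGNOSTIC_MAMMOGRAPHY = "Diagnostic mammography"
SCREENING_MAMMOGRAPHY = "Screening mammography"
DENTAL = "Dental radiography (without CBCT)"
CBCT = "CBCT"
CT = "CT"
RADIOSCOPY = "Conventional radioscopy"
CORONARY_ANGIOPLASTY = "Coronary angioplasty (CA)"
OTHER_DIAGNOSTIC_IR = "Other diagnostic interventional radiological procedures"
PTCA = "Percutaneous transluminal coronary angioplasty (PTCA)"
OTHER_THERAPEUTIC_IR = "Other therapeutic interventional radiological procedures"
NUCLEAR_MEDICINE = "Nuclear medicine"

MODALITIES: tuple[str, ...] = (
    RADIOGRAPHY,
    DIAGNOSTIC_MAMMOGRAPHY,
    SCREENING_MAMMOGRAPHY,
    DENTAL,
    CBCT,
    CT,
    RADIOSCOPY,
    CORONARY_ANGIOPLASTY,
    OTHER_DIAGNOSTIC_IR,
    PTCA,
    OTHER_THERAPEUTIC_IR,
    NUCLEAR_MEDICINE,
)

#: Dental imaging pooled for frequency-share reporting (plain dental + CBCT).
DENTAL_MODALITIES: tuple[str, ...] = (DENTAL, CBCT)

CHEST_ABDOMEN = "chest and abdomen"

CT_REGIONS: tuple[str, ...] = (
    "head",
    "face/sinus",
    "dental",
    "neck",
    "chest",
    "abdomen",
    CHEST_ABDOMEN,
    "pelvis",
    "spine",
    "shoulder",
    "elbow",
    "wrist/hand",
    "hip",
    "knee",
    "ankle/foot",
)

#: Placeholder region for modalities where the analysis does not resolve anatomy.
UNSPECIFIED_REGION = "unspecified"

FACILITY_STRATA: tuple[str, ...] = ("university", "regional", "private")

UNIVERSITY = "university"
NONUNIVERSITY = "nonuniversity"
#: Dose records are stratified into two practice groups only.
DOSE_STRATA: tuple[str, ...] = (UNIVERSITY, NONUNIVERSITY)

TOTAL = "Total"
TOTAL_WITHOUT_NM = "Total X-ray medical imaging without nuclear medicine"
TOTAL_WITH_NM = "Total X-ray medical imaging with nuclear medicine"


def dose_stratum(facility_stratum: str) -> str:
    """Collapse a facility stratum to the two-level dose-practice stratum."""
    return UNIVERSITY if facility_stratum == UNIVERSITY else NONUNIVERSITY
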