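"""Published summary demographics of the reference glioma cohort.

The reference cohort comprises 151 right-handed participants: four glioma
subgroups defined by tumour location — left frontal (LFG, n=27), left
temporal (LTG, n=26), right frontal (RFG, n=29), right temporal (RTG,
n=27) — and 42 healthy controls (HC).  Only group-level summaries (counts
and mean ± SD cells) are available; the raw data are not public.  These
summaries drive the summary-statistics ANOVA and chi-square routines and
serve as fixed validation inputs for them.
"""

from __future__ import annotations

from .stats import ContingencyTable, GroupSummary

__all__ = [
    "GROUP_LABELS",
    "PATIENT_GROUPS",
    "GROUP_SIZES",
    "GROUP_TO_SUBSYSTEM",
    "GENDER_COUNTS",
    "PATHOLOGY_TYPE_COUNTS",
    "PATHOLOGY_GRADE_COUNTS",
    "EDUCATION_YEARS",
    "TUMOR_VOLUME_CM3",
    "AGE_YEARS",
]

GROUP_LABELS: tuple[str, ...] = ("LFG", "LTG", "RFG", "RTG", "HC")
PATIENT_GROUPS: tuple[str, ...] = ("LFG", "LTG", "RFG", "RTG")

GROUP_SIZES: dict[str, int] = {"LFG": 27, "LTG": 26, "RFG": 29, "RTG": 27, "HC": 42}

GROUP_TO_SUBSYSTEM: dict[str, str] = {
    "LFG": "LF",
    "LTG": "LT",
    "RFG": "RF",
    "RTG": "RT",
}

# males / females per group (rows follow GROUP_LABELS)
GENDER_COUNTS = ContingencyTable(
    [[15, 12], [10, 16], [15, 14], [18, 9], [24, 18]],
    row_labels=GROUP_LABELS,
    col_labels=("male", "female"),
)

# histological type per patient group: low-grade glioma, anaplastic
# astrocytoma/oligodendroglioma, glioblastoma
PATHOLOGY_TYPE_COUNTS = ContingencyTable(
    [[15, 7, 5], [13, 8, 5], [15, 5, 9], [12, 4, 11]],
    row_labels=PATIENT_GROUPS,
    col_labels=("low_grade", "anaplastic", "glioblastoma"),
)

# WHO grade split per patient group: I/II vs III/IV
PATHOLOGY_GRADE_COUNTS = ContingencyTable(
    [[15, 12], [13, 13], [15, 14], [12, 15]],
    row_labels=PATIENT_GROUPS,
    col_labels=("WHO_I_II", "WHO_III_IV"),
)

EDUCATION_YEARS = GroupSummary(
    means=(11.37, 13.12, 12.61, 11.93, 13.71),
    sds=(3.58, 3.99, 3.78, 4.70, 3.79),
    sizes=(27, 26, 29, 27, 42),
    labels=GROUP_LABELS,
)

# patient groups only (controls have no tumour)
TUMOR_VOLUME_CM3 = GroupSummary(
    means=(106.6, 85.58, 110.7, 98.16),
    sds=(64.60, 44.69, 67.60, 66.77),
    sizes=(27, 26, 29, 27),
    labels=PATIENT_GROUPS,
)

AGE_YEARS = GroupSummary(
    means=(45.04, 42.35, 40.76, 43.44, 39.55),
    sds=(12.82, 11.53, 12.68, 13.93, 9.96),
    sizes=(27, 26, 29, 27, 42),
    labels=GROUP_LABELS,
)
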