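"""Feature schema for the multi-feature Parkinson's disease cohort.

The participant-level table is organized as prefixed columns
``"<category>__<name>"`` with five candidate categories (demographic,
clinical, physical_lifestyle, mocap, wearable) plus a ``meta`` category
for bookkeeping columns (e.g. education years, used only for MoCA
adjustment) that never enter the candidate feature pool.

The candidate pool counts are fixed by design:

* demographic            5 columns (sex, age, height, weight, BMI)
* clinical              21 columns (incl. the MoCA total score, which is
                          excluded again from all modelling as a direct
                          cognitive measure)
* physical_lifestyle    10 columns
* mocap                 38 columns (6 spatiotemporal parameters for each
                          of the 6 walking/turning conditions, plus the
                          two contralateral coordination indices for
                          forward walking)
* wearable             360 columns (6 placements x 6 conditions x 10
                          sensor features)

for a total candidate pool of 434 variables.
"""

from __future__ import annotations

from typing import Iterable

# IMU placements: more/less affected upper arm, more/less affected ankle,
# 10th thoracic vertebra, lumbar (posterior superior iliac spine midpoint).
PLACEMENTS: tuple[str, ...] = ("MELB", "LELB", "MANK", "LANK", "T10", "PSIS")

# Walking tasks: forward, backward, and 360-degree turns at preferred (PS)
# or fast (FS) speed toward the inner (IMA) or outer (OMA) step of the
# more affected side.
TASKS: tuple[str, ...] = (
    "FW",
    "BW",
    "TurnPS_IMA",
    "TurnPS_OMA",
    "TurnFS_IMA",
    "TurnFS_OMA",
)

TURN_TASKS: tuple[str, ...] = tuple(t for t in TASKS if t.startswith("Turn"))

# The ten wearable-sensor features computed per (placement, task).
WEARABLE_FEATURES: tuple[str, ...] = (
    "MaxJerk",
    "MaxAngJerk",
    "MeanAcc",
    "MaxAcc",
    "RMSAcc",
    "MeanGyr",
    "MaxGyr",
    "RMSGyr",
    "SampEnAcc",
    "SampEnGyr",
)

# Spatiotemporal parameters reported per condition: walking speed, stride
# length of the more (SLM) / less (SLL) affected side, single-support
# percentage per side, double-support percentage.
MOCAP_FEATURES: tuple[str, ...] = ("Speed", "SLM", "SLL", "SSM", "SSL", "DS")

# Contralateral temporal coordination (elbow vs. contralateral knee peak
# timing, % cycle), computed for forward walking only.
MOCAP_COORD_FEATURES: tuple[str, ...] = ("CoordMALA", "CoordLAMA")

DEMOGRAPHIC_COLUMNS: tuple[str, ...] = (
    "demographic__sex",
    "demographic__age",
    "demographic__height",
    "demographic__weight",
    "demographic__bmi",
)

CLINICAL_COLUMNS: tuple[str, ...] = (
    "clinical__moca",
    "clinical__hoehn_yahr",
    "clinical__updrs_total",
    "clinical__updrs_i",
    "clinical__updrs_ii",
    "clinical__updrs_iii",
    "clinical__updrs_iv",
    "clinical__symptom_duration",
    "clinical__treatment_duration",
    "clinical__ledd",
    "clinical__bdi",
    "clinical__bai",
    "clinical__pdss2",
    "clinical__ess",
    "clinical__fss",
    "clinical__fall_history",
    "clinical__fes",
    "clinical__see",
    "clinical__nfogq",
    "clinical__nmss",
    "clinical__pdq39",
)

PHYSICAL_LIFESTYLE_COLUMNS: tuple[str, ...] = (
    "physical_lifestyle__grip_strength",
    "physical_lifestyle__ftsts",
    "physical_lifestyle__six_mwt",
    "physical_lifestyle__sppb",
    "physical_lifestyle__mini_best",
    "physical_lifestyle__nq",
    "physical_lifestyle__sf36_total",
    "physical_lifestyle__sf36_physical",
    "physical_lifestyle__sf36_mental",
    "physical_lifestyle__ipaq",
)

# Direct cognitive test scores, excluded from every screening, regression
# and classification step (the outcome is carried separately).
COGNITIVE_COLUMNS: tuple[str, ...] = ("clinical__moca",)

EDUCATION_COLUMN = "meta__education_years"


def mocap_columns() -> list[str]:
    cols = [f"mocap__{task}_{feat}" for task in TASKS for feat in MOCAP_FEATURES]
    cols += [f"mocap__FW_{feat}" for feat in MOCAP_COORD_FEATURES]
    return cols


def wearable_columns() -> list[str]:
    return [
        f"wearable__{task}_{placement}_{feat}"
        for task in TASKS
        for placement in PLACEMENTS
        for feat in WEARABLE_FEATURES
    ]


def candidate_columns() -> list[str]:
    """All 434 columns of the candidate feature pool, in canonical order."""
    return (
        list(DEMOGRAPHIC_COLUMNS)
        + list(CLINICAL_COLUMNS)
        + list(PHYSICAL_LIFESTYLE_COLUMNS)
        + mocap_columns()
        + wearable_columns()
    )


def category_of(column: str) -> str:
    """Category tag encoded in a prefixed column name."""
    prefix, _, _ = column.partition("__")
    return prefix


def columns_in(columns: Iterable[str], categories: Iterable[str]) -> list[str]:
    cats = set(categories)
    return [c for c in columns if category_of(c) in cats]


def block_counts(columns: Iterable[str]) -> dict[str, int]:
    counts: dict[str, int] = {}
    for c in columns:
        counts[category_of(c)] = counts.get(category_of(c), 0) + 1
    return counts


# Column sets for the three classification configurations.  Physical
# function and lifestyle measures sit with the clinical block: the
# balance battery (Mini-BEST) is a clinical-style instrument rather than
# a sensor-derived gait measure.
CONFIGURATION_CATEGORIES: dict[str, tuple[str, ...]] = {
    "clinical_only": ("demographic", "clinical", "physical_lifestyle"),
    "gait_only": ("mocap", "wearable"),
    "combined": ("demographic", "clinical", "physical_lifestyle", "mocap", "wearable"),
}
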