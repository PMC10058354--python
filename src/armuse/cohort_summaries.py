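"""Reference per-subject outcome tables for a 15-person demonstration cohort.

These are the per-subject outcomes of a wrist-sensor functional-use study of
ten unimpaired adults (non-dominant arm) and five upper-limb prosthesis
users (prosthetic side): minutes spent on each activity group, the
annotation-derived percentage of time in functional use, classifier
accuracies under both segmentation schemes and both protocols, and the
functional-use percentages each classifier predicted.  They feed the
summary-statistics demonstrations and the reproduction script; all cohort
medians, ranges and group tests are recomputed from these raw per-subject
values, never stored.
"""

from __future__ import annotations

import pandas as pd

#: Minutes per activity group (laundry, kitchen, shopping, making the bed),
#: minutes of non-purposeful movement, and annotated functional-use %.
ACTIVITY_TIMES = pd.DataFrame(
    [
        ("C01", "control", 5, 7, 5, 3, 13, 61.46),
        ("C02", "control", 5, 6, 7, 4, 11, 55.53),
        ("C03", "control", 5, 6, 5, 4, 9, 69.84),
        ("C04", "control", 6, 5, 4, 3, 10, 67.92),
        ("C05", "control", 7, 6, 4, 2, 10, 63.59),
        ("C06", "control", 11, 5, 6, 3, 12, 70.98),
        ("C07", "control", 8, 5, 3, 4, 19, 57.30),
        ("C08", "control", 5, 5, 3, 4, 14, 67.49),
        ("C09", "control", 6, 4, 2, 4, 13, 57.11),
        ("C10", "control", 6, 5, 4, 4, 15, 58.45),
        ("A11", "amputee", 8, 7, 4, 7, 11, 61.23),
        ("A12", "amputee", 7, 6, 4, 5, 8, 70.78),
        ("A13", "amputee", 14, 6, 5, 4, 16, 63.50),
        ("A14", "amputee", 6, 6, 4, 4, 11, 58.33),
        ("A15", "amputee", 11, 8, 5, 10, 13, 74.94),
    ],
    columns=["subject_id", "group", "laundry_min", "kitchen_min",
             "shopping_min", "bed_min", "nonfunctional_min", "fu_percent"],
)

#: Classifier accuracy (%) for the five prosthesis users, per segmentation
#: scheme (fixed 800-sample vs variable) and protocol (intra 10-fold vs LOSO).
AMPUTEE_ACCURACY = pd.DataFrame(
    [
        ("A11", 85.84, 50.06, 61.36, 54.22),
        ("A12", 83.73, 67.57, 72.75, 66.90),
        ("A13", 82.70, 79.88, 69.75, 79.17),
        ("A14", 82.17, 69.90, 63.65, 71.60),
        ("A15", 79.31, 90.84, 71.13, 80.21),
    ],
    columns=["subject_id", "intra_fixed", "intra_variable",
             "inter_fixed", "inter_variable"],
)

#: Functional-use % for the prosthesis users: annotation ground truth and the
#: value each classifier configuration predicted.
AMPUTEE_FU = pd.DataFrame(
    [
        ("A11", 61.23, 78.98, 86.96, 58.37, 60.87),
        ("A12", 70.78, 60.76, 65.66, 75.11, 72.15),
        ("A13", 63.50, 57.11, 51.02, 64.79, 66.67),
        ("A14", 58.33, 52.45, 60.23, 54.52, 64.77),
        ("A15", 74.94, 73.08, 71.67, 78.82, 72.41),
    ],
    columns=["subject_id", "ground_truth", "intra_fixed", "intra_variable",
             "inter_fixed", "inter_variable"],
)


def activity_minutes(group: str) -> pd.Series:
    """Total functional-activity minutes per subject of one group."""
    rows = ACTIVITY_TIMES[ACTIVITY_TIMES["group"] == group]
    return (rows[["laundry_min", "kitchen_min", "shopping_min", "bed_min"]]
            .sum(axis=1))


def fu_percent(group: str) -> pd.Series:
    rows = ACTIVITY_TIMES[ACTIVITY_TIMES["group"] == group]
    return rows["fu_percent"]
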