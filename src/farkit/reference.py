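"""Published margin-level counts of the multicentre feasibility cohort.

The clinical study assessed 385 margins in 66 patients on both FAR and
histopathology and reported confusion matrices for the overall cohort and
for subgroups split by decay-corrected activity (97 MBq) and invasive
tumour grade.  Those counts — which are the inputs to every diagnostic-
accuracy computation here — are recorded below, together with a synthetic
expansion into a margin-level table whose subgroup tabulations reproduce
every published matrix exactly.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .margins import MARGIN_NAMES
from .stats import ConfusionMatrix

__all__ = [
    "OVERALL",
    "HIGH_ACTIVITY",
    "LOW_ACTIVITY",
    "GRADE",
    "N_MARGINS",
    "reference_margin_table",
]

#: whole-population confusion matrix (tp, fp, fn, tn), 385 margins
OVERALL = ConfusionMatrix(tp=6, fp=68, fn=7, tn=304)
#: decay-corrected activity >= 97 MBq cohort, 181 margins
HIGH_ACTIVITY = ConfusionMatrix(tp=5, fp=49, fn=2, tn=125)
#: decay-corrected activity < 97 MBq cohort, 204 margins
LOW_ACTIVITY = ConfusionMatrix(tp=1, fp=19, fn=5, tn=179)
#: invasive tumour grade subgroups (grade 3 had no positive margins)
GRADE = {
    "1": ConfusionMatrix(tp=3, fp=18, fn=1, tn=110),
    "2": ConfusionMatrix(tp=3, fp=33, fn=6, tn=99),
    "3": ConfusionMatrix(tp=0, fp=15, fn=0, tn=79),
}

N_MARGINS = OVERALL.total

# Joint (cell, activity-cohort, grade) allocation.  Only the marginal counts
# above were published; this particular joint is a synthetic but feasible
# assignment (cells sum to every published matrix).  Grade "unknown" absorbs
# the margins of the four ungraded patients.
_JOINT = [
    # (histo, far, cohort, grade, count)
    ("positive", "positive", "high", "1", 3),
    ("positive", "positive", "high", "2", 2),
    ("positive", "positive", "low", "2", 1),
    ("positive", "negative", "high", "1", 1),
    ("positive", "negative", "high", "2", 1),
    ("positive", "negative", "low", "2", 5),
    ("negative", "positive", "high", "1", 18),
    ("negative", "positive", "high", "2", 31),
    ("negative", "positive", "low", "2", 2),
    ("negative", "positive", "low", "3", 15),
    ("negative", "positive", "low", "unknown", 2),
    ("negative", "negative", "high", "1", 60),
    ("negative", "negative", "high", "2", 40),
    ("negative", "negative", "high", "3", 20),
    ("negative", "negative", "high", "unknown", 5),
    ("negative", "negative", "low", "1", 50),
    ("negative", "negative", "low", "2", 59),
    ("negative", "negative", "low", "3", 59),
    ("negative", "negative", "low", "unknown", 11),
]


def reference_margin_table() -> pd.DataFrame:
    """A 385-row margin-level table reproducing the published matrices.

    Columns: patient_id, margin, activity_cohort (high/low at the 97 MBq
    decay-corrected threshold), grade, site_rule, invasive_mm, dcis_mm,
    histo_status, far_status.  Patient ids and the joint cohort-by-grade
    allocation are synthetic plumbing; tabulating ``histo_status`` vs
    ``far_status`` overall, by ``activity_cohort`` or by ``grade``
    reproduces each published confusion matrix exactly.
    """
    rows = []
    for histo, far, cohort, grade, count in _JOINT:
        for _ in range(count):
            rows.append(
                {
                    "activity_cohort": cohort,
                    "grade": grade,
                    "histo_status": histo,
                    "far_status": far,
                    "site_rule": "site12",
                    "invasive_mm": 0.0 if histo == "positive" else 5.0,
                    "dcis_mm": np.nan,
                }
            )
    df = pd.DataFrame(rows)
    # synthetic patients: six margins per patient within (cohort, grade) strata
    df = df.sort_values(["activity_cohort", "grade"], kind="stable").reset_index(drop=True)
    ids, margins = [], []
    for (_, _), grp in df.groupby(["activity_cohort", "grade"], sort=True):
        for j, idx in enumerate(grp.index):
            ids.append(j // 6)
            margins.append(MARGIN_NAMES[j % 6])
    prefix = df["activity_cohort"].str[0] + df["grade"].str[0]
    df["patient_id"] = [f"{p}{i:03d}" for p, i in zip(prefix, ids)]
    df["margin"] = margins
    cols = [
        "patient_id",
        "margin",
        "activity_cohort",
        "grade",
        "site_rule",
        "invasive_mm",
        "dcis_mm",
        "histo_status",
        "far_status",
    ]
    return df[cols]
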