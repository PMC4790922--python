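"""Published baseline characteristics of the WHIMS-MRI cohort.

Demographic, lifestyle and clinical counts by treatment assignment for the
two hormone-therapy trials nested in the WHIMS-MRI study (conjugated equine
estrogens alone, CEE-Alone, n = 254 active / 256 placebo; CEE plus
medroxyprogesterone acetate, CEE+MPA, n = 420 active / 435 placebo).  These
counts are the inputs to the balance statistics: a Pearson chi-square
homogeneity test per variable, p reported in percent.  The pooled
"HT vs Placebo" comparison sums the two trials' arms.

Some variables have complete-case totals below the arm sizes (missing
values excluded pairwise).
"""

from __future__ import annotations

import numpy as np

from .cohort_stats import ContingencyTable

__all__ = ["whims_table1", "whims_comparison_table"]

# rows: categories; columns: CEE-Alone active, CEE-Alone placebo,
#                            CEE+MPA active, CEE+MPA placebo
_TABLE1 = {
    "age": (
        ["65-69 y", "70-74 y", "75+ y"],
        [[123, 128, 220, 225],
         [93, 89, 147, 150],
         [38, 39, 53, 60]],
    ),
    "ethnicity": (
        ["Black/African American", "White, non-Hispanic", "Other"],
        [[13, 16, 17, 15],
         [222, 232, 392, 399],
         [17, 7, 11, 22]],
    ),
    "education": (
        ["<High school", "High school/GED", ">High school, <4 y college",
         ">4 y college"],
        [[16, 8, 15, 21],
         [69, 69, 84, 95],
         [94, 115, 174, 161],
         [75, 64, 146, 156]],
    ),
    "smoking": (
        ["Never", "Former", "Current"],
        [[147, 142, 248, 247],
         [95, 98, 152, 168],
         [9, 15, 18, 15]],
    ),
    "bmi": (
        ["<25", "25-29", "30-34", ">=35"],
        [[59, 63, 134, 153],
         [98, 107, 157, 151],
         [60, 55, 89, 86],
         [35, 30, 39, 44]],
    ),
    "hypertension": (
        ["None", "Current/controlled", "Current/uncontrolled"],
        [[120, 134, 227, 234],
         [51, 53, 53, 45],
         [83, 69, 140, 156]],
    ),
    "prior_cvd": (
        ["No", "History of stroke", "History of other CVD"],
        [[233, 233, 399, 414],
         [3, 4, 1, 5],
         [18, 19, 20, 16]],
    ),
    "diabetes": (
        ["No", "Yes"],
        [[238, 235, 405, 414],
         [16, 21, 15, 21]],
    ),
    "prior_ht": (
        ["No", "Yes"],
        [[129, 124, 328, 335],
         [125, 132, 92, 100]],
    ),
    "three_ms": (
        ["<90", "90-94", "95-100"],
        [[20, 19, 20, 17],
         [50, 57, 63, 77],
         [182, 178, 336, 335]],
    ),
}

_COLS = {"cee_alone": (0, 1), "cee_mpa": (2, 3)}


def whims_table1() -> dict:
    """Raw four-column counts per variable (both trials' arms)."""
    return {
        var: ContingencyTable(
            row_labels=list(rows),
            col_labels=["cee_alone", "cee_alone_placebo", "cee_mpa", "cee_mpa_placebo"],
            counts=np.array(counts),
        )
        for var, (rows, counts) in _TABLE1.items()
    }


def whims_comparison_table(variable: str, comparison: str) -> ContingencyTable:
    """Two-column table for one comparison: cee_alone, cee_mpa or ht (pooled)."""
    rows, counts = _TABLE1[variable]
    counts = np.array(counts)
    if comparison in _COLS:
        a, b = _COLS[comparison]
        two = counts[:, [a, b]]
    elif comparison == "ht":
        two = np.stack([counts[:, 0] + counts[:, 2], counts[:, 1] + counts[:, 3]], axis=1)
    else:
        raise ValueError(f"unknown comparison {comparison!r}")
    return ContingencyTable(
        row_labels=list(rows), col_labels=["active", "placebo"], counts=two
    )
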