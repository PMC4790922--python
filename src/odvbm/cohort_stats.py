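"""Baseline-characteristics balance statistics and site-dispersion diagnostics.

Randomized trial reports tabulate categorical demographics per arm together
with a homogeneity p-value per variable; this module reproduces that table
convention (Pearson chi-square without continuity correction, p reported in
percent) and the multi-site dispersion diagnostics (IQR, mean absolute
deviation, range, sample SD of per-site means) used to show that nuisance
correction removes site effects.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ContingencyTable",
    "ChiSquareResult",
    "DispersionStats",
    "chi_square_homogeneity",
    "characteristics_report",
    "site_dispersion",
]


@dataclass
class ContingencyTable:
    """Counts of a categorical variable cross-tabulated by trial arm."""

    row_labels: list
    col_labels: list
    counts: np.ndarray

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.ndim != 2:
            raise ValueError("counts must be a 2D array")
        if self.counts.shape != (len(self.row_labels), len(self.col_labels)):
            raise ValueError("counts shape must match labels")
        if np.any(self.counts < 0):
            raise ValueError("counts must be >= 0")


@dataclass
class ChiSquareResult:
    statistic: float
    df: int
    p: float

    @property
    def p_percent(self) -> float:
        return 100.0 * self.p


@dataclass
class DispersionStats:
    """Dispersion of per-site sample means; all in the input's units."""

    iqr: float
    mad: float
    range: float
    std: float

    def as_dict(self):
        return {"iqr": self.iqr, "mad": self.mad, "range": self.range, "std": self.std}


def chi_square_homogeneity(table: ContingencyTable) -> ChiSquareResult:
    """Pearson chi-square test of homogeneity, no continuity correction.

    Expected counts are ``row_total * col_total / grand_total``; the p-value
    is the upper tail of the chi-square distribution with (r-1)(c-1) degrees
    of freedom.  Raises if any row or column total is zero (expected counts
    undefined).
    """
    counts = table.counts
    if counts.shape[0] < 2 or counts.shape[1] < 2:
        raise ValueError("need at least 2 rows and 2 columns")
    row_tot = counts.sum(axis=1)
    col_tot = counts.sum(axis=0)
    if np.any(row_tot == 0) or np.any(col_tot == 0):
        raise ValueError("zero row or column total: expected counts undefined")
    grand = counts.sum()
    expected = np.outer(row_tot, col_tot) / grand
    statistic = float(((counts - expected) ** 2 / expected).sum())
    df = (counts.shape[0] - 1) * (counts.shape[1] - 1)
    p = float(stats.chi2.sf(statistic, df))
    return ChiSquareResult(statistic=statistic, df=df, p=p)


def _crosstab(values: pd.Series, groups: pd.Series) -> ContingencyTable:
    ok = values.notna()
    ct = pd.crosstab(values[ok], groups[ok])
    return ContingencyTable(
        row_labels=[str(r) for r in ct.index],
        col_labels=[str(c) for c in ct.columns],
        counts=ct.to_numpy(),
    )


def characteristics_report(frame: pd.DataFrame, variables, group_col: str = "group"):
    """Balance table: per-variable counts, column percentages and p (percent).

    Parameters
    ----------
    frame : DataFrame
        One row per subject; ``group_col`` holds the arm; missing values in a
        variable are excluded pairwise (per-variable complete-case totals).
    variables : list of str
        Categorical column names to tabulate.

    Returns
    -------
    DataFrame with columns variable, category, count per arm, pct per arm and
    p_percent (NaN = not applicable for single-category variables).
    """
    arms = sorted(frame[group_col].unique())
    if len(arms) != 2:
        raise ValueError("exactly two arms required")
    rows = []
    for var in variables:
        if var not in frame.columns or frame[var].notna().sum() == 0:
            raise ValueError(f"variable {var!r} absent for every subject")
        table = _crosstab(frame[var], frame[group_col])
        if len(table.row_labels) < 2:
            p_pct = np.nan  # degenerate single-category variable: not applicable
        else:
            p_pct = chi_square_homogeneity(table).p_percent
        col_tot = table.counts.sum(axis=0)
        for r, cat in enumerate(table.row_labels):
            rows.append(
                {
                    "variable": var,
                    "category": cat,
                    "count_arm1": int(table.counts[r, 0]),
                    "pct_arm1": 100.0 * table.counts[r, 0] / col_tot[0],
                    "count_arm2": int(table.counts[r, 1]),
                    "pct_arm2": 100.0 * table.counts[r, 1] / col_tot[1],
                    "p_percent": p_pct,
                }
            )
    return pd.DataFrame(rows)


def site_dispersion(values, sites) -> DispersionStats:
    """Dispersion of per-site means of a per-subject scalar.

    Computes the sample mean of ``values`` within each site, then the
    interquartile range (linear-interpolation quantiles), mean absolute
    deviation about the mean, range, and sample standard deviation (ddof=1)
    across those site means.
    """
    values = np.asarray(values, dtype=float)
    sites = np.asarray(sites)
    uniq = np.unique(sites)
    if len(uniq) < 2:
        raise ValueError("need >= 2 distinct sites")
    means = np.array([values[sites == s].mean() for s in uniq])
    q75, q25 = np.percentile(means, [75, 25])
    return DispersionStats(
        iqr=float(q75 - q25),
        mad=float(np.abs(means - means.mean()).mean()),
        range=float(means.max() - means.min()),
        std=float(means.std(ddof=1)),
    )
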