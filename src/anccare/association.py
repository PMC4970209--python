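"""Cross-tabulations and Pearson chi-squared screening.

Every bivariate association in the analysis is a plain Pearson
chi-squared test on an r x c contingency table (no Yates continuity
correction, no exact tests).  Each test carries a validity flag per the
Cochran rule: the approximation is flagged unreliable when more than 20%
of the expected counts fall below 5 or any expected count falls below 1.

Rows with a missing value in either variable are excluded per test
(complete-case), with the excluded count logged on the table.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ContingencyTable",
    "contingency",
    "chi_square",
    "chi_square_counts",
    "crosstab_report",
    "format_p",
]


@dataclass
class ContingencyTable:
    row_var: str
    col_var: str
    row_labels: list
    col_labels: list
    observed: np.ndarray
    n_dropped_missing: int = 0
    expected: np.ndarray | None = None
    chi2: float | None = None
    df: int | None = None
    p: float | None = None
    valid: bool | None = None
    note: str = ""

    @property
    def n(self) -> int:
        return int(self.observed.sum())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.observed, index=self.row_labels,
                            columns=self.col_labels)


def contingency(
    data: pd.DataFrame, row_var: str, col_var: str
) -> ContingencyTable:
    """Observed-count cross-tabulation of two categorical columns.

    Complete-case: rows missing either variable are dropped and counted.
    A variable with fewer than two observed levels cannot be tested and
    raises.
    """
    for v in (row_var, col_var):
        if v not in data.columns:
            raise ValueError(f"column {v!r} not in data")
    sub = data[[row_var, col_var]]
    complete = sub.dropna()
    if complete.empty:
        raise ValueError(f"no complete cases for {row_var} x {col_var}")
    tab = pd.crosstab(complete[row_var], complete[col_var])
    if tab.shape[0] < 2 or tab.shape[1] < 2:
        raise ValueError(
            f"{row_var} x {col_var}: both variables need >= 2 observed "
            f"levels (got {tab.shape[0]} x {tab.shape[1]})"
        )
    return ContingencyTable(
        row_var=row_var,
        col_var=col_var,
        row_labels=list(tab.index),
        col_labels=list(tab.columns),
        observed=tab.to_numpy(dtype=np.int64),
        n_dropped_missing=len(sub) - len(complete),
    )


def chi_square(table: ContingencyTable) -> ContingencyTable:
    """Complete a table with the Pearson statistic, p-value and validity.

    Statistic: sum over cells of (O - E)^2 / E with E from the product of
    the margins; p from the chi-squared survival function at
    (r-1)(c-1) degrees of freedom.  No continuity correction.
    """
    obs = table.observed
    row_sums = obs.sum(axis=1)
    col_sums = obs.sum(axis=0)
    if (row_sums == 0).any() or (col_sums == 0).any():
        bad_rows = [table.row_labels[i] for i in np.flatnonzero(row_sums == 0)]
        bad_cols = [table.col_labels[j] for j in np.flatnonzero(col_sums == 0)]
        raise ValueError(
            f"zero margin in {table.row_var} x {table.col_var}: "
            f"empty levels {bad_rows + bad_cols}"
        )
    chi2, p, df, expected = stats.chi2_contingency(obs, correction=False)
    frac_small = float((expected < 5).mean())
    valid = frac_small <= 0.20 and float(expected.min()) >= 1.0
    note = "" if valid else (
        f"chi-squared approximation unreliable: {frac_small:.0%} of expected "
        f"counts < 5, minimum expected {expected.min():.2f}"
    )
    table.expected = expected
    table.chi2 = float(chi2)
    table.df = int(df)
    table.p = float(p)
    table.valid = valid
    table.note = note
    return table


def chi_square_counts(observed, row_labels=None, col_labels=None) -> ContingencyTable:
    """Run the Pearson test directly on a matrix of observed counts."""
    obs = np.asarray(observed, dtype=np.int64)
    table = ContingencyTable(
        row_var="rows",
        col_var="cols",
        row_labels=row_labels or list(range(obs.shape[0])),
        col_labels=col_labels or list(range(obs.shape[1])),
        observed=obs,
    )
    return chi_square(table)


def format_p(p: float) -> str:
    """Three-decimal p-value with a "<0.001" floor, table style."""
    if p < 0.0005:
        return "<0.001"
    return f"{p:.3f}"


def crosstab_report(
    data: pd.DataFrame,
    variables: Sequence[str],
    outcome: str,
    outcome_order: Sequence | None = None,
) -> pd.DataFrame:
    """Determinant-by-outcome report in the style of the published tables.

    One row per level of each candidate variable: the level's total count
    and its row percentages (one decimal) across the outcome categories,
    with the variable-level chi-squared p-value (three decimals) and a
    validity marker on the variable's first row.
    """
    if outcome_order is None:
        outcome_order = sorted(data[outcome].dropna().unique())
    rows = []
    for var in variables:
        tab = chi_square(contingency(data, var, outcome))
        frame = tab.to_frame().reindex(columns=list(outcome_order), fill_value=0)
        p_str = format_p(tab.p)
        for i, (level, counts) in enumerate(frame.iterrows()):
            total = int(counts.sum())
            row = {
                "variable": var if i == 0 else "",
                "level": level,
                "n": total,
                "p": p_str if i == 0 else "",
                "validity": ("" if tab.valid else "a") if i == 0 else "",
            }
            for cat in outcome_order:
                pct = 100.0 * counts[cat] / total if total else 0.0
                row[f"{cat}"] = f"{int(counts[cat])} ({pct:.1f})"
            rows.append(row)
    cols = ["variable", "level", "n", *list(outcome_order), "p", "validity"]
    return pd.DataFrame(rows, columns=cols)
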