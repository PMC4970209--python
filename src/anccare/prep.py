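"""Pooled-cohort construction: inclusion, hot-deck imputation, matching.

The pooled two-region data set is built in three steps:

1. **Inclusion** — keep adult women (age strictly over 18) residing in an
   urban area (household density of at least 2500 per km²) with a
   low-risk onset of pregnancy.
2. **Hot-deck multiple imputation** of missing household income: each
   non-respondent receives ``m`` independent donor draws (uniform, with
   replacement) from respondents in the same occupation × education cell,
   and the completed value is the mean of the draws (``m`` = 5 by
   default).  Empty donor cells widen to an education-only class and then
   to the full respondent pool, with each widening logged.
3. **Exact 1:1 matching without replacement** of donor-region women to
   treated-region women on binary education and three-band maternal age:
   donors are permuted at random, treated units are processed in input
   order and paired to the first unused donor with identical values on
   all matching variables.  Unmatched treated units are excluded, so the
   matched variables are exactly balanced across regions afterwards.

All functions operate on the ``women.csv`` table dialect (a pandas
DataFrame with the documented columns) and are deterministic given their
seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ImputationSpec",
    "MatchSpec",
    "InclusionLog",
    "apply_inclusion",
    "hot_deck_impute",
    "exact_match",
    "MatchResult",
    "balance_report",
]

ADULT_AGE = 18
URBAN_DENSITY = 2500.0


@dataclass(frozen=True)
class ImputationSpec:
    target: str = "household_income"
    donor_class_vars: tuple[str, ...] = ("occupation", "education")
    m: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.m < 1:
            raise ValueError("number of imputations m must be >= 1")
        if not self.donor_class_vars:
            raise ValueError("donor_class_vars must be non-empty")


@dataclass(frozen=True)
class MatchSpec:
    treated_side: str = "brussels"
    donor_side: str = "dutch_urban"
    match_vars: tuple[str, ...] = ("education", "age_band")
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.match_vars:
            raise ValueError("match_vars must be non-empty")


@dataclass
class InclusionLog:
    n_input: int
    n_excluded_age: int
    n_excluded_density: int
    n_excluded_risk: int
    n_kept: int


def apply_inclusion(women: pd.DataFrame) -> tuple[pd.DataFrame, InclusionLog]:
    """Apply the common eligibility criteria, logging removals per criterion.

    Age is strictly greater than 18 (an 18-year-old is excluded); the
    density threshold is inclusive (exactly 2500 households/km² counts as
    urban); ``low_risk_onset`` must be true.  Exclusion counts are
    attributed in that order.
    """
    required = {"age_years", "urban_density", "low_risk_onset"}
    missing = required - set(women.columns)
    if missing:
        raise ValueError(f"women table is missing columns: {sorted(missing)}")
    adult = women["age_years"] > ADULT_AGE
    urban = women["urban_density"] >= URBAN_DENSITY
    low_risk = women["low_risk_onset"].astype(bool)
    log = InclusionLog(
        n_input=len(women),
        n_excluded_age=int((~adult).sum()),
        n_excluded_density=int((adult & ~urban).sum()),
        n_excluded_risk=int((adult & urban & ~low_risk).sum()),
        n_kept=int((adult & urban & low_risk).sum()),
    )
    return women[adult & urban & low_risk].copy(), log


def hot_deck_impute(
    women: pd.DataFrame, spec: ImputationSpec = ImputationSpec()
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Complete missing incomes by hot-deck multiple imputation.

    Returns the completed table plus an audit log with one row per
    imputed record: the donor class actually used (including any pool
    widening), the ``m`` donor values drawn and the completed mean.
    Observed incomes and every other column are untouched.
    """
    target = spec.target
    if target not in women.columns:
        raise ValueError(f"target column {target!r} not in table")
    for v in spec.donor_class_vars:
        if v not in women.columns:
            raise ValueError(f"donor class variable {v!r} not in table")

    rng = np.random.default_rng(spec.seed)
    observed = women[women[target].notna()]
    out = women.copy()
    audit_rows = []
    for idx, row in women[women[target].isna()].iterrows():
        pool = observed
        used_vars = list(spec.donor_class_vars)
        # widen: full class -> drop leading class vars one by one -> marginal
        while used_vars:
            mask = np.ones(len(observed), dtype=bool)
            for v in used_vars:
                mask &= (observed[v] == row[v]).to_numpy()
            pool = observed[mask]
            if len(pool):
                break
            used_vars = used_vars[1:]
        else:
            pool = observed
        if not len(pool):
            raise ValueError(
                f"no observed {target!r} values anywhere: cannot impute"
            )
        draws = rng.choice(pool[target].to_numpy(), size=spec.m, replace=True)
        completed = float(np.mean(draws))
        out.loc[idx, target] = completed
        audit_rows.append(
            {
                "id": row.get("id", idx),
                "donor_class": " x ".join(used_vars) if used_vars else "(marginal)",
                "widened": len(used_vars) < len(spec.donor_class_vars),
                "n_donors": len(pool),
                "draws": ";".join(f"{d:.2f}" for d in draws),
                "completed": completed,
            }
        )
    audit = pd.DataFrame(
        audit_rows,
        columns=["id", "donor_class", "widened", "n_donors", "draws", "completed"],
    )
    return out, audit


@dataclass
class MatchResult:
    pairs: pd.DataFrame  # columns: treated_id, donor_id, plus match_vars
    matched: pd.DataFrame  # pooled table of matched units from both sides
    unmatched_treated: list


def exact_match(women: pd.DataFrame, spec: MatchSpec = MatchSpec()) -> MatchResult:
    """Exact 1:1 matching without replacement on the matching variables.

    Donor-side rows are permuted with the spec seed; treated rows are
    processed in input order and paired to the first unused donor agreeing
    exactly on all ``match_vars``.  The pooled output contains only
    matched units, so each matching variable has identical per-category
    counts in the two regions.
    """
    if "region" not in women.columns:
        raise ValueError("women table needs a 'region' column")
    for v in spec.match_vars:
        if v not in women.columns:
            raise ValueError(f"match variable {v!r} not in table")
    treated = women[women["region"] == spec.treated_side]
    donors = women[women["region"] == spec.donor_side]
    if treated.empty or donors.empty:
        raise ValueError(
            f"both sides must be non-empty (treated {len(treated)}, "
            f"donors {len(donors)})"
        )
    rng = np.random.default_rng(spec.seed)
    perm = rng.permutation(len(donors))
    donor_queue: dict[tuple, list] = {}
    donor_keys = donors.iloc[perm]
    for pos, (idx, row) in enumerate(donor_keys.iterrows()):
        key = tuple(row[v] for v in spec.match_vars)
        donor_queue.setdefault(key, []).append(idx)

    pairs, unmatched = [], []
    for idx, row in treated.iterrows():
        key = tuple(row[v] for v in spec.match_vars)
        queue = donor_queue.get(key, [])
        if queue:
            donor_idx = queue.pop(0)
            pairs.append(
                {
                    "treated_id": row.get("id", idx),
                    "donor_id": donors.loc[donor_idx].get("id", donor_idx),
                    "_treated_idx": idx,
                    "_donor_idx": donor_idx,
                    **{v: row[v] for v in spec.match_vars},
                }
            )
        else:
            unmatched.append(row.get("id", idx))
    pairs_df = pd.DataFrame(
        pairs,
        columns=["treated_id", "donor_id", "_treated_idx", "_donor_idx",
                 *spec.match_vars],
    )
    keep = list(pairs_df["_treated_idx"]) + list(pairs_df["_donor_idx"])
    matched = women.loc[keep].copy()
    return MatchResult(
        pairs=pairs_df.drop(columns=["_treated_idx", "_donor_idx"]),
        matched=matched,
        unmatched_treated=unmatched,
    )


def balance_report(
    pre: pd.DataFrame,
    post: pd.DataFrame,
    variables: Sequence[str],
    region_col: str = "region",
) -> pd.DataFrame:
    """Per-variable chi-squared comparison across regions, before and after.

    One row per variable with the cross-region chi-squared p-value and
    test-validity flag in the pre and post tables.  Delegates the test to
    the bivariate-association module.
    """
    from .association import contingency, chi_square

    rows = []
    for var in variables:
        entry: dict = {"variable": var}
        for label, df in (("pre", pre), ("post", post)):
            try:
                tab = chi_square(contingency(df, var, region_col))
                entry[f"p_{label}"] = tab.p
                entry[f"valid_{label}"] = tab.valid
            except ValueError:
                entry[f"p_{label}"] = np.nan
                entry[f"valid_{label}"] = False
        rows.append(entry)
    return pd.DataFrame(rows, columns=["variable", "p_pre", "valid_pre",
                                       "p_post", "valid_post"])
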