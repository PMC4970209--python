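"""Continuity-of-care index, equivalised income and categorical recodes.

Continuity of carer is measured by the COC index

    COC = (sum_j n_j**2 - n) / (n * (n - 1))

over ``n`` visits of which ``n_j`` were to provider ``j``: 1 when all
visits are to one provider, 0 when every visit is to a different one.
Providers are compared by exact label equality, with no weighting by
provider type.

Household income is equivalised with the modified OECD scale, dividing
total monthly household income by ``1 + 0.5*x + 0.3*y`` where ``x`` is
the number of adults beyond the first and ``y`` the number of children
under 18.  A literal variant (``x`` = all adults, so a single adult gets
divisor 1.5) is available behind a switch because survey codebooks differ
on this point; the standard scale is the default.
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Sequence

__all__ = [
    "coc_index",
    "coc_category",
    "equivalent_income",
    "income_band",
    "recode_education",
    "IncomeBands",
    "EducationRecode",
    "COC_LOW",
    "COC_HIGH",
    "ISCED_VOCABULARY",
]

COC_LOW = "<50%"
COC_HIGH = ">=50%"

INCOME_BANDS = ("low", "moderate", "high")


def coc_index(providers: Sequence[str] | Iterable[str]) -> float:
    """COC index of a provider sequence; order of visits is irrelevant.

    A single visit makes the formula 0/0; one visit is perfectly
    concentrated, so 1.0 is returned (with a warning, since the index is
    then uninformative).
    """
    counts = Counter(providers)
    n = sum(counts.values())
    if n == 0:
        raise ValueError("empty provider sequence: COC requires >= 1 visit")
    if n == 1:
        warnings.warn(
            "COC for a single visit is undefined (0/0); returning 1.0",
            stacklevel=2,
        )
        return 1.0
    return (sum(c * c for c in counts.values()) - n) / (n * (n - 1))


def coc_category(value: float) -> str:
    """Dichotomise a COC value at the 50% cut-off (0.5 maps to high)."""
    if not 0.0 <= value <= 1.0:
        raise ValueError(f"COC value {value!r} outside [0, 1]")
    return COC_HIGH if value >= 0.5 else COC_LOW


def equivalent_income(
    household_income: float,
    n_adults: int,
    n_children_u18: int,
    *,
    count_first_adult: bool = False,
) -> float:
    """Modified-OECD equivalised monthly income.

    Divides total household income by ``1 + 0.5*x + 0.3*y``.  By default
    ``x`` is the number of adults beyond the first (standard modified-OECD
    scale; a single adult with no children keeps their full income).
    ``count_first_adult=True`` instead puts every adult into ``x``.
    """
    if household_income < 0:
        raise ValueError(f"household income {household_income!r} must be >= 0")
    if n_adults < 1:
        raise ValueError("a household has at least one adult")
    if n_children_u18 < 0:
        raise ValueError("number of children must be >= 0")
    x = n_adults if count_first_adult else n_adults - 1
    return household_income / (1.0 + 0.5 * x + 0.3 * n_children_u18)


@dataclass(frozen=True)
class IncomeBands:
    """Income banding relative to the national median equivalised income.

    ``cut_low`` is the at-risk-of-poverty threshold (fraction of the
    median below which income is "low"); incomes between ``cut_low`` and
    ``cut_high`` times the median (both edges inclusive) are "moderate",
    above that "high".
    """

    national_median: float
    cut_low: float = 0.60
    cut_high: float = 1.20

    def __post_init__(self) -> None:
        if self.national_median <= 0:
            raise ValueError("national median income must be > 0")
        if not 0 < self.cut_low < self.cut_high:
            raise ValueError("need 0 < cut_low < cut_high")


def income_band(eq_income: float, bands: IncomeBands) -> str:
    """Band an equivalised income as low / moderate / high."""
    if eq_income < bands.cut_low * bands.national_median:
        return "low"
    if eq_income <= bands.cut_high * bands.national_median:
        return "moderate"
    return "high"


#: ISCED 2011 levels accepted by :func:`recode_education`.
ISCED_VOCABULARY: dict[int, str] = {
    0: "early childhood",
    1: "primary",
    2: "lower secondary",
    3: "upper secondary",
    4: "post-secondary non-tertiary",
    5: "short-cycle tertiary",
    6: "bachelor",
    7: "master",
    8: "doctoral",
}


@dataclass(frozen=True)
class EducationRecode:
    binary: str  # "up-to-secondary" | "tertiary"
    three_level: str  # "low" | "medium" | "high"


def recode_education(isced_level: int) -> EducationRecode:
    """Collapse an ISCED 2011 level to the analysis categories.

    Three-level grouping: low (ISCED 0-2), medium (3-4), high (5-8).
    The binary collapse used in the tables is up-to-secondary (0-4)
    versus tertiary (5-8).
    """
    if isced_level not in ISCED_VOCABULARY:
        raise ValueError(
            f"unknown ISCED level {isced_level!r}; expected one of "
            + ", ".join(f"{k} ({v})" for k, v in ISCED_VOCABULARY.items())
        )
    three = "low" if isced_level <= 2 else "medium" if isced_level <= 4 else "high"
    binary = "tertiary" if isced_level >= 5 else "up-to-secondary"
    return EducationRecode(binary=binary, three_level=three)
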