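"""Content and Timing of care in Pregnancy (CTP) classifier.

The CTP tool grades a pregnancy's antenatal care trajectory into four
ordered adequacy categories — inadequate < intermediate < sufficient <
appropriate — from three dimensions of the visit diary:

1. initiation: gestational age of the first antenatal visit (first
   trimester or later);
2. quantity: the number of occurrences of each basic intervention
   (ultrasound US, blood-pressure measurement BP, blood screening BS)
   against guideline lower/upper ranges;
3. timing: whether every recommended timing window for each intervention
   contains at least one occurrence.

The numeric guideline ranges are configuration, not constants: national
guidelines differ and the tool is meant to be re-parameterised.  The
shipped :data:`DEFAULT_RANGES` are an illustrative NICE-like schedule
(documented in the package docs), chosen so that all four categories are
reachable; they are not a verbatim transcription of any guideline.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

__all__ = [
    "CTP_CATEGORIES",
    "INTERVENTIONS",
    "Visit",
    "VisitDiary",
    "InterventionRange",
    "GuidelineRanges",
    "CTPResult",
    "DEFAULT_RANGES",
    "initiation_trimester",
    "intervention_counts",
    "timing_ok",
    "classify_ctp",
]

#: Ordered adequacy categories, worst first.
CTP_CATEGORIES: tuple[str, ...] = (
    "inadequate",
    "intermediate",
    "sufficient",
    "appropriate",
)

#: The three basic interventions the tool scores.
INTERVENTIONS: tuple[str, ...] = ("US", "BP", "BS")

#: Upper bound (exclusive) on plausible gestational age, in weeks.
MAX_GESTATION_WEEKS = 45.0


class DiaryError(ValueError):
    """Raised for diaries that cannot be classified (e.g. no visits)."""


class RangesError(ValueError):
    """Raised for invalid guideline-range configurations."""


@dataclass(frozen=True)
class Visit:
    """A single antenatal visit.

    Gestational age is in decimal weeks (day-precision inputs should be
    converted as ``days / 7`` before construction).  An intervention
    occurring more than once at one visit counts once: presence is a flag.
    """

    gestational_age_weeks: float
    provider_id: str = ""
    has_us: bool = False
    has_bp: bool = False
    has_bs: bool = False

    def __post_init__(self) -> None:
        ga = self.gestational_age_weeks
        if not (0.0 <= ga < MAX_GESTATION_WEEKS) or math.isnan(ga):
            raise DiaryError(
                f"gestational age {ga!r} outside [0, {MAX_GESTATION_WEEKS}) weeks"
            )

    def has(self, intervention: str) -> bool:
        return {"US": self.has_us, "BP": self.has_bp, "BS": self.has_bs}[intervention]


@dataclass
class VisitDiary:
    """An ordered record of antenatal visits for one pregnancy."""

    visits: list[Visit] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.visits = sorted(self.visits, key=lambda v: v.gestational_age_weeks)

    def __len__(self) -> int:
        return len(self.visits)

    def __iter__(self):
        return iter(self.visits)

    @property
    def first_visit_weeks(self) -> float:
        if not self.visits:
            raise DiaryError("empty diary: at least one visit is required")
        return self.visits[0].gestational_age_weeks

    @property
    def providers(self) -> list[str]:
        """Provider id of each visit, in gestational order."""
        return [v.provider_id for v in self.visits]


@dataclass(frozen=True)
class InterventionRange:
    """Guideline count range and timing windows for one intervention.

    ``upper`` of ``None`` means unbounded above.  Each window is a
    half-open gestational-age interval ``[start, end)`` in weeks that must
    contain at least one occurrence for the timing to be adequate.
    """

    lower: int
    upper: int | None
    windows: tuple[tuple[float, float], ...] = ()

    def __post_init__(self) -> None:
        if self.lower < 0:
            raise RangesError(f"lower count {self.lower} must be >= 0")
        if self.upper is not None and self.upper < self.lower:
            raise RangesError(
                f"upper count {self.upper} below lower count {self.lower}"
            )
        for start, end in self.windows:
            if not (0.0 <= start < end <= MAX_GESTATION_WEEKS):
                raise RangesError(
                    f"window [{start}, {end}) outside [0, {MAX_GESTATION_WEEKS})"
                )
        if len(self.windows) > self.lower:
            raise RangesError(
                f"{len(self.windows)} timing windows but lower count {self.lower}: "
                "timing adequacy would require more events than the count minimum"
            )


@dataclass(frozen=True)
class GuidelineRanges:
    """Per-intervention guideline ranges plus trimester boundaries."""

    us: InterventionRange
    bp: InterventionRange
    bs: InterventionRange
    t1_boundary_weeks: float = 14.0
    t2_boundary_weeks: float = 28.0

    def __post_init__(self) -> None:
        if not (0.0 < self.t1_boundary_weeks < self.t2_boundary_weeks < MAX_GESTATION_WEEKS):
            raise RangesError(
                "trimester boundaries must satisfy 0 < t1 < t2 < "
                f"{MAX_GESTATION_WEEKS}; got t1={self.t1_boundary_weeks}, "
                f"t2={self.t2_boundary_weeks}"
            )

    def __getitem__(self, intervention: str) -> InterventionRange:
        try:
            return {"US": self.us, "BP": self.bp, "BS": self.bs}[intervention]
        except KeyError:
            raise KeyError(
                f"unknown intervention {intervention!r}; expected one of {INTERVENTIONS}"
            ) from None


#: Illustrative NICE-like default schedule (not guideline-verbatim):
#: two dating/anomaly ultrasounds, blood pressure at every routine visit
#: across all trimesters, first-trimester blood screening.
DEFAULT_RANGES = GuidelineRanges(
    us=InterventionRange(lower=2, upper=3, windows=((10.0, 14.0), (18.0, 24.0))),
    bp=InterventionRange(
        lower=7, upper=12, windows=((0.0, 14.0), (14.0, 28.0), (28.0, 42.0))
    ),
    bs=InterventionRange(lower=1, upper=3, windows=((0.0, 14.0),)),
)


@dataclass(frozen=True)
class CTPResult:
    """Classification outcome with the audit flags that produced it."""

    category: str
    initiation_trimester: int
    counts: dict[str, int]
    below_lower: dict[str, bool]
    above_upper: dict[str, bool]
    timing_ok: dict[str, bool]

    @property
    def category_index(self) -> int:
        """0 = inadequate .. 3 = appropriate."""
        return CTP_CATEGORIES.index(self.category)


def initiation_trimester(diary: VisitDiary, ranges: GuidelineRanges) -> int:
    """Trimester (1, 2 or 3) of the earliest recorded visit.

    The comparison with each boundary is strict: a first visit exactly at
    the first-trimester boundary falls in trimester 2.
    """
    first = diary.first_visit_weeks
    if first < ranges.t1_boundary_weeks:
        return 1
    if first < ranges.t2_boundary_weeks:
        return 2
    return 3


def intervention_counts(diary: VisitDiary) -> dict[str, int]:
    """Number of visits at which each intervention occurred."""
    if not diary.visits:
        raise DiaryError("empty diary: at least one visit is required")
    return {
        i: sum(1 for v in diary.visits if v.has(i)) for i in INTERVENTIONS
    }


def timing_ok(diary: VisitDiary, ranges: GuidelineRanges, intervention: str) -> bool:
    """Whether every timing window for ``intervention`` is covered.

    Coverage semantics: each recommended window must contain at least one
    occurrence; occurrences outside every window are ignored, so adding a
    visit can never turn an adequate timing inadequate.
    """
    times = [
        v.gestational_age_weeks for v in diary.visits if v.has(intervention)
    ]
    return all(
        any(start <= t < end for t in times)
        for start, end in ranges[intervention].windows
    )


def classify_ctp(diary: VisitDiary, ranges: GuidelineRanges) -> CTPResult:
    """Assign the CTP adequacy category for one visit diary.

    Decision table (evaluated in order):

    a. initiation of care after the first trimester — **inadequate**;
    b. else, if the count of at least one intervention is below its lower
       range: **intermediate** when at least one (other) intervention
       exceeded its upper range, **inadequate** when none did;
    c. else (all counts at or above their lower ranges): **sufficient**
       when the timing of at least one intervention is not as recommended,
       **appropriate** when all timings are.

    Interventions with an unbounded upper range never count as exceeding.
    """
    if not diary.visits:
        raise DiaryError("empty diary: at least one visit is required")

    trimester = initiation_trimester(diary, ranges)
    counts = intervention_counts(diary)
    below = {i: counts[i] < ranges[i].lower for i in INTERVENTIONS}
    above = {
        i: ranges[i].upper is not None and counts[i] > ranges[i].upper
        for i in INTERVENTIONS
    }
    timing = {i: timing_ok(diary, ranges, i) for i in INTERVENTIONS}

    if trimester > 1:
        category = "inadequate"
    elif any(below.values()):
        category = "intermediate" if any(above.values()) else "inadequate"
    elif not all(timing.values()):
        category = "sufficient"
    else:
        category = "appropriate"

    return CTPResult(
        category=category,
        initiation_trimester=trimester,
        counts=counts,
        below_lower=below,
        above_upper=above,
        timing_ok=timing,
    )


def classify_many(
    diaries: Iterable[VisitDiary], ranges: GuidelineRanges
) -> list[CTPResult]:
    """Classify a sequence of diaries with one range configuration."""
    return [classify_ctp(d, ranges) for d in diaries]
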