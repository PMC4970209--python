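"""Seedable synthetic two-region antenatal-care cohorts.

Real individual-level data from the two source studies (a Brussels
metropolitan cohort and an urban Dutch midwifery cohort) are not publicly
deposited, so every downstream stage of the pipeline is exercised on
synthetic cohorts that reproduce the statistical structure the analysis
assumes:

* per-region marginal distributions of the predisposing, enabling and
  pregnancy-related characteristics (the shipped defaults read the
  published sample-characteristics table of the pooled data set);
* household income drawn log-normally, then masked missing-at-random
  with probabilities depending on occupation and education (the
  mechanism reported for the Dutch subsample's income non-response);
* one visit diary per woman, constructed to classify to a target CTP
  category drawn from a configurable per-region category mix.

Variables are drawn independently within region except income, whose
missingness depends on occupation and education — the published tables
document only marginals, and this is the simplest structure that
exercises every pipeline stage.  The generator is therefore a test bed,
not a population model: see the package methods note for what passing
tests on it do and do not show about real cohorts.

Cohorts round-trip through two delimited tables: ``women.csv`` (one row
per woman) and ``visits.csv`` (one row per visit, keyed by woman id).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .ctp import (
    CTP_CATEGORIES,
    INTERVENTIONS,
    DEFAULT_RANGES,
    GuidelineRanges,
    Visit,
    VisitDiary,
    classify_ctp,
)

__all__ = [
    "CohortConfig",
    "WomanRecord",
    "ConfigError",
    "UnreachableCategoryError",
    "generate_cohort",
    "generate_diary",
    "inject_missingness",
    "brussels_2008_region",
    "dutch_urban_2009_region",
    "default_config",
    "cohort_to_frames",
    "frames_to_records",
    "write_cohort",
    "WOMEN_COLUMNS",
    "VISIT_COLUMNS",
]


class ConfigError(ValueError):
    """Invalid cohort configuration (e.g. probabilities not summing to 1)."""


class UnreachableCategoryError(ValueError):
    """A target CTP category cannot be produced under the given ranges."""


# --------------------------------------------------------------------------
# configuration

_PROB_TOL = 1e-9

#: Categorical variables drawn directly from per-region marginals.
MARGINAL_VARS = (
    "age_band",
    "marital",
    "education",
    "occupation",
    "nationality",
    "partner_education",
    "partner_nationality",
    "insurance",
    "additional_insurance",
    "parity",
    "wanted",
    "planned",
    "attended_classes",
    "n_adults",
    "n_children_u18",
)


@dataclass(frozen=True)
class IncomeModel:
    """Log-normal monthly household income plus the national median
    equivalised income used for banding (currency units)."""

    mu: float
    sigma: float
    national_median: float


@dataclass
class CohortConfig:
    n_per_region: int
    region_labels: tuple[str, str]
    marginal_probs: dict[str, dict[str, dict[str, float]]]
    income_model: dict[str, IncomeModel]
    missingness_rates: dict[str, dict[tuple[str, str], float]]
    category_mix: dict[str, dict[str, float]]
    ranges: GuidelineRanges = DEFAULT_RANGES
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_per_region < 1:
            raise ConfigError("n_per_region must be >= 1")
        for region in self.region_labels:
            for var, probs in self.marginal_probs[region].items():
                self._check_probs(f"{region}.{var}", probs)
            self._check_probs(f"{region}.category_mix", self.category_mix[region])
            if set(self.category_mix[region]) != set(CTP_CATEGORIES):
                raise ConfigError(
                    f"category_mix for {region} must cover exactly {CTP_CATEGORIES}"
                )
            for cell, rate in self.missingness_rates.get(region, {}).items():
                if not 0.0 <= rate <= 1.0:
                    raise ConfigError(
                        f"missingness rate {rate} for {region}/{cell} outside [0, 1]"
                    )

    @staticmethod
    def _check_probs(name: str, probs: Mapping[str, float]) -> None:
        total = sum(probs.values())
        if any(p < 0 for p in probs.values()) or abs(total - 1.0) > _PROB_TOL:
            raise ConfigError(
                f"probabilities for {name} must be non-negative and sum to 1 "
                f"(got sum {total!r})"
            )


@dataclass
class WomanRecord:
    """One synthetic participant with her visit diary."""

    id: str
    region: str
    age_years: int
    age_band: str
    marital: str
    education: str
    occupation: str
    nationality: str
    partner_education: str
    partner_nationality: str
    household_income: float | None
    n_adults: int
    n_children_u18: int
    insurance: bool
    additional_insurance: bool
    parity: str
    wanted: bool
    planned: bool
    attended_classes: bool
    urban_density: float
    low_risk_onset: bool
    target_category: str
    diary: VisitDiary


# --------------------------------------------------------------------------
# shipped default configurations

AGE_BANDS = ("<=20", "21-35", ">35")


def _shared_household_marginals() -> dict[str, dict[str, float]]:
    # Household composition is not tabulated in the source studies; a small
    # categorical distribution suffices to exercise the OECD scale.
    return {
        "n_adults": {"1": 0.10, "2": 0.85, "3": 0.05},
        "n_children_u18": {"0": 0.45, "1": 0.30, "2": 0.18, "3": 0.07},
    }


def brussels_2008_region() -> dict:
    """Default marginals for the Brussels metropolitan subsample (n=321
    column of the published pooled-sample characteristics table)."""
    marginals = {
        "age_band": {"<=20": 0.012, "21-35": 0.822, ">35": 0.166},
        "marital": {"cohabiting/married": 0.907, "single": 0.093},
        "education": {"up-to-secondary": 0.586, "tertiary": 0.414},
        "occupation": {"employed": 0.464, "unemployed": 0.536},
        "nationality": {"native": 0.573, "other": 0.427},
        "partner_education": {
            "no partner": 0.093,
            "up-to-secondary": 0.508,
            "tertiary": 0.399,
        },
        "partner_nationality": {
            "no partner": 0.093,
            "native": 0.530,
            "other": 0.377,
        },
        "insurance": {"yes": 0.941, "no": 0.059},
        "additional_insurance": {"yes": 0.470, "no": 0.530},
        "parity": {"primiparae": 0.377, "multiparae": 0.623},
        "wanted": {"yes": 0.963, "no": 0.037},
        "planned": {"yes": 0.779, "no": 0.221},
        "attended_classes": {"yes": 0.221, "no": 0.779},
        **_shared_household_marginals(),
    }
    return {
        "marginal_probs": marginals,
        # Wide income spread: 28.7/47.0/24.3 % low/moderate/high bands.
        "income_model": IncomeModel(mu=7.70, sigma=0.75, national_median=1150.0),
        # No income non-response was reported for the Belgian study.
        "missingness_rates": {},
        "category_mix": {
            "inadequate": 31 / 321,
            "intermediate": 26 / 321,
            "sufficient": 118 / 321,
            "appropriate": 146 / 321,
        },
    }


def dutch_urban_2009_region() -> dict:
    """Default marginals for the urban Dutch subsample (n=321 column)."""
    marginals = {
        "age_band": {"<=20": 0.012, "21-35": 0.822, ">35": 0.166},
        "marital": {"cohabiting/married": 0.975, "single": 0.025},
        "education": {"up-to-secondary": 0.586, "tertiary": 0.414},
        "occupation": {"employed": 0.841, "unemployed": 0.159},
        "nationality": {"native": 0.907, "other": 0.093},
        "partner_education": {
            "no partner": 0.025,
            "up-to-secondary": 0.533,
            "tertiary": 0.442,
        },
        "partner_nationality": {
            "no partner": 0.025,
            "native": 0.844,
            "other": 0.131,
        },
        "insurance": {"yes": 1.0, "no": 0.0},
        "additional_insurance": {"yes": 0.872, "no": 0.128},
        "parity": {"primiparae": 0.508, "multiparae": 0.492},
        "wanted": {"yes": 0.997, "no": 0.003},
        "planned": {"yes": 0.816, "no": 0.184},
        "attended_classes": {"yes": 0.520, "no": 0.480},
        **_shared_household_marginals(),
    }
    # Cell rates chosen to average ~15% overall income non-response for
    # this marginal structure, concentrated in unemployed / lower-educated
    # cells (the reported MAR mechanism).
    missing = {
        ("unemployed", "up-to-secondary"): 0.30,
        ("unemployed", "tertiary"): 0.20,
        ("employed", "up-to-secondary"): 0.15,
        ("employed", "tertiary"): 0.08,
    }
    return {
        "marginal_probs": marginals,
        # Narrow income spread: 6.2/93.5/0.3 % low/moderate/high bands.
        "income_model": IncomeModel(mu=7.82, sigma=0.22, national_median=1300.0),
        "missingness_rates": missing,
        "category_mix": {
            "inadequate": 18 / 321,
            "intermediate": 20 / 321,
            "sufficient": 96 / 321,
            "appropriate": 187 / 321,
        },
    }


def default_config(
    n_per_region: int = 321,
    seed: int = 0,
    ranges: GuidelineRanges = DEFAULT_RANGES,
) -> CohortConfig:
    """Two-region default: Brussels 2008 vs urban Dutch 2009 marginals."""
    brussels = brussels_2008_region()
    dutch = dutch_urban_2009_region()
    labels = ("brussels", "dutch_urban")
    return CohortConfig(
        n_per_region=n_per_region,
        region_labels=labels,
        marginal_probs={
            "brussels": brussels["marginal_probs"],
            "dutch_urban": dutch["marginal_probs"],
        },
        income_model={
            "brussels": brussels["income_model"],
            "dutch_urban": dutch["income_model"],
        },
        missingness_rates={
            "brussels": brussels["missingness_rates"],
            "dutch_urban": dutch["missingness_rates"],
        },
        category_mix={
            "brussels": brussels["category_mix"],
            "dutch_urban": dutch["category_mix"],
        },
        ranges=ranges,
        seed=seed,
    )


# --------------------------------------------------------------------------
# diary generation

_MAX_PLACEMENT_WEEK = 44.0  # keep generated ages safely below the 45-week cap
_RETRIES = 32


def _draw(rng: np.random.Generator, probs: Mapping[str, float]) -> str:
    keys = list(probs)
    p = np.asarray([probs[k] for k in keys], dtype=float)
    return keys[rng.choice(len(keys), p=p / p.sum())]


def _uniform_in(rng: np.random.Generator, start: float, end: float) -> float:
    return float(rng.uniform(start, end))


def _uniform_outside(
    rng: np.random.Generator, window: tuple[float, float]
) -> float | None:
    """Uniform draw in [0, _MAX_PLACEMENT_WEEK) excluding ``window``."""
    s, e = window
    segments = [(0.0, min(s, _MAX_PLACEMENT_WEEK)), (min(e, _MAX_PLACEMENT_WEEK), _MAX_PLACEMENT_WEEK)]
    segments = [(a, b) for a, b in segments if b - a > 1e-9]
    if not segments:
        return None
    lengths = np.asarray([b - a for a, b in segments])
    a, b = segments[rng.choice(len(segments), p=lengths / lengths.sum())]
    return _uniform_in(rng, a, b)


def _cover_times(
    rng: np.random.Generator, spec, count: int, skip: int | None = None
) -> list[float] | None:
    """Occurrence times for one intervention.

    Covers every timing window (or all but window ``skip``), then tops up
    to ``count`` total occurrences placed outside the skipped window (or
    anywhere when nothing is skipped).  Returns ``None`` when infeasible.
    """
    times: list[float] = []
    for j, (ws, we) in enumerate(spec.windows):
        if j == skip:
            continue
        if skip is not None:
            # avoid accidentally covering the skipped window when windows overlap
            ss, se = spec.windows[skip]
            pieces = [(ws, min(we, ss)), (max(ws, se), we)]
            pieces = [(a, b) for a, b in pieces if b - a > 1e-9]
            if not pieces:
                return None
            lengths = np.asarray([b - a for a, b in pieces])
            a, b = pieces[rng.choice(len(pieces), p=lengths / lengths.sum())]
            times.append(_uniform_in(rng, a, b))
        else:
            times.append(_uniform_in(rng, ws, min(we, _MAX_PLACEMENT_WEEK)))
    while len(times) < count:
        if skip is not None:
            t = _uniform_outside(rng, spec.windows[skip])
            if t is None:
                return None
        else:
            t = _uniform_in(rng, 0.0, _MAX_PLACEMENT_WEEK)
        times.append(t)
    return times


def _assign_providers(rng: np.random.Generator, n_visits: int) -> list[str]:
    """Provider labels giving a spread of continuity-of-care values."""
    n_prov = int(rng.choice([1, 2, 3, 4], p=[0.30, 0.35, 0.20, 0.15]))
    if n_prov == 1:
        return ["prov1"] * n_visits
    # one dominant provider, the rest sharing the remainder
    dominant = float(rng.uniform(0.3, 0.9))
    weights = [dominant] + [(1 - dominant) / (n_prov - 1)] * (n_prov - 1)
    idx = rng.choice(n_prov, size=n_visits, p=np.asarray(weights) / sum(weights))
    return [f"prov{i + 1}" for i in idx]


def _build_target_times(
    target: str, ranges: GuidelineRanges, rng: np.random.Generator
) -> dict[str, list[float]] | None:
    """Per-intervention occurrence times for one attempt; None to retry."""
    specs = {i: ranges[i] for i in INTERVENTIONS}
    times: dict[str, list[float]] = {i: [] for i in INTERVENTIONS}

    if target == "appropriate":
        for i, spec in specs.items():
            count = spec.lower
            if spec.upper is None or spec.upper > spec.lower:
                count += int(rng.integers(0, 2))  # occasionally one above minimum
            t = _cover_times(rng, spec, count)
            if t is None:
                return None
            times[i] = t
        return times

    if target == "sufficient":
        # one intervention keeps its count but leaves one window uncovered
        candidates = [
            (i, j)
            for i, spec in specs.items()
            for j in range(len(spec.windows))
        ]
        if not candidates:
            raise UnreachableCategoryError(
                "sufficient is unreachable: no intervention has a timing window"
            )
        rng.shuffle(candidates)
        for i, spec in specs.items():
            t = _cover_times(rng, spec, spec.lower)
            if t is None:
                return None
            times[i] = t
        for vi, vj in candidates:
            t = _cover_times(rng, specs[vi], specs[vi].lower, skip=vj)
            if t is not None:
                times[vi] = t
                return times
        return None

    if target == "inadequate":
        # two mechanisms: late initiation, or first-trimester initiation with
        # a count deficit and no excess
        deficit_ok = any(spec.lower >= 1 for spec in specs.values())
        late = (not deficit_ok) or bool(rng.integers(0, 2))
        if late:
            start = ranges.t1_boundary_weeks
            end = min(start + 10.0, _MAX_PLACEMENT_WEEK)
            for i, spec in specs.items():
                times[i] = [
                    _uniform_in(rng, start, end) for _ in range(max(spec.lower, 1))
                ]
            return times
        low_i = rng.choice([i for i, s in specs.items() if s.lower >= 1])
        for i, spec in specs.items():
            count = spec.lower - 1 if i == low_i else spec.lower
            times[i] = [
                _uniform_in(rng, 0.0, _MAX_PLACEMENT_WEEK) for _ in range(count)
            ]
        return times

    if target == "intermediate":
        lows = [i for i, s in specs.items() if s.lower >= 1]
        highs = [i for i, s in specs.items() if s.upper is not None]
        pairs = [(a, b) for a in lows for b in highs if a != b]
        if not pairs:
            raise UnreachableCategoryError(
                "intermediate is unreachable: needs one intervention with a "
                "positive lower range and a different one with a bounded upper range"
            )
        low_i, high_i = pairs[rng.integers(0, len(pairs))]
        for i, spec in specs.items():
            if i == low_i:
                count = spec.lower - 1
            elif i == high_i:
                count = spec.upper + 1
            else:
                count = spec.lower
            times[i] = [
                _uniform_in(rng, 0.0, _MAX_PLACEMENT_WEEK) for _ in range(count)
            ]
        return times

    raise ValueError(f"unknown CTP category {target!r}; expected {CTP_CATEGORIES}")


def generate_diary(
    target_category: str,
    ranges: GuidelineRanges = DEFAULT_RANGES,
    seed: int | np.random.Generator = 0,
) -> VisitDiary:
    """Construct a visit diary that classifies to ``target_category``.

    The construction inverts the CTP decision table and is self-checking:
    every candidate diary is passed through :func:`classify_ctp` with the
    same ranges before it is returned, so the round trip is exact by
    contract.  Targets that no diary can reach under the given ranges
    (e.g. "intermediate" when every lower range is zero) raise
    :class:`UnreachableCategoryError` naming the category.
    """
    if target_category not in CTP_CATEGORIES:
        raise ValueError(
            f"unknown CTP category {target_category!r}; expected {CTP_CATEGORIES}"
        )
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    for _ in range(_RETRIES):
        times = _build_target_times(target_category, ranges, rng)
        if times is None:
            continue
        visits = [
            Visit(
                gestational_age_weeks=round(t, 2),
                has_us=(i == "US"),
                has_bp=(i == "BP"),
                has_bs=(i == "BS"),
            )
            for i, ts in times.items()
            for t in ts
        ]
        # A booking visit (no scored intervention) pins first-trimester
        # initiation.  Inadequate diaries must not get one when the
        # late-initiation mechanism was used, and do need one when the
        # count-deficit mechanism produced no visits at all.
        needs_booking = target_category in (
            "appropriate", "sufficient", "intermediate"
        ) or (target_category == "inadequate" and not visits)
        if needs_booking:
            booking = Visit(
                gestational_age_weeks=round(
                    _uniform_in(rng, 4.0, min(ranges.t1_boundary_weeks, 13.9)), 2
                )
            )
            visits.append(booking)
        if not visits:
            continue
        providers = _assign_providers(rng, len(visits))
        diary = VisitDiary(
            [dataclasses.replace(v, provider_id=p) for v, p in zip(sorted(
                visits, key=lambda v: v.gestational_age_weeks), providers)]
        )
        if classify_ctp(diary, ranges).category == target_category:
            return diary
    raise UnreachableCategoryError(
        f"could not construct a diary classifying to {target_category!r} "
        f"under the given ranges after {_RETRIES} attempts"
    )


# --------------------------------------------------------------------------
# cohort generation

def _draw_age(rng: np.random.Generator, band: str) -> int:
    # inclusion restricts to adults (>18), so the lowest band is 19-20
    if band == "<=20":
        return int(rng.integers(19, 21))
    if band == "21-35":
        return int(rng.integers(21, 36))
    return int(rng.integers(36, 46))


def generate_woman(
    rng: np.random.Generator,
    config: CohortConfig,
    region: str,
    ident: str,
) -> WomanRecord:
    probs = config.marginal_probs[region]
    age_band = _draw(rng, probs["age_band"])
    marital = _draw(rng, probs["marital"])
    if marital == "single":
        partner_edu = partner_nat = "no partner"
    else:
        pe = {k: v for k, v in probs["partner_education"].items() if k != "no partner"}
        pn = {k: v for k, v in probs["partner_nationality"].items() if k != "no partner"}
        partner_edu = _draw(rng, {k: v / sum(pe.values()) for k, v in pe.items()})
        partner_nat = _draw(rng, {k: v / sum(pn.values()) for k, v in pn.items()})
    income_model = config.income_model[region]
    income = float(rng.lognormal(income_model.mu, income_model.sigma))
    target = _draw(rng, config.category_mix[region])
    diary = generate_diary(target, config.ranges, rng)
    return WomanRecord(
        id=ident,
        region=region,
        age_years=_draw_age(rng, age_band),
        age_band=age_band,
        marital=marital,
        education=_draw(rng, probs["education"]),
        occupation=_draw(rng, probs["occupation"]),
        nationality=_draw(rng, probs["nationality"]),
        partner_education=partner_edu,
        partner_nationality=partner_nat,
        household_income=round(income, 2),
        n_adults=int(_draw(rng, probs["n_adults"])),
        n_children_u18=int(_draw(rng, probs["n_children_u18"])),
        insurance=_draw(rng, probs["insurance"]) == "yes",
        additional_insurance=_draw(rng, probs["additional_insurance"]) == "yes",
        parity=_draw(rng, probs["parity"]),
        wanted=_draw(rng, probs["wanted"]) == "yes",
        planned=_draw(rng, probs["planned"]) == "yes",
        attended_classes=_draw(rng, probs["attended_classes"]) == "yes",
        urban_density=round(float(rng.uniform(2500.0, 15000.0)), 1),
        low_risk_onset=True,
        target_category=target,
        diary=diary,
    )


def generate_cohort(config: CohortConfig) -> list[WomanRecord]:
    """Draw ``n_per_region`` records per region; deterministic in the seed.

    Income is drawn for every woman and then masked per the configured
    missingness model (see :func:`inject_missingness`).
    """
    rng = np.random.default_rng(config.seed)
    records = [
        generate_woman(rng, config, region, f"{region}-{i:04d}")
        for region in config.region_labels
        for i in range(config.n_per_region)
    ]
    return inject_missingness(records, config, rng=rng)


def inject_missingness(
    records: Sequence[WomanRecord],
    config: CohortConfig,
    rng: np.random.Generator | None = None,
) -> list[WomanRecord]:
    """Mask household income missing-at-random given occupation x education.

    Every other field is untouched; records whose cell has no configured
    rate keep their income.  Deterministic given the generator state.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed + 1_000_003)
    out = []
    for rec in records:
        rate = config.missingness_rates.get(rec.region, {}).get(
            (rec.occupation, rec.education), 0.0
        )
        if rate > 0.0 and rng.random() < rate:
            rec = dataclasses.replace(rec, household_income=None)
        out.append(rec)
    return out


# --------------------------------------------------------------------------
# delimited-table round trip

#: Column dictionary for ``women.csv``.
WOMEN_COLUMNS = (
    "id", "region", "age_years", "age_band", "marital", "education",
    "occupation", "nationality", "partner_education", "partner_nationality",
    "household_income", "n_adults", "n_children_u18", "insurance",
    "additional_insurance", "parity", "wanted", "planned",
    "attended_classes", "urban_density", "low_risk_onset", "target_category",
)

#: Column dictionary for ``visits.csv``.
VISIT_COLUMNS = (
    "woman_id", "gestational_age_weeks", "provider_id",
    "has_us", "has_bp", "has_bs",
)

_BOOL_WOMEN = ("insurance", "additional_insurance", "wanted", "planned",
               "attended_classes", "low_risk_onset")


def cohort_to_frames(
    records: Iterable[WomanRecord],
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Split records into the ``women`` and ``visits`` tables."""
    women_rows, visit_rows = [], []
    for rec in records:
        row = {c: getattr(rec, c) for c in WOMEN_COLUMNS}
        women_rows.append(row)
        for v in rec.diary:
            visit_rows.append(
                {
                    "woman_id": rec.id,
                    "gestational_age_weeks": v.gestational_age_weeks,
                    "provider_id": v.provider_id,
                    "has_us": v.has_us,
                    "has_bp": v.has_bp,
                    "has_bs": v.has_bs,
                }
            )
    women = pd.DataFrame(women_rows, columns=list(WOMEN_COLUMNS))
    visits = pd.DataFrame(visit_rows, columns=list(VISIT_COLUMNS))
    return women, visits


def frames_to_records(
    women: pd.DataFrame, visits: pd.DataFrame
) -> list[WomanRecord]:
    """Rebuild records from the two tables (inverse of cohort_to_frames)."""
    missing = set(WOMEN_COLUMNS) - set(women.columns)
    if missing:
        raise ValueError(f"women table is missing columns: {sorted(missing)}")
    missing = set(VISIT_COLUMNS) - set(visits.columns)
    if missing:
        raise ValueError(f"visits table is missing columns: {sorted(missing)}")
    by_woman: dict[str, list[Visit]] = {}
    for r in visits.itertuples(index=False):
        by_woman.setdefault(str(r.woman_id), []).append(
            Visit(
                gestational_age_weeks=float(r.gestational_age_weeks),
                provider_id=str(r.provider_id),
                has_us=bool(r.has_us),
                has_bp=bool(r.has_bp),
                has_bs=bool(r.has_bs),
            )
        )
    records = []
    for row in women.itertuples(index=False):
        d = row._asdict()
        income = d["household_income"]
        records.append(
            WomanRecord(
                id=str(d["id"]),
                region=str(d["region"]),
                age_years=int(d["age_years"]),
                age_band=str(d["age_band"]),
                marital=str(d["marital"]),
                education=str(d["education"]),
                occupation=str(d["occupation"]),
                nationality=str(d["nationality"]),
                partner_education=str(d["partner_education"]),
                partner_nationality=str(d["partner_nationality"]),
                household_income=None if pd.isna(income) else float(income),
                n_adults=int(d["n_adults"]),
                n_children_u18=int(d["n_children_u18"]),
                insurance=bool(d["insurance"]),
                additional_insurance=bool(d["additional_insurance"]),
                parity=str(d["parity"]),
                wanted=bool(d["wanted"]),
                planned=bool(d["planned"]),
                attended_classes=bool(d["attended_classes"]),
                urban_density=float(d["urban_density"]),
                low_risk_onset=bool(d["low_risk_onset"]),
                target_category=str(d["target_category"]),
                diary=VisitDiary(by_woman.get(str(d["id"]), [])),
            )
        )
    return records


def write_cohort(records: Iterable[WomanRecord], women_path, visits_path) -> None:
    """Write the two delimited tables (UTF-8, comma, header row)."""
    women, visits = cohort_to_frames(records)
    women.to_csv(women_path, index=False)
    visits.to_csv(visits_path, index=False)
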