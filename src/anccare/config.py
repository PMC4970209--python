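"""Structured run configuration (YAML).

One file governs everything a user must be able to vary: the guideline
ranges behind the CTP classifier, trimester boundary, income banding
cut-offs, cohort size and seed, imputation and matching settings, and the
covariate blocks of the ordinal model.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .ctp import DEFAULT_RANGES, GuidelineRanges, InterventionRange
from .ordinal import ModelSpec
from .prep import ImputationSpec, MatchSpec


class ConfigurationError(ValueError):
    """Missing or malformed run-configuration entries."""


#: Default covariate blocks, following the behavioural-model grouping.
#: Partner education/nationality are screened bivariately but are not
#: model candidates: their "no partner" level coincides exactly with
#: single marital status, so the three variables are jointly aliased.
DEFAULT_BLOCKS: list[tuple[str, list[str]]] = [
    ("predisposing", ["age_band", "marital", "education", "occupation",
                      "nationality"]),
    ("enabling", ["income_band", "insurance", "additional_insurance"]),
    ("pregnancy_related", ["parity", "wanted", "planned", "coc_band",
                           "attended_classes"]),
]

#: Reference levels chosen so that the disadvantaged level carries the
#: odds ratio (mirrors the published table's orientation).
DEFAULT_REFERENCES: dict[str, object] = {
    "age_band": "21-35",
    "marital": "cohabiting/married",
    "education": "tertiary",
    "occupation": "employed",
    "nationality": "native",
    "partner_education": "tertiary",
    "partner_nationality": "native",
    "income_band": "moderate",
    "insurance": True,
    "additional_insurance": True,
    "parity": "primiparae",
    "wanted": True,
    "planned": True,
    "coc_band": ">=50%",
    "attended_classes": True,
    "region": "dutch_urban",
}


@dataclass
class RunConfig:
    seed: int = 0
    n_per_region: int = 321
    ranges: GuidelineRanges = DEFAULT_RANGES
    income_cut_low: float = 0.60
    income_cut_high: float = 1.20
    imputation_m: int = 5
    treated_side: str = "brussels"
    donor_side: str = "dutch_urban"
    match_vars: tuple[str, ...] = ("education", "age_band")
    stay_level: float = 0.05
    blocks: list[tuple[str, list[str]]] = field(
        default_factory=lambda: [(n, list(v)) for n, v in DEFAULT_BLOCKS])
    reference_levels: dict = field(
        default_factory=lambda: dict(DEFAULT_REFERENCES))

    def imputation_spec(self, seed_offset: int = 11) -> ImputationSpec:
        return ImputationSpec(m=self.imputation_m, seed=self.seed + seed_offset)

    def match_spec(self, seed_offset: int = 23) -> MatchSpec:
        return MatchSpec(treated_side=self.treated_side,
                         donor_side=self.donor_side,
                         match_vars=self.match_vars,
                         seed=self.seed + seed_offset)

    def model_spec(self, outcome: str = "ctp_category",
                   outcome_order=None) -> ModelSpec:
        return ModelSpec(outcome=outcome, blocks=self.blocks,
                         fixed=["region"], stay_level=self.stay_level,
                         reference_levels=self.reference_levels,
                         outcome_order=outcome_order)


def _parse_intervention(name: str, raw: dict) -> InterventionRange:
    try:
        return InterventionRange(
            lower=int(raw["lower"]),
            upper=None if raw.get("upper") in (None, "none") else int(raw["upper"]),
            windows=tuple((float(a), float(b)) for a, b in raw.get("windows", [])),
        )
    except (KeyError, TypeError, ValueError) as exc:
        raise ConfigurationError(f"invalid guideline range for {name}: {exc}") from exc


def load_config(path: str | Path) -> RunConfig:
    """Read a YAML run configuration, validating before any compute.

    The guideline ranges are mandatory: a config without a ``ranges``
    section fails immediately with a configuration error.
    """
    raw = yaml.safe_load(Path(path).read_text())
    if not isinstance(raw, dict):
        raise ConfigurationError(f"config {path} is not a mapping")
    if "ranges" not in raw:
        raise ConfigurationError(
            f"config {path} is missing the required 'ranges' section "
            "(guideline count ranges and timing windows per intervention)"
        )
    r = raw["ranges"]
    for key in ("us", "bp", "bs"):
        if key not in r:
            raise ConfigurationError(f"ranges section missing intervention {key!r}")
    ranges = GuidelineRanges(
        us=_parse_intervention("us", r["us"]),
        bp=_parse_intervention("bp", r["bp"]),
        bs=_parse_intervention("bs", r["bs"]),
        t1_boundary_weeks=float(r.get("t1_boundary_weeks", 14.0)),
        t2_boundary_weeks=float(r.get("t2_boundary_weeks", 28.0)),
    )
    cfg = RunConfig(ranges=ranges)
    cfg.seed = int(raw.get("seed", cfg.seed))
    cohort = raw.get("cohort", {})
    cfg.n_per_region = int(cohort.get("n_per_region", cfg.n_per_region))
    bands = raw.get("income_bands", {})
    cfg.income_cut_low = float(bands.get("cut_low", cfg.income_cut_low))
    cfg.income_cut_high = float(bands.get("cut_high", cfg.income_cut_high))
    imp = raw.get("imputation", {})
    cfg.imputation_m = int(imp.get("m", cfg.imputation_m))
    match = raw.get("match", {})
    cfg.treated_side = match.get("treated_side", cfg.treated_side)
    cfg.donor_side = match.get("donor_side", cfg.donor_side)
    cfg.match_vars = tuple(match.get("match_vars", cfg.match_vars))
    model = raw.get("model", {})
    cfg.stay_level = float(model.get("stay_level", cfg.stay_level))
    if "blocks" in model:
        cfg.blocks = [(name, list(vars_)) for name, vars_ in model["blocks"].items()]
    if "reference_levels" in model:
        cfg.reference_levels.update(model["reference_levels"])
    return cfg


def default_config_yaml() -> str:
    """Render the default configuration as a YAML document."""
    rng = DEFAULT_RANGES
    doc = {
        "seed": 0,
        "cohort": {"n_per_region": 321},
        "ranges": {
            "t1_boundary_weeks": rng.t1_boundary_weeks,
            "t2_boundary_weeks": rng.t2_boundary_weeks,
            **{
                k: {
                    "lower": iv.lower,
                    "upper": iv.upper,
                    "windows": [list(w) for w in iv.windows],
                }
                for k, iv in (("us", rng.us), ("bp", rng.bp), ("bs", rng.bs))
            },
        },
        "income_bands": {"cut_low": 0.60, "cut_high": 1.20},
        "imputation": {"m": 5},
        "match": {
            "treated_side": "brussels",
            "donor_side": "dutch_urban",
            "match_vars": ["education", "age_band"],
        },
        "model": {
            "stay_level": 0.05,
            "blocks": {name: vars_ for name, vars_ in DEFAULT_BLOCKS},
        },
    }
    return yaml.safe_dump(doc, sort_keys=False)
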