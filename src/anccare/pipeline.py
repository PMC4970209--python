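"""End-to-end orchestration: synthesise/ingest, derive, classify, prepare,
screen and model, with a reproducibility manifest.

Stage order mirrors the study design: cohort (or ingest) → eligibility →
income imputation → derived indices → CTP classification → exact matching
→ bivariate screening → hierarchical ordinal model.  All artifacts are
UTF-8 comma-delimited tables with a header row; identical seed and config
produce byte-identical artifacts.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .association import chi_square, contingency, crosstab_report, format_p
from .config import RunConfig
from .ctp import CTP_CATEGORIES, classify_ctp
from .indices import IncomeBands, coc_category, coc_index, equivalent_income, income_band
from .ordinal import HierarchicalResult, hierarchical_selection
from .prep import apply_inclusion, exact_match, hot_deck_impute
from .synth import (
    CohortConfig,
    WomanRecord,
    cohort_to_frames,
    default_config,
    frames_to_records,
    generate_cohort,
)

__all__ = ["RunManifest", "run_pipeline", "read_cohort", "derive_columns",
           "classify_cohort", "PipelineError"]


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@dataclass
class RunManifest:
    seed: int
    config_digest: str
    input_digests: dict[str, str] = field(default_factory=dict)
    stage_seconds: dict[str, float] = field(default_factory=dict)
    outputs: list[str] = field(default_factory=list)
    version: str = __version__

    def to_json(self) -> str:
        return json.dumps(self.__dict__, indent=2, sort_keys=True)


def _digest(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def read_cohort(women_path, visits_path) -> list[WomanRecord]:
    """Load a cohort from the documented ``women.csv``/``visits.csv`` dialect.

    Visits referencing an unknown woman id are rejected with an error;
    women without any visit get an empty diary (they fail classification
    later, where the empty diary is reported).
    """
    women = pd.read_csv(women_path)
    visits = pd.read_csv(visits_path)
    known = set(women["id"].astype(str)) if "id" in women.columns else set()
    if "woman_id" in visits.columns:
        orphan = set(visits["woman_id"].astype(str)) - known
        if orphan:
            raise ValueError(
                f"visits reference unknown woman ids: {sorted(orphan)[:5]}"
                f"{' …' if len(orphan) > 5 else ''}"
            )
    return frames_to_records(women, visits)


def classify_cohort(records: list[WomanRecord], ranges) -> pd.DataFrame:
    """Per-woman CTP category with the audit flags, as a table."""
    rows = []
    for rec in records:
        res = classify_ctp(rec.diary, ranges)
        rows.append({
            "id": rec.id,
            "ctp_category": res.category,
            "initiation_trimester": res.initiation_trimester,
            **{f"count_{i.lower()}": res.counts[i] for i in res.counts},
            **{f"below_lower_{i.lower()}": res.below_lower[i] for i in res.below_lower},
            **{f"above_upper_{i.lower()}": res.above_upper[i] for i in res.above_upper},
            **{f"timing_ok_{i.lower()}": res.timing_ok[i] for i in res.timing_ok},
        })
    return pd.DataFrame(rows)


def derive_columns(
    women: pd.DataFrame,
    records: list[WomanRecord],
    cfg: RunConfig,
    cohort_cfg: CohortConfig,
) -> pd.DataFrame:
    """Append COC, COC band, equivalised income and income band columns."""
    by_id = {rec.id: rec for rec in records}
    coc_vals, coc_bands, eq_vals, bands = [], [], [], []
    for _, row in women.iterrows():
        rec = by_id[str(row["id"])]
        c = coc_index(rec.diary.providers) if len(rec.diary) > 1 else 1.0
        coc_vals.append(round(c, 4))
        coc_bands.append(coc_category(c))
        income = row["household_income"]
        if pd.isna(income):
            eq_vals.append(np.nan)
            bands.append(np.nan)
        else:
            eq = equivalent_income(float(income), int(row["n_adults"]),
                                   int(row["n_children_u18"]))
            eq_vals.append(round(eq, 2))
            median = cohort_cfg.income_model[row["region"]].national_median
            bands.append(income_band(eq, IncomeBands(
                median, cfg.income_cut_low, cfg.income_cut_high)))
    out = women.copy()
    out["coc"] = coc_vals
    out["coc_band"] = coc_bands
    out["eq_income"] = eq_vals
    out["income_band"] = bands
    return out


def _table1(women: pd.DataFrame, variables: list[str]) -> pd.DataFrame:
    """Characteristics by region with the cross-region chi-squared p."""
    rows = []
    for var in variables:
        tab = chi_square(contingency(women, var, "region"))
        frame = tab.to_frame()
        for i, (level, counts) in enumerate(frame.iterrows()):
            row = {"variable": var if i == 0 else "", "level": level,
                   "p": format_p(tab.p) if i == 0 else "",
                   "valid": ("" if tab.valid else "a") if i == 0 else ""}
            for col in frame.columns:
                col_total = int(frame[col].sum())
                row[str(col)] = f"{int(counts[col])} ({100.0 * counts[col] / col_total:.1f})"
            rows.append(row)
    return pd.DataFrame(rows)


def run_pipeline(cfg: RunConfig, outdir: str | Path,
                 config_path: str | Path | None = None) -> RunManifest:
    """Run every stage on a synthesised two-region cohort.

    Writes the cohort tables, the three report tables (characteristics,
    determinants, regional comparison), the model report and the run
    manifest under ``outdir`` and returns the manifest.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(
        seed=cfg.seed,
        config_digest=(_digest(Path(config_path)) if config_path else "(defaults)"),
    )
    t_all = time.perf_counter()

    def stage(name):
        class _Timer:
            def __enter__(self):
                self.t0 = time.perf_counter()

            def __exit__(self, exc_type, exc, tb):
                manifest.stage_seconds[name] = round(
                    time.perf_counter() - self.t0, 3)
                if exc is not None:
                    raise PipelineError(f"stage {name!r} failed: {exc}") from exc
        return _Timer()

    def emit(frame: pd.DataFrame, name: str):
        path = outdir / name
        frame.to_csv(path, index=False)
        manifest.outputs.append(name)

    with stage("synth"):
        cohort_cfg = default_config(n_per_region=cfg.n_per_region,
                                    seed=cfg.seed, ranges=cfg.ranges)
        records = generate_cohort(cohort_cfg)
        women, visits = cohort_to_frames(records)
        emit(women, "women.csv")
        emit(visits, "visits.csv")

    with stage("inclusion"):
        women, incl_log = apply_inclusion(women)

    with stage("impute"):
        women, audit = hot_deck_impute(women, cfg.imputation_spec())
        emit(audit, "impute_audit.csv")

    with stage("indices"):
        women = derive_columns(women, records, cfg, cohort_cfg)

    with stage("classify"):
        classified = classify_cohort(
            [r for r in records if r.id in set(women["id"])], cfg.ranges)
        women = women.merge(classified[["id", "ctp_category"]], on="id")
        emit(classified, "classified.csv")

    with stage("match"):
        result = exact_match(women, cfg.match_spec())
        emit(result.pairs, "match_pairs.csv")
        pd.DataFrame({"unmatched_treated": result.unmatched_treated}).to_csv(
            outdir / "unmatched.csv", index=False)
        manifest.outputs.append("unmatched.csv")
        pooled = result.matched.reset_index(drop=True)
        emit(pooled, "pooled.csv")

    screen_vars = [
        "age_band", "marital", "education", "occupation", "nationality",
        "partner_education", "partner_nationality", "income_band",
        "insurance", "additional_insurance", "parity", "wanted", "planned",
        "coc_band", "attended_classes",
    ]
    with stage("screen"):
        emit(_table1(pooled, screen_vars), "table1.csv")
        emit(
            crosstab_report(pooled, screen_vars, "ctp_category",
                            outcome_order=list(CTP_CATEGORIES)),
            "table2.csv",
        )
        t3 = chi_square(contingency(pooled, "ctp_category", "region"))
        frame3 = t3.to_frame()
        frame3.insert(0, "category", frame3.index)
        frame3["p"] = [format_p(t3.p)] + [""] * (len(frame3) - 1)
        emit(frame3.reset_index(drop=True), "table3.csv")

    with stage("model"):
        pooled_model = pooled.copy()
        pooled_model["ctp_category"] = pd.Categorical(
            pooled_model["ctp_category"], categories=list(CTP_CATEGORIES),
            ordered=True)
        selection = hierarchical_selection(
            pooled_model, cfg.model_spec(outcome_order=list(CTP_CATEGORIES)))
        emit(selection.report(), "model_steps.csv")
        final = selection.final_fit
        or_table = final.odds_ratios.round(4)
        or_table.insert(0, "term", or_table.index)
        emit(or_table.reset_index(drop=True), "model_or.csv")
        conc = selection.concordance
        summary = pd.DataFrame([{
            "selected": ", ".join(selection.selected) or "(region only)",
            "loglik": round(final.loglik, 4),
            "pct_concordant": (round(conc.pct_concordant, 2)
                               if conc.pct_concordant is not None else ""),
            "pct_tied": (round(conc.pct_tied, 2)
                         if conc.pct_tied is not None else ""),
        }])
        emit(summary, "model_summary.csv")

    manifest.stage_seconds["total"] = round(time.perf_counter() - t_all, 3)
    for name in list(manifest.outputs):
        manifest.input_digests[name] = _digest(outdir / name)
    (outdir / "manifest.json").write_text(manifest.to_json())
    return manifest
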