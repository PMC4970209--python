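"""Inclusion filters, hot-deck imputation and exact matching."""

import numpy as np
import pandas as pd
import pytest

from anccare.prep import (
    ImputationSpec,
    MatchSpec,
    apply_inclusion,
    balance_report,
    exact_match,
    hot_deck_impute,
)


def women_frame(rows):
    return pd.DataFrame(rows)


class TestInclusion:
    BASE = dict(urban_density=3000.0, low_risk_onset=True)

    def test_age_threshold_strict(self):
        df = women_frame([
            dict(id="a", age_years=18, **self.BASE),
            dict(id="b", age_years=19, **self.BASE),
        ])
        kept, log = apply_inclusion(df)
        assert list(kept["id"]) == ["b"]
        assert log.n_excluded_age == 1

    def test_density_threshold_inclusive(self):
        df = women_frame([
            dict(id="a", age_years=30, urban_density=2500.0, low_risk_onset=True),
            dict(id="b", age_years=30, urban_density=2499.9, low_risk_onset=True),
        ])
        kept, log = apply_inclusion(df)
        assert list(kept["id"]) == ["a"]
        assert log.n_excluded_density == 1

    def test_high_risk_excluded_and_counts_logged(self):
        df = women_frame([
            dict(id="a", age_years=30, urban_density=9000.0, low_risk_onset=False),
            dict(id="b", age_years=30, **self.BASE),
        ])
        kept, log = apply_inclusion(df)
        assert list(kept["id"]) == ["b"]
        assert (log.n_input, log.n_excluded_risk, log.n_kept) == (2, 1, 1)

    def test_all_eligible_passthrough(self):
        df = women_frame([dict(id=i, age_years=25, **self.BASE) for i in range(5)])
        kept, log = apply_inclusion(df)
        pd.testing.assert_frame_equal(kept, df)
        assert log.n_kept == 5

    def test_missing_column_rejected(self):
        with pytest.raises(ValueError, match="low_risk_onset"):
            apply_inclusion(women_frame([dict(id="a", age_years=30,
                                              urban_density=3000.0)]))


def impute_frame(missing_income=(), incomes=None):
    incomes = incomes or {}
    rows = []
    grid = [("employed", "tertiary"), ("employed", "up-to-secondary"),
            ("unemployed", "tertiary"), ("unemployed", "up-to-secondary")]
    i = 0
    for occ, edu in grid:
        for _ in range(3):
            ident = f"w{i}"
            rows.append(dict(
                id=ident, occupation=occ, education=edu,
                household_income=(np.nan if ident in missing_income
                                  else incomes.get((occ, edu), 1500.0)),
            ))
            i += 1
    return pd.DataFrame(rows)


class TestHotDeck:
    def test_no_missing_is_identity(self):
        df = impute_frame()
        out, audit = hot_deck_impute(df, ImputationSpec(seed=1))
        pd.testing.assert_frame_equal(out, df)
        assert audit.empty

    def test_single_donor_cell_gives_exact_value(self):
        df = pd.DataFrame([
            dict(id="m", occupation="employed", education="tertiary",
                 household_income=np.nan),
            dict(id="d", occupation="employed", education="tertiary",
                 household_income=2000.0),
            dict(id="x", occupation="unemployed", education="tertiary",
                 household_income=900.0),
        ])
        out, audit = hot_deck_impute(df, ImputationSpec(seed=5))
        assert out.loc[out["id"] == "m", "household_income"].item() == 2000.0
        assert audit.loc[0, "donor_class"] == "occupation x education"

    def test_mean_of_m_draws_converges(self):
        """Donor cell {1000, 2000}: with m=200 the completed value sits
        within 3 standard errors of 1500."""
        df = pd.DataFrame([
            dict(id="m", occupation="e", education="t", household_income=np.nan),
            dict(id="a", occupation="e", education="t", household_income=1000.0),
            dict(id="b", occupation="e", education="t", household_income=2000.0),
        ])
        out, _ = hot_deck_impute(df, ImputationSpec(m=200, seed=9))
        completed = out.loc[out["id"] == "m", "household_income"].item()
        se = 500.0 / np.sqrt(200)
        assert abs(completed - 1500.0) < 3 * se

    def test_completed_values_confined_to_donor_pool_range(self):
        rng = np.random.default_rng(3)
        df = impute_frame(
            missing_income={"w0", "w3", "w6", "w9"},
            incomes={k: float(rng.uniform(800, 4000)) for k in
                     [("employed", "tertiary"), ("employed", "up-to-secondary"),
                      ("unemployed", "tertiary"), ("unemployed", "up-to-secondary")]},
        )
        observed = df["household_income"].dropna()
        out, audit = hot_deck_impute(df, ImputationSpec(seed=2))
        filled = out.loc[df["household_income"].isna(), "household_income"]
        assert filled.between(observed.min() - 1e-9, observed.max() + 1e-9).all()
        # observed rows untouched
        pd.testing.assert_frame_equal(
            out[df["household_income"].notna()],
            df[df["household_income"].notna()],
        )

    def test_empty_cell_widens_with_audit_flag(self):
        df = pd.DataFrame([
            dict(id="m", occupation="unemployed", education="tertiary",
                 household_income=np.nan),
            dict(id="d", occupation="employed", education="tertiary",
                 household_income=1800.0),
        ])
        out, audit = hot_deck_impute(df, ImputationSpec(seed=4))
        assert out["household_income"].notna().all()
        assert bool(audit.loc[0, "widened"])
        assert audit.loc[0, "donor_class"] == "education"

    def test_seed_reproducible(self):
        df = impute_frame(missing_income={"w1", "w4"})
        a, _ = hot_deck_impute(df, ImputationSpec(seed=8))
        b, _ = hot_deck_impute(df, ImputationSpec(seed=8))
        pd.testing.assert_frame_equal(a, b)


def match_frame(treated, donors):
    rows = []
    for i, (edu, age) in enumerate(treated):
        rows.append(dict(id=f"t{i}", region="brussels", education=edu,
                         age_band=age))
    for i, (edu, age) in enumerate(donors):
        rows.append(dict(id=f"d{i}", region="dutch_urban", education=edu,
                         age_band=age))
    return pd.DataFrame(rows)


class TestExactMatch:
    def test_superset_donor_pool_matches_everyone(self):
        treated = [("low", "21-35"), ("high", ">35"), ("low", "<=20")]
        df = match_frame(treated, treated + treated)
        res = exact_match(df, MatchSpec(seed=0))
        assert len(res.pairs) == 3
        assert res.unmatched_treated == []

    def test_absent_combination_goes_unmatched_and_excluded(self):
        df = match_frame([("low", "21-35"), ("high", ">35")],
                         [("low", "21-35")])
        res = exact_match(df, MatchSpec(seed=0))
        assert res.unmatched_treated == ["t1"]
        assert set(res.matched["id"]) == {"t0", "d0"}

    def test_post_match_exact_balance(self):
        rng = np.random.default_rng(0)
        edus = rng.choice(["low", "high"], 80)
        ages = rng.choice(["<=20", "21-35", ">35"], 80, p=[0.1, 0.7, 0.2])
        treated = list(zip(edus, ages))
        donors = list(zip(rng.choice(["low", "high"], 200),
                          rng.choice(["<=20", "21-35", ">35"], 200)))
        res = exact_match(match_frame(treated, donors), MatchSpec(seed=1))
        tab = pd.crosstab(
            [res.matched["education"], res.matched["age_band"]],
            res.matched["region"],
        )
        assert (tab["brussels"] == tab["dutch_urban"]).all()

    def test_no_donor_used_twice(self):
        df = match_frame([("low", "21-35")] * 5, [("low", "21-35")] * 3)
        res = exact_match(df, MatchSpec(seed=2))
        assert len(res.pairs) == 3
        assert res.pairs["donor_id"].is_unique
        assert len(res.unmatched_treated) == 2

    def test_depends_only_on_seed(self):
        df = match_frame([("low", "21-35")] * 4 + [("high", ">35")] * 2,
                         [("low", "21-35")] * 6 + [("high", ">35")] * 4)
        a = exact_match(df, MatchSpec(seed=9))
        b = exact_match(df, MatchSpec(seed=9))
        pd.testing.assert_frame_equal(a.pairs, b.pairs)

    def test_empty_side_rejected(self):
        df = match_frame([("low", "21-35")], [])
        with pytest.raises(ValueError):
            exact_match(df, MatchSpec(seed=0))


class TestBalanceReport:
    def test_matched_variables_reach_p_one(self):
        treated = [("low", "21-35")] * 30 + [("high", ">35")] * 20
        donors = treated * 2
        df = match_frame(treated, donors)
        res = exact_match(df, MatchSpec(seed=0))
        rep = balance_report(df, res.matched, ["education", "age_band"])
        assert np.allclose(rep["p_post"], 1.0)

    def test_identical_subsamples_all_p_one(self):
        treated = [("low", "21-35")] * 10 + [("high", "21-35")] * 10
        df = match_frame(treated, treated)
        rep = balance_report(df, df, ["education"])
        assert rep["p_pre"].iloc[0] == pytest.approx(1.0)

    def test_distinct_marginals_detected(self):
        rng = np.random.default_rng(5)
        treated = [("low" if u < 0.8 else "high", "21-35") for u in rng.random(400)]
        donors = [("low" if u < 0.3 else "high", "21-35") for u in rng.random(400)]
        rep = balance_report(match_frame(treated, donors),
                             match_frame(treated, donors), ["education"])
        assert rep["p_pre"].iloc[0] < 0.001
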