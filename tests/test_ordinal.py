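"""Cumulative-logit fitting, diagnostics and backward elimination."""

import numpy as np
import pandas as pd
import pytest

from anccare.ordinal import (
    ConvergenceError,
    Design,
    ModelSpec,
    RankError,
    backward_eliminate,
    build_design,
    collinearity_check,
    fit_proportional_odds,
    hierarchical_selection,
    percent_concordant,
    score_test_po,
    simulate_po_outcome,
)

THRESH = [-2.0, -0.6, 1.0]


def po_frame(rng, n, betas: dict, thresholds=THRESH, extra_null=()):
    cols = {}
    for name in list(betas) + list(extra_null):
        cols[name] = rng.integers(0, 2, n).astype(float)
    X = np.column_stack([cols[c] for c in cols])
    beta_vec = [betas.get(c, 0.0) for c in cols]
    y = simulate_po_outcome(X, thresholds, beta_vec, rng)
    df = pd.DataFrame(cols)
    df["y"] = y
    return df


class TestFit:
    def test_recovers_injected_log_odds_ratio(self, rng):
        df = po_frame(rng, 4000, {"x": np.log(0.49)})
        fit = fit_proportional_odds(df, "y", ["x"])
        assert abs(fit.beta["x"] - np.log(0.49)) < 3 * fit.se["x"]

    def test_null_effects_recovered_near_one(self, rng):
        df = po_frame(rng, 4000, {"a": 0.0, "b": 0.0})
        fit = fit_proportional_odds(df, "y", ["a", "b"])
        for c in ("a", "b"):
            assert abs(fit.beta[c]) < 3 * fit.se[c]
            ors = fit.odds_ratios.loc[c]
            assert ors["ci_low"] < ors["OR"] < ors["ci_high"]

    def test_thresholds_strictly_ordered(self, rng):
        df = po_frame(rng, 1500, {"x": 0.5})
        fit = fit_proportional_odds(df, "y", ["x"])
        assert (np.diff(fit.thresholds) > 0).all()

    def test_loglik_matches_independent_optimizer(self, rng):
        """Cross-check against an independent ordered-logit routine."""
        sm = pytest.importorskip("statsmodels.miscmodels.ordinal_model")
        df = po_frame(rng, 800, {"x": -0.6, "z": 0.4})
        fit = fit_proportional_odds(df, "y", ["x", "z"])
        m = sm.OrderedModel(df["y"], df[["x", "z"]], distr="logit")
        res = m.fit(method="bfgs", disp=False)
        assert fit.loglik == pytest.approx(res.llf, abs=1e-6)
        np.testing.assert_allclose(fit.beta.values, res.params[:2].values,
                                   atol=1e-4)

    def test_binary_outcome_equals_plain_logistic(self, rng):
        sm_api = pytest.importorskip("statsmodels.api")
        n = 600
        x = rng.integers(0, 2, n).astype(float)
        y = simulate_po_outcome(x[:, None], [0.3], [-0.8], rng)
        df = pd.DataFrame({"x": x, "y": y})
        fit = fit_proportional_odds(df, "y", ["x"])
        logit = sm_api.Logit(y, sm_api.add_constant(x)).fit(disp=False)
        # P(Y=1) = expit(x beta - alpha): slope matches, intercept = -alpha
        assert fit.beta["x"] == pytest.approx(logit.params[1], abs=1e-6)
        assert -fit.thresholds[0] == pytest.approx(logit.params[0], abs=1e-6)

    def test_separation_raises_with_diagnostics(self):
        df = pd.DataFrame({"x": [0.0] * 20 + [1.0] * 20,
                           "y": [0] * 20 + [2] * 20})
        with pytest.raises(ConvergenceError):
            fit_proportional_odds(df, "y", ["x"])

    def test_aliased_design_names_columns(self, rng):
        df = po_frame(rng, 300, {"a": 0.3})
        df["b"] = df["a"]
        with pytest.raises(RankError, match="b"):
            fit_proportional_odds(df, "y", ["a", "b"])

    def test_single_level_outcome_rejected(self):
        df = pd.DataFrame({"x": [0.0, 1.0], "y": [1, 1]})
        with pytest.raises(ValueError):
            fit_proportional_odds(df, "y", ["x"])

    def test_categorical_reference_levels_respected(self, rng):
        df = po_frame(rng, 500, {"x": 0.5})
        df["edu"] = np.where(df["x"] > 0, "tertiary", "up-to-secondary")
        fit = fit_proportional_odds(df, "y", ["edu"],
                                    reference_levels={"edu": "tertiary"})
        assert list(fit.beta.index) == ["edu[up-to-secondary]"]


class TestScoreTest:
    def test_two_level_outcome_not_applicable(self, rng):
        x = rng.integers(0, 2, 200).astype(float)
        y = simulate_po_outcome(x[:, None], [0.0], [0.5], rng)
        fit = fit_proportional_odds(pd.DataFrame({"x": x, "y": y}), "y", ["x"])
        res = score_test_po(fit)
        assert not res.applicable
        assert "not applicable" in res.note

    def test_degrees_of_freedom(self, rng):
        df = po_frame(rng, 600, {"a": 0.4, "b": -0.3})
        res = score_test_po(fit_proportional_odds(df, "y", ["a", "b"]))
        assert res.df == 2 * (4 - 2)
        assert 0.0 <= res.p <= 1.0

    def test_power_against_non_parallel_slopes(self, rng):
        rejections = 0
        for _ in range(30):
            x = rng.integers(0, 2, 500).astype(float)[:, None]
            y = simulate_po_outcome(x, THRESH, None, rng,
                                    slopes_per_cut=np.array([[1.2, 0.0, -1.2]]))
            fit = fit_proportional_odds(
                pd.DataFrame({"x": x[:, 0], "y": y}), "y", ["x"])
            rejections += score_test_po(fit).p < 0.05
        assert rejections > 24


class TestConcordance:
    def test_perfect_separation_scores_hundred(self, rng):
        df = po_frame(rng, 400, {"x": 0.4})
        fit = fit_proportional_odds(df, "y", ["x"])
        # overwrite with a perfectly separating score via a fresh design
        fit.design.X = fit.y[:, None].astype(float)
        fit.beta = pd.Series([1.0], index=["x"])
        assert percent_concordant(fit).pct_concordant == pytest.approx(100.0)

    def test_small_fixture_matches_all_pairs_enumeration(self):
        from types import SimpleNamespace

        # fixed latent scores including a tie across outcome levels
        scores = np.array([0.5, 1.2, 0.5, 2.0, 1.2, 0.1])
        y = np.array([0, 1, 0, 2, 1, 1])
        fit = SimpleNamespace(latent_scores=scores, y=y)
        conc = disc = tied = pairs = 0
        for i in range(6):
            for j in range(i + 1, 6):
                if y[i] == y[j]:
                    continue
                pairs += 1
                lo, hi = (i, j) if y[i] < y[j] else (j, i)
                if scores[hi] > scores[lo]:
                    conc += 1
                elif scores[hi] < scores[lo]:
                    disc += 1
                else:
                    tied += 1
        res = percent_concordant(fit)
        assert res.n_pairs == pairs
        assert res.pct_concordant == pytest.approx(100 * conc / pairs)
        assert res.pct_discordant == pytest.approx(100 * disc / pairs)
        assert res.pct_tied == pytest.approx(100 * tied / pairs)

    def test_outcome_independent_score_near_fifty(self, rng):
        df = po_frame(rng, 3000, {"noise": 0.0})
        df["noise"] = rng.normal(size=3000)  # continuous, no ties
        fit = fit_proportional_odds(df, "y", ["noise"])
        res = percent_concordant(fit)
        assert res.pct_concordant == pytest.approx(50.0, abs=3.0)


class TestCollinearity:
    def test_orthogonal_design_unit_vif(self):
        X = np.column_stack([np.tile([0, 1], 4), np.repeat([0, 1], 4)]).astype(float)
        d = Design(X=X, columns=["a", "b"], var_columns={}, references={})
        vif = collinearity_check(d)
        np.testing.assert_allclose(vif["vif"], [1.0, 1.0], atol=1e-10)
        assert not vif["flagged"].any()

    def test_correlated_pair_matches_closed_form(self, rng):
        n, r = 20000, 0.95
        a = rng.normal(size=n)
        b = r * a + np.sqrt(1 - r * r) * rng.normal(size=n)
        d = Design(X=np.column_stack([a, b]), columns=["a", "b"],
                   var_columns={}, references={})
        vif = collinearity_check(d)
        expected = 1.0 / (1.0 - r * r)
        assert vif["vif"].iloc[0] == pytest.approx(expected, rel=0.10)

    def test_duplicated_column_flagged_aliased(self, rng):
        a = rng.normal(size=100)
        d = Design(X=np.column_stack([a, a]), columns=["a", "a_copy"],
                   var_columns={}, references={})
        vif = collinearity_check(d)
        assert np.isinf(vif["vif"]).all()
        assert vif["flagged"].all()


class TestBackwardElimination:
    def test_strong_candidate_retained(self, rng):
        df = po_frame(rng, 1500, {"strong": -0.9}, extra_null=["noise"])
        res = backward_eliminate(df, "y", ["strong", "noise"])
        assert "strong" in res.retained

    def test_fixed_variable_survives_null_effect(self, rng):
        df = po_frame(rng, 800, {"region": 0.0, "x": -0.8})
        res = backward_eliminate(df, "y", ["x"], fixed=["region"])
        assert "region" in res.final_fit.beta.index

    def test_trace_records_each_removal(self, rng):
        df = po_frame(rng, 700, {}, extra_null=["n1", "n2", "n3"])
        res = backward_eliminate(df, "y", ["n1", "n2", "n3"], stay_level=0.01)
        removed = [s.removed for s in res.trace if s.removed]
        assert len(removed) == len(set(removed))
        assert set(res.retained) | set(removed) == {"n1", "n2", "n3"}

    def test_candidate_fixed_overlap_rejected(self, rng):
        df = po_frame(rng, 100, {"x": 0.0})
        with pytest.raises(ValueError):
            backward_eliminate(df, "y", ["x"], fixed=["x"])


class TestHierarchicalSelection:
    def blocks_frame(self, rng, n=4000):
        betas = {
            "education": np.log(0.60), "occupation": np.log(0.49),
            "coc_band": np.log(0.60), "attended_classes": np.log(0.67),
        }
        nulls = ["marital", "nationality", "income_band", "insurance",
                 "parity", "planned", "region"]
        cols = {}
        for name in list(betas) + nulls:
            cols[name] = rng.integers(0, 2, n).astype(float)
        X = np.column_stack(list(cols.values()))
        y = simulate_po_outcome(X, THRESH,
                                [betas.get(c, 0.0) for c in cols], rng)
        df = pd.DataFrame(cols)
        df["y"] = y
        return df

    def spec(self):
        return ModelSpec(
            outcome="y",
            blocks=[
                ("predisposing", ["marital", "education", "occupation",
                                  "nationality"]),
                ("enabling", ["income_band", "insurance"]),
                ("pregnancy_related", ["parity", "planned", "coc_band",
                                       "attended_classes"]),
            ],
            fixed=["region"],
        )

    def test_true_effects_retained_and_enabling_emptied(self, rng):
        df = self.blocks_frame(rng)
        res = hierarchical_selection(df, self.spec())
        assert {"education", "occupation"} <= set(res.steps[0].retained)
        assert res.steps[1].retained == []
        assert {"coc_band", "attended_classes"} <= set(res.steps[2].retained)
        # region fixed throughout despite its null effect
        assert "region" in res.final_fit.beta.index
        assert res.concordance.pct_concordant > 60.0

    def test_all_null_blocks_leave_region_only(self):
        rng = np.random.default_rng(424)
        cols = {c: rng.integers(0, 2, 900).astype(float)
                for c in ["marital", "education", "occupation", "nationality",
                          "income_band", "insurance", "parity", "planned",
                          "coc_band", "attended_classes", "region"]}
        X = np.column_stack(list(cols.values()))
        y = simulate_po_outcome(X, THRESH, np.zeros(len(cols)), rng)
        df = pd.DataFrame(cols)
        df["y"] = y
        res = hierarchical_selection(df, self.spec())
        assert res.selected == []
        assert list(res.final_fit.beta.index) == ["region"]

    def test_deterministic_given_data_and_spec(self, rng):
        df = self.blocks_frame(rng, n=1200)
        a = hierarchical_selection(df, self.spec())
        b = hierarchical_selection(df, self.spec())
        assert a.selected == b.selected
        pd.testing.assert_series_equal(a.final_fit.beta, b.final_fit.beta)
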