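import numpy as np
import pandas as pd
import pytest

from faerspv.regression import (
    ConvergenceError,
    adjusted_ror,
    fit_logistic,
    interaction_ror,
    prepare_rows,
    sensitivity_table,
)


def _rows(counts):
    """Expand {(drug, y, sex, age): n} into a row-level frame."""
    recs = []
    for key, n in counts.items():
        drug, y = key[0], key[1]
        sex = key[2] if len(key) > 2 else 0
        age = key[3] if len(key) > 3 else 0
        recs += [{"caseid": "", "drug": drug, "outcome_s": y, "sex": sex,
                  "age_group": age, "country_us": 0}] * n
    return pd.DataFrame(recs)


class TestFitLogistic:
    def test_intercept_only_closed_form(self):
        y = np.array([1] * 25 + [0] * 75)
        fit = fit_logistic(pd.DataFrame(index=range(100)), y)
        assert fit.params["intercept"] == pytest.approx(np.log(1 / 3), abs=1e-8)

    def test_deviance_monotone_non_increasing(self):
        rng = np.random.default_rng(3)
        X = pd.DataFrame({"x1": rng.normal(size=400), "x2": rng.random(400) < 0.5})
        y = (rng.random(400) < 0.3).astype(int)
        fit = fit_logistic(X, y)
        assert all(b <= a + 1e-9 for a, b in zip(fit.deviance_path,
                                                 fit.deviance_path[1:]))
        assert fit.converged

    def test_matches_statsmodels(self):
        sm = pytest.importorskip("statsmodels.api")
        rng = np.random.default_rng(4)
        X = pd.DataFrame({
            "exposure": (rng.random(500) < 0.4).astype(float),
            "sex": (rng.random(500) < 0.6).astype(float),
        })
        logit = -1.0 + 0.8 * X["exposure"] + 0.5 * X["sex"]
        y = (rng.random(500) < 1 / (1 + np.exp(-logit))).astype(int)
        fit = fit_logistic(X, y)
        ref = sm.GLM(y, sm.add_constant(X), family=sm.families.Binomial()).fit()
        np.testing.assert_allclose(fit.params.values, ref.params.values, rtol=1e-6)
        np.testing.assert_allclose(fit.bse.values, ref.bse.values, rtol=1e-5)

    def test_separation_flagged_not_silent(self):
        X = pd.DataFrame({"x": [0.0] * 20 + [1.0] * 20})
        y = np.array([0] * 20 + [1] * 20)
        fit = fit_logistic(X, y)
        assert "x" in fit.separation

    def test_single_class_outcome_rejected(self):
        with pytest.raises(ValueError):
            fit_logistic(pd.DataFrame({"x": [0.0, 1.0]}), np.array([1, 1]))


class TestAdjustedRor:
    def test_model1_equals_collapsed_2x2_odds_ratio(self):
        rng = np.random.default_rng(5)
        for _ in range(25):
            a, b, c, d = (int(x) for x in rng.integers(5, 150, 4))
            rows = _rows({("X", 1): a, ("X", 0): b, ("O", 1): c, ("O", 0): d})
            (ror, lo, hi), _ = adjusted_ror(rows, "X", "s", model=1)
            assert ror == pytest.approx(a * d / (b * c), rel=1e-10)
            assert lo < ror < hi

    def test_exactly_balanced_covariate_leaves_estimate_unchanged(self):
        # identical counts in both covariate strata -> covariate MLE is 0
        # and the exposure coefficient collapses to the crude one
        counts = {}
        for sex in (0, 1):
            counts[("X", 1, sex)] = 30
            counts[("X", 0, sex)] = 70
            counts[("O", 1, sex)] = 20
            counts[("O", 0, sex)] = 80
        rows = _rows(counts)
        (crude, _, _), _ = adjusted_ror(rows, "X", "s", model=1)
        (adj, _, _), fit = adjusted_ror(rows, "X", "s", model=2)
        assert adj == pytest.approx(crude, abs=1e-6)
        assert fit.params["sex"] == pytest.approx(0.0, abs=1e-7)

    def test_confounded_crude_differs_from_adjusted(self):
        rng = np.random.default_rng(6)
        n = 5000
        sex = (rng.random(n) < 0.5).astype(int)
        exposed = (rng.random(n) < 1 / (1 + np.exp(-(-1.5 + 2.0 * sex)))).astype(int)
        y = (rng.random(n) < 1 / (1 + np.exp(-(-1.0 + 1.2 * sex)))).astype(int)
        rows = pd.DataFrame({
            "caseid": "", "drug": np.where(exposed == 1, "X", "O"),
            "outcome_s": y, "sex": sex, "age_group": 0, "country_us": 0,
        })
        (crude, _, _), _ = adjusted_ror(rows, "X", "s", model=1)
        (adj, lo, hi), _ = adjusted_ror(rows, "X", "s", model=2)
        assert abs(np.log(crude)) > abs(np.log(adj))  # confounding removed
        assert lo <= 1.0 <= hi  # true conditional OR is 1


class TestInteraction:
    def test_saturated_model_recovers_stratum_or_ratio(self):
        counts = {
            ("X", 1, 0): 40, ("X", 0, 0): 60, ("O", 1, 0): 25, ("O", 0, 0): 75,
            ("X", 1, 1): 55, ("X", 0, 1): 45, ("O", 1, 1): 20, ("O", 0, 1): 80,
        }
        rows = _rows(counts)

        def or_in(s):
            return (counts[("X", 1, s)] * counts[("O", 0, s)]) / (
                counts[("X", 0, s)] * counts[("O", 1, s)]
            )

        (iror, _, _), _ = interaction_ror(rows, "X", "s", "sex")
        assert iror == pytest.approx(or_in(1) / or_in(0), rel=1e-8)

    def test_equal_stratum_ors_give_unit_interaction(self):
        counts = {}
        for s in (0, 1):
            counts[("X", 1, s)] = 40
            counts[("X", 0, s)] = 60
            counts[("O", 1, s)] = 25
            counts[("O", 0, s)] = 75
        (iror, lo, hi), _ = interaction_ror(_rows(counts), "X", "s", "sex")
        assert iror == pytest.approx(1.0, abs=1e-7)
        assert lo <= 1.0 <= hi

    def test_constant_factor_not_estimable(self):
        rows = _rows({("X", 1): 10, ("X", 0): 10, ("O", 1): 10, ("O", 0): 10})
        with pytest.raises(ValueError, match="constant"):
            interaction_ror(rows, "X", "s", "sex")


class TestPrepareRows:
    def test_one_row_per_case_with_exclusions_counted(self, analysis_set,
                                                      small_corpus):
        maps = small_corpus.config.term_maps()
        socs = ["Skin and subcutaneous tissue disorders"]
        drugs = ["deucravacitinib", "upadacitinib", "tofacitinib"]
        rows, median_age, excl = prepare_rows(analysis_set, socs, maps, drugs)
        assert rows["caseid"].is_unique
        led = small_corpus.ledger.cases
        pooled = led[led["in_cohort"] & led["drug"].isin(drugs)]
        complete = pooled[
            pooled["sex"].notna() & pooled["age_years"].notna()
            & pooled["country"].notna()
        ]
        assert len(rows) == len(complete)
        assert excl["missing_sex"] == int(pooled["sex"].isna().sum())

    def test_age_splits_at_pooled_median(self, analysis_set, small_corpus):
        maps = small_corpus.config.term_maps()
        drugs = ["deucravacitinib", "upadacitinib", "tofacitinib"]
        rows, median_age, _ = prepare_rows(
            analysis_set, ["Gastrointestinal disorders"], maps, drugs
        )
        led = small_corpus.ledger.cases
        pooled = led[led["in_cohort"] & led["drug"].isin(drugs)]
        assert median_age == pytest.approx(
            float(np.median(pooled["age_years"].dropna()))
        )

    def test_sensitivity_table_has_all_models(self, analysis_set, small_corpus):
        maps = small_corpus.config.term_maps()
        drugs = ["deucravacitinib", "upadacitinib", "tofacitinib"]
        socs = ["Skin and subcutaneous tissue disorders"]
        rows, _, _ = prepare_rows(analysis_set, socs, maps, drugs)
        table = sensitivity_table(rows, drugs, socs)
        assert set(table["model"]) == {f"model{i}" for i in range(1, 6)}
        assert len(table) == len(drugs) * len(socs) * 5
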