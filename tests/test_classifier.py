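"""Logistic fitting, c statistic, BIC model averaging, LOOCV, printed equations."""

import math

import numpy as np
import pytest
from scipy import stats
from scipy.special import expit

import sasangface as sf
from sasangface.classifier import PerfectSeparationError, _intercept_only_fit
from sasangface.metrics import METRIC_NAMES


def _brute_force_auc(scores, labels):
    scores = np.asarray(scores, float)
    labels = np.asarray(labels, float)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    wins = (pos[:, None] > neg[None, :]).sum() + 0.5 * (pos[:, None] == neg[None, :]).sum()
    return wins / (len(pos) * len(neg))


class TestFitLogistic:
    def test_parameter_recovery_on_simulated_data(self):
        rng = np.random.default_rng(10)
        n = 10_000
        x = rng.normal(22.0, 3.0, n)
        eta = -10.0 + 0.45 * x
        y = (rng.random(n) < expit(eta)).astype(float)
        fit = sf.fit_logistic(y, x[:, None], names=("x",))
        assert fit.converged
        assert abs(fit.params[0] - (-10.0)) < 3 * fit.bse[0]
        assert abs(fit.params[1] - 0.45) < 3 * fit.bse[1]

    def test_matches_statsmodels_oracle(self, m20s_records):
        import statsmodels.api as sm

        y = (m20s_records["sasang_type"] == "TE").to_numpy(float)
        X = m20s_records[["bmi", "CJWR"]].to_numpy()
        ours = sf.fit_logistic(y, X, names=("bmi", "CJWR"))
        theirs = sm.Logit(y, sm.add_constant(X)).fit(disp=0)
        assert ours.params == pytest.approx(theirs.params, rel=1e-6)
        assert ours.bse == pytest.approx(theirs.bse, rel=1e-4)
        assert ours.loglik == pytest.approx(theirs.llf, abs=1e-8)
        assert ours.bic == pytest.approx(theirs.bic, abs=1e-6)

    def test_all_labels_equal_rejected(self):
        with pytest.raises(ValueError, match="no variation"):
            sf.fit_logistic(np.ones(20), np.arange(20.0)[:, None])

    def test_constant_predictor_rejected(self):
        y = np.array([0, 1] * 10, dtype=float)
        X = np.ones((20, 1))
        with pytest.raises(ValueError, match="constant predictor"):
            sf.fit_logistic(y, X)

    def test_perfect_separation_detected(self):
        x = np.array([-3.0, -2.0, -1.0, 1.0, 2.0, 3.0])
        y = np.array([0.0, 0.0, 0.0, 1.0, 1.0, 1.0])
        with pytest.raises(PerfectSeparationError):
            sf.fit_logistic(y, x[:, None])
        flagged = sf.fit_logistic(y, x[:, None], on_separation="flag")
        assert flagged.separation

    def test_published_bmi_only_odds_ratio_scale(self):
        # single-predictor BMI model: OR per unit BMI near the published 1.63
        ors = []
        for seed in range(40):
            rec = sf.generate_metric_level(sf.default_config(strata=["M20s"], seed=seed))
            model = sf.TaeEumClassifier(rec)
            res = model.fit(predictors=["bmi"])
            ors.append(res.odds_ratios().loc["bmi", "odds_ratio"])
        assert np.mean(ors) == pytest.approx(1.6, abs=0.12)

    def test_odds_ratio_uses_comparison_unit(self, m20s_records):
        model = sf.TaeEumClassifier(m20s_records)
        res = model.fit(predictors=["CJWR"])
        table = res.odds_ratios()
        beta = res.params["CJWR"]
        assert table.loc["CJWR", "unit"] == 0.05
        assert table.loc["CJWR", "odds_ratio"] == pytest.approx(math.exp(0.05 * beta))


class TestCStatistic:
    def test_perfectly_ordered_scores(self):
        y = np.array([0, 0, 0, 1, 1])
        s = np.array([0.1, 0.2, 0.3, 0.8, 0.9])
        assert sf.c_statistic(s, y) == 1.0

    def test_uninformative_scores_near_half(self):
        rng = np.random.default_rng(11)
        y = rng.integers(0, 2, 5000)
        s = rng.normal(size=5000)
        assert sf.c_statistic(s, y) == pytest.approx(0.5, abs=0.03)

    def test_ties_count_one_half(self):
        y = np.array([0, 1])
        s = np.array([0.4, 0.4])
        assert sf.c_statistic(s, y) == 0.5

    def test_matches_brute_force_and_sklearn(self):
        from sklearn.metrics import roc_auc_score

        rng = np.random.default_rng(12)
        for _ in range(200):
            n = int(rng.integers(10, 60))
            y = rng.integers(0, 2, n)
            if y.min() == y.max():
                continue
            s = rng.integers(0, 8, n).astype(float)  # integer scores force ties
            ours = sf.c_statistic(s, y)
            assert ours == pytest.approx(_brute_force_auc(s, y), abs=1e-12)
            assert ours == pytest.approx(roc_auc_score(y, s), abs=1e-12)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="both classes"):
            sf.c_statistic([0.1, 0.2], [1, 1])

    def test_joint_fit_dominates_single_predictors(self, m20s_records):
        model = sf.TaeEumClassifier(m20s_records)
        joint = model.fit(predictors=["bmi", "CJWR"]).c_statistic
        for pred in ("bmi", "CJWR"):
            assert joint >= model.fit(predictors=[pred]).c_statistic - 1e-12


class TestBma:
    def test_intercept_only_bic_closed_form(self, m20s_records):
        y = (m20s_records["sasang_type"] == "TE").to_numpy(float)
        fit = _intercept_only_fit(y)
        n, n1 = len(y), y.sum()
        phat = n1 / n
        expected = -2 * (n1 * math.log(phat) + (n - n1) * math.log(1 - phat)) + math.log(n)
        assert fit.bic == pytest.approx(expected, abs=1e-9)

    def test_single_candidate_weights(self):
        rng = np.random.default_rng(13)
        x = rng.normal(size=400)
        y = (rng.random(400) < expit(1.5 * x)).astype(float)
        res = sf.bma(y, x[:, None], names=("x",))
        assert len(res.models) == 2
        assert res.parsimonious.predictor_names == ("x",)
        assert res.inclusion_probs["x"] > 0.5
        assert res.weights.sum() == pytest.approx(1.0)

    def test_enumerates_full_model_space(self, m20s_records):
        model = sf.TaeEumClassifier(m20s_records)
        res = model.fit_bma()
        assert len(res.models) + res.n_failed == 2**8
        assert res.weights.sum() == pytest.approx(1.0)
        assert res.bics[np.argmax(res.weights)] == pytest.approx(min(res.bics))

    def test_selection_recovers_true_support_in_most_seeds(self):
        # quick version of the selection-consistency experiment (full version
        # in the acceptance suite)
        hits = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            n = 230
            X = rng.normal(size=(n, 4))
            eta = -0.3 + 1.0 * X[:, 0] - 1.0 * X[:, 1]
            y = (rng.random(n) < expit(eta)).astype(float)
            res = sf.bma(y, X, names=("a", "b", "n1", "n2"))
            hits += set(res.parsimonious.predictor_names) == {"a", "b"}
        assert hits >= 15


class TestLoocv:
    def test_separable_toy_data_classified_perfectly(self):
        x = np.concatenate([np.linspace(-3, -1, 15), np.linspace(1, 3, 15)])
        y = np.concatenate([np.zeros(15), np.ones(15)])
        assert sf.loocv_correct_rate(y, x[:, None]) == 100.0

    def test_shuffled_labels_near_chance(self, m20s_records):
        rng = np.random.default_rng(14)
        y = (m20s_records["sasang_type"] == "TE").to_numpy(float)
        y = rng.permutation(y)
        X = m20s_records[["bmi", "CJWR"]].to_numpy()
        rate = sf.loocv_correct_rate(y, X)
        chance = 100.0 * max(y.mean(), 1 - y.mean())
        assert abs(rate - chance) < 15.0


class TestPrintedEquations:
    def test_te_probability_at_published_group_means(self):
        # x = 0.236 - 0.454*25.1 + 9.237*1.13 = -0.72159
        p = sf.predict_printed("M20s", 25.1, 1.13)
        assert p == pytest.approx(1.0 / (1.0 + math.exp(-0.72159)), abs=1e-6)
        assert p == pytest.approx(0.673, abs=1e-3)

    def test_cjwr_limit_drives_probability_to_zero(self):
        assert sf.predict_printed("M20s", 25.1, 100.0) < 1e-12

    def test_bmi_fold_changes_match_published(self):
        # the published per-unit-BMI fold changes; F20s prints 1.58 while
        # exp(0.4617) = 1.5868 rounds to 1.59, so that stratum is held to
        # 0.01 rather than exact rounding
        folds = {"M20s": 1.57, "M60s": 1.45, "F20s": 1.58, "F60s": 1.72}
        for stratum, fold in folds.items():
            b_bmi = sf.reference.PRINTED_EQUATIONS[stratum][1]
            value = math.exp(abs(b_bmi))
            if stratum == "F20s":
                assert value == pytest.approx(fold, abs=0.01)
            else:
                assert round(value, 2) == pytest.approx(fold)

    def test_unknown_stratum_rejected(self):
        with pytest.raises(KeyError, match="unknown stratum"):
            sf.predict_printed("M40s", 22.0, 1.1)

    def test_vectorized_evaluation(self):
        out = sf.predict_printed("F20s", np.array([18.0, 25.0]), np.array([1.2, 1.1]))
        assert out.shape == (2,)
        assert np.all((out > 0) & (out < 1))


class TestInteraction:
    def test_null_interaction_p_uniform(self):
        pvals = []
        for seed in range(400):
            rng = np.random.default_rng(seed)
            n = 230
            zb, zc = rng.normal(size=n), rng.normal(size=n)
            y = (rng.random(n) < expit(0.5 * zb - 0.5 * zc)).astype(float)
            pvals.append(sf.interaction_check(y, zb, zc))
        ks = stats.kstest(pvals, "uniform")
        assert ks.pvalue > 0.01
        # the test's size is correct at the 5% level
        assert 0.02 <= np.mean(np.asarray(pvals) < 0.05) <= 0.09

    def test_strong_interaction_detected_with_high_power(self):
        hits = 0
        for seed in range(100):
            rng = np.random.default_rng(seed)
            n = 230
            zb, zc = rng.normal(size=n), rng.normal(size=n)
            y = (rng.random(n) < expit(0.5 * zb - 0.5 * zc + 0.8 * zb * zc)).astype(float)
            hits += sf.interaction_check(y, zb, zc) < 0.05
        assert hits >= 90

    def test_published_design_interaction_usually_ns(self):
        hits = 0
        for seed in range(40):
            rec = sf.generate_metric_level(sf.default_config(strata=["M20s"], seed=seed))
            model = sf.TaeEumClassifier(rec)
            hits += model.interaction_check() > 0.05
        assert hits > 20


class TestModelResultsSurface:
    def test_fit_and_summary(self, m20s_records):
        model = sf.TaeEumClassifier.from_dataframe(m20s_records)
        res = model.fit(predictors=["bmi", "CJWR"])
        assert list(res.params.index) == ["intercept", "bmi", "CJWR"]
        assert res.bic == pytest.approx(res.fit.bic)
        text = res.summary()
        assert "c statistic" in text and "CJWR" in text and "BIC" in text

    def test_published_convention_is_negated_eta(self, m20s_records):
        res = sf.TaeEumClassifier(m20s_records).fit(predictors=["bmi", "CJWR"])
        assert np.allclose(res.published_equation_x().to_numpy(), -res.params.to_numpy())

    def test_predict_on_new_data(self, m20s_records):
        model = sf.TaeEumClassifier(m20s_records)
        res = model.fit(predictors=["bmi", "CJWR"])
        out = res.predict(m20s_records.head(5))
        assert out.shape == (5,)
        assert np.allclose(out, res.fit.fittedvalues[:5])

    def test_candidate_predictor_list(self):
        assert sf.classifier.CANDIDATE_PREDICTORS == ("bmi",) + METRIC_NAMES

    def test_missing_column_rejected(self, m20s_records):
        with pytest.raises(KeyError, match="predictor"):
            sf.TaeEumClassifier(m20s_records.drop(columns=["WHR"]))
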