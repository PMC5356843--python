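"""Fold-change selection, DLDA, and stepwise-AIC logistic regression."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from scipy.special import expit
from scipy.stats import norm

from classifiability.classifiers import (
    build_design,
    fit_dlda,
    fit_stepwise_logistic,
    loo_dlda_scores,
    predict_dlda,
    predict_logistic,
    select_top_genes,
)
from classifiability.cohort import CohortError
from conftest import make_cohort


def _frame(X, samples=None, genes=None):
    samples = samples or [f"s{i}" for i in range(X.shape[1])]
    genes = genes or [f"g{i}" for i in range(X.shape[0])]
    return pd.DataFrame(X, index=genes, columns=samples)


def _labels(groups, samples):
    return pd.Series(groups, index=samples)


# --- gene selection ---------------------------------------------------------

class TestSelectTopGenes:
    def test_matches_brute_force_ranking(self):
        """Agrees with an exhaustive sort of per-gene |mean(A) - mean(B)|."""
        rng = np.random.default_rng(0)
        X = rng.normal(size=(50, 12))
        expr = _frame(X)
        y = _labels(["a"] * 6 + ["b"] * 6, expr.columns)
        got = select_top_genes(expr, y, k=10)
        diffs = {
            g: abs(X[i, :6].mean() - X[i, 6:].mean())
            for i, g in enumerate(expr.index)
        }
        expected = sorted(diffs, key=lambda g: -diffs[g])[:10]
        assert got == expected

    def test_absolute_fold_change_ranks(self):
        X = np.array([[0.0, 0, 2, 2], [0, 0, -3, -3]])
        expr = _frame(X)
        y = _labels(["a", "a", "b", "b"], expr.columns)
        assert select_top_genes(expr, y, k=1) == ["g1"]

    def test_k_larger_than_gene_count_returns_all(self):
        expr = _frame(np.random.default_rng(1).normal(size=(5, 6)))
        y = _labels(["a"] * 3 + ["b"] * 3, expr.columns)
        assert len(select_top_genes(expr, y, k=1000)) == 5

    def test_invariant_to_sample_order_and_label_swap(self):
        rng = np.random.default_rng(2)
        expr = _frame(rng.normal(size=(30, 10)))
        y = _labels(["a"] * 5 + ["b"] * 5, expr.columns)
        base = select_top_genes(expr, y, k=7)
        perm = list(rng.permutation(expr.columns))
        assert select_top_genes(expr[perm], y.loc[perm], k=7) == base
        swapped = y.map({"a": "b", "b": "a"})
        assert select_top_genes(expr, swapped, k=7) == base

    def test_single_class_rejected(self):
        expr = _frame(np.zeros((3, 4)))
        y = _labels(["a"] * 4, expr.columns)
        with pytest.raises(CohortError):
            select_top_genes(expr, y, k=2)


# --- DLDA -------------------------------------------------------------------

class TestDlda:
    def test_fit_matches_explicit_sums(self):
        """Means and pooled variances recomputed with explicit formulas."""
        rng = np.random.default_rng(3)
        X = rng.normal(size=(3, 6))
        expr = _frame(X)
        y = _labels(["a", "a", "a", "b", "b", "b"], expr.columns)
        model = fit_dlda(expr, y, list(expr.index))
        np.testing.assert_allclose(model.means[0], X[:, :3].mean(axis=1))
        np.testing.assert_allclose(model.means[1], X[:, 3:].mean(axis=1))
        ss = ((X[:, :3] - X[:, :3].mean(axis=1, keepdims=True)) ** 2).sum(axis=1) + (
            (X[:, 3:] - X[:, 3:].mean(axis=1, keepdims=True)) ** 2
        ).sum(axis=1)
        np.testing.assert_allclose(model.pooled_var, ss / 4)
        np.testing.assert_allclose(model.priors, [0.5, 0.5])

    def test_degenerate_variance_floored(self):
        X = np.array([[0.0, 0, 2, 2], [0, 0, 2, 2]])
        expr = _frame(X)
        y = _labels(["a", "a", "b", "b"], expr.columns)
        model = fit_dlda(expr, y, list(expr.index))
        assert model.floor_applied
        assert np.all(model.pooled_var > 0)
        label, score = predict_dlda(model, expr["s0"])
        assert label == "a" and np.isfinite(score)

    def test_sample_at_centroid_and_tie(self):
        X = np.array([[0.0, 0, 2, 2], [0, 0, 2, 2], [1, -1, 3, 1]])
        expr = _frame(X)
        y = _labels(["a", "a", "b", "b"], expr.columns)
        model = fit_dlda(expr, y, list(expr.index))
        label, score = predict_dlda(model, pd.Series([0.0, 0.0, 0.0], index=expr.index))
        assert label == "a" and score < 0
        # equidistant sample: tie breaks to the first class, score flags it
        label, score = predict_dlda(model, pd.Series([1.0, 1.0, 1.0], index=expr.index))
        assert label == "a" and score == 0.0

    def test_label_permutation_within_class_is_irrelevant(self):
        rng = np.random.default_rng(4)
        expr = _frame(rng.normal(size=(4, 8)))
        y = _labels(["a"] * 4 + ["b"] * 4, expr.columns)
        perm = ["s1", "s3", "s0", "s2", "s7", "s5", "s6", "s4"]
        m1 = fit_dlda(expr, y, list(expr.index))
        m2 = fit_dlda(expr[perm], y.loc[perm], list(expr.index))
        np.testing.assert_allclose(m1.means, m2.means)
        np.testing.assert_allclose(m1.pooled_var, m2.pooled_var)

    def test_agrees_with_diagonal_gaussian_oracle(self):
        """Label equals argmax of the diagonal-covariance Gaussian
        log-likelihood plus log prior, evaluated independently."""
        rng = np.random.default_rng(5)
        for _ in range(25):
            n0, n1 = rng.integers(3, 9, 2)
            p = rng.integers(2, 8)
            X = rng.normal(size=(p, n0 + n1))
            expr = _frame(X)
            y = _labels(["a"] * n0 + ["b"] * n1, expr.columns)
            model = fit_dlda(expr, y, list(expr.index))
            x = rng.normal(size=p)
            label, _ = predict_dlda(model, pd.Series(x, index=expr.index))
            sd = np.sqrt(model.pooled_var)
            ll = [
                norm.logpdf(x, loc=model.means[i], scale=sd).sum()
                + np.log(model.priors[i])
                for i in range(2)
            ]
            assert label == ("a" if ll[0] >= ll[1] else "b")

    def test_decision_invariant_to_per_gene_shift(self):
        """Adding a constant to one gene everywhere (train + test) cannot
        change selection or predictions."""
        rng = np.random.default_rng(6)
        expr = _frame(rng.normal(size=(20, 10)))
        y = _labels(["a"] * 5 + ["b"] * 5, expr.columns)
        x = pd.Series(rng.normal(size=20), index=expr.index)
        genes = select_top_genes(expr, y, k=8)
        base = predict_dlda(fit_dlda(expr, y, genes), x)
        shifted = expr.copy()
        shifted.loc["g3"] += 17.5
        x2 = x.copy()
        x2.loc["g3"] += 17.5
        genes2 = select_top_genes(shifted, y, k=8)
        assert genes2 == genes
        out = predict_dlda(fit_dlda(shifted, y, genes2), x2)
        assert out[0] == base[0]
        assert out[1] == pytest.approx(base[1], rel=1e-9, abs=1e-9)

    def test_missing_gene_rejected(self):
        expr = _frame(np.zeros((3, 4)) + np.arange(4))
        y = _labels(["a", "a", "b", "b"], expr.columns)
        with pytest.raises(CohortError, match="absent"):
            fit_dlda(expr, y, ["g0", "nope"])

    def test_loo_scores_match_literal_recomposition(self):
        """The rank-one-update fast path equals refitting the whole pipeline
        without each sample in turn."""
        cohort = make_cohort(n_per_class=5, n_genes=30, seed=9, signal=1.0)
        k = 12
        fast = loo_dlda_scores(cohort.expression, cohort.labels, k=k, classes=cohort.classes)
        for sid in cohort.sample_ids:
            rest = [s for s in cohort.sample_ids if s != sid]
            expr = cohort.expression[rest]
            y = cohort.labels.loc[rest]
            genes = select_top_genes(expr, y, k=k, classes=cohort.classes)
            model = fit_dlda(expr, y, genes, classes=cohort.classes)
            _, score = predict_dlda(model, cohort.expression[sid])
            assert fast[sid] == pytest.approx(score, rel=1e-9, abs=1e-9)


# --- stepwise logistic ------------------------------------------------------

class TestStepwiseLogistic:
    def test_informative_variable_beats_noise(self):
        """x1 tracks the labels, x2 is noise: exhaustive AIC over the four
        candidate models (statsmodels) confirms {x1} is selected."""
        rng = np.random.default_rng(11)
        n = 60
        y = np.array([0] * 30 + [1] * 30)
        clinical = pd.DataFrame(
            {
                "x1": y + rng.normal(scale=0.6, size=n),
                "x2": rng.normal(size=n),
            },
            index=[f"s{i}" for i in range(n)],
        )
        labels = pd.Series(np.where(y == 1, "poor", "good"), index=clinical.index)
        model = fit_stepwise_logistic(clinical, labels, classes=("good", "poor"))
        assert "x1" in model.selected_variables

        aics = {}
        for subset in [(), ("x1",), ("x2",), ("x1", "x2")]:
            X = np.column_stack([np.ones(n)] + [clinical[v] for v in subset])
            aics[subset] = sm.Logit(y, X).fit(disp=0).aic
        best = min(aics, key=aics.get)
        assert set(model.selected_variables) == set(best)
        assert model.aic == pytest.approx(aics[best], rel=1e-8)

    def test_zero_candidates_gives_intercept_only_closed_form(self):
        clinical = pd.DataFrame(index=[f"s{i}" for i in range(10)])
        labels = pd.Series(["good"] * 4 + ["poor"] * 6, index=clinical.index)
        model = fit_stepwise_logistic(clinical, labels, classes=("good", "poor"))
        assert model.selected_variables == []
        phat = 0.6
        ll = 6 * np.log(phat) + 4 * np.log(1 - phat)
        assert model.aic == pytest.approx(2 - 2 * ll, rel=1e-10)
        assert model.coefficients["intercept"] == pytest.approx(np.log(phat / (1 - phat)))

    def test_null_candidate_rarely_selected(self):
        """Single noise covariate enters only when its deviance drop beats
        the 2-point AIC penalty (~16% of null replicates)."""
        rng = np.random.default_rng(12)
        picked = 0
        n_rep = 150
        for _ in range(n_rep):
            n = 50
            clinical = pd.DataFrame(
                {"x": rng.normal(size=n)}, index=[f"s{i}" for i in range(n)]
            )
            labels = pd.Series(
                np.where(rng.random(n) < 0.5, "poor", "good"), index=clinical.index
            )
            if labels.nunique() < 2:
                continue
            m = fit_stepwise_logistic(clinical, labels, classes=("good", "poor"))
            picked += bool(m.selected_variables)
        assert picked / n_rep < 0.3

    def test_never_worse_than_intercept_only(self):
        rng = np.random.default_rng(13)
        for seed in range(5):
            cohort = make_cohort(seed=seed, n_per_class=10, n_clinical=4)
            model = fit_stepwise_logistic(
                cohort.clinical, cohort.labels, classes=cohort.classes
            )
            n = cohort.n_samples
            k = (cohort.labels == "poor").sum()
            phat = k / n
            ll0 = k * np.log(phat) + (n - k) * np.log(1 - phat)
            assert model.aic <= 2 - 2 * ll0 + 1e-9

    def test_categorical_block_enters_whole(self):
        rng = np.random.default_rng(14)
        n = 90
        cat = rng.choice(["lo", "mid", "hi"], n)
        eta = np.select([cat == "lo", cat == "mid"], [-1.5, 0.0], default=1.5)
        labels = pd.Series(
            np.where(rng.random(n) < expit(eta), "poor", "good"),
            index=[f"s{i}" for i in range(n)],
        )
        clinical = pd.DataFrame({"grade": cat}, index=labels.index)
        model = fit_stepwise_logistic(clinical, labels, classes=("good", "poor"))
        assert model.selected_variables == ["grade"]
        assert len(model.coefficients) == 3  # intercept + 2 indicators

    def test_directions_forward_and_backward_run(self):
        cohort = make_cohort(seed=21, n_per_class=10, n_clinical=4)
        for direction in ("forward", "backward"):
            m = fit_stepwise_logistic(
                cohort.clinical, cohort.labels, direction=direction, classes=cohort.classes
            )
            assert np.isfinite(m.aic)


class TestPredictLogistic:
    def test_intercept_only_threshold_convention(self):
        clinical = pd.DataFrame(index=[f"s{i}" for i in range(8)])
        labels = pd.Series(["good"] * 4 + ["poor"] * 4, index=clinical.index)
        model = fit_stepwise_logistic(clinical, labels, classes=("good", "poor"))
        label, prob = predict_logistic(model, {})
        assert prob == pytest.approx(0.5)
        assert label == "poor"  # >= threshold goes to the positive class

    def test_probability_is_inverse_logit(self):
        cohort = make_cohort(seed=15, n_per_class=12, n_clinical=3, signal=0.0)
        model = fit_stepwise_logistic(cohort.clinical, cohort.labels, classes=cohort.classes)
        record = cohort.clinical.iloc[0]
        _, prob = predict_logistic(model, record)
        X, names, _ = build_design(
            record.to_frame().T, model.selected_variables, terms=model.terms
        )
        eta = float((X @ np.array([model.coefficients[nm] for nm in names]))[0])
        assert prob == pytest.approx(float(expit(eta)), abs=1e-12)

    def test_large_linear_predictor_saturates(self):
        rng = np.random.default_rng(16)
        x = np.array([0.0] * 20 + [1.0] * 20)
        labels = pd.Series(
            np.where(x == 1, "poor", "good"), index=[f"s{i}" for i in range(40)]
        )
        clinical = pd.DataFrame({"x": x}, index=labels.index)
        model = fit_stepwise_logistic(clinical, labels, classes=("good", "poor"))
        label, prob = predict_logistic(model, {"x": 1.0})
        assert label == "poor" and prob > 0.999

    def test_unseen_level_raises_with_level_name(self):
        rng = np.random.default_rng(17)
        cat = np.array(["a"] * 15 + ["b"] * 15)
        # strong association guarantees the variable is selected
        flip = rng.random(30) < 0.1
        labels = pd.Series(
            np.where((cat == "b") ^ flip, "poor", "good"),
            index=[f"s{i}" for i in range(30)],
        )
        clinical = pd.DataFrame({"grade": cat}, index=labels.index)
        model = fit_stepwise_logistic(clinical, labels, classes=("good", "poor"))
        assert model.selected_variables == ["grade"]
        with pytest.raises(CohortError, match="zzz"):
            predict_logistic(model, {"grade": "zzz"})
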