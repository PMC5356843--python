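"""Balanced leave-two-out cross-validation of the five classification
schemes, within-stratum evaluation, and bootstrap interval summaries.

Each CV repeat holds out one sample from each prognosis class, retrains the
complete pipeline of the evaluated method on the remainder — gene selection,
stepwise selection, inner leave-one-out and routing included, so no held-out
information leaks into any fitting step — and predicts the held-out pair.
The reported error is the balanced error over the pooled held-out
predictions; 95% intervals come from a percentile bootstrap over repeats.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .classifiers import (
    dlda_scores,
    fit_dlda,
    fit_stepwise_logistic,
    predict_logistic_table,
    select_top_genes,
)
from .cohort import Cohort, CohortError
from .integration import (
    fit_prevalidation,
    fit_rf_integration,
    predict_rf,
    prevalidated_vector,
)
from .multistep import fit_multistep, predict_multistep_table

METHODS = ("dlda", "clinical", "prevalidation", "rf", "multistep")

BOOTSTRAP_RESAMPLES = 1000


def balanced_error(true_labels, predicted) -> float:
    """Mean of the two class-conditional misclassification rates."""
    true_labels = np.asarray(true_labels)
    predicted = np.asarray(predicted)
    if true_labels.shape != predicted.shape:
        raise ValueError("label vectors differ in length")
    classes = pd.unique(true_labels)
    if len(classes) != 2:
        raise ValueError(
            f"balanced error needs both classes in true_labels, got {list(classes)}"
        )
    rates = [
        float(np.mean(predicted[true_labels == c] != c)) for c in classes
    ]
    return float(np.mean(rates))


@dataclass
class EvaluationResult:
    """Distribution of balanced leave-two-out errors for one method."""

    method: str
    per_repeat_errors: np.ndarray
    mean_error: float
    interval: tuple
    n_repeats: int
    seed: int
    held_out: pd.DataFrame = field(repr=False, default=None)

    def summary_row(self) -> dict:
        return {
            "method": self.method,
            "mean_error": self.mean_error,
            "ci_lower": self.interval[0],
            "ci_upper": self.interval[1],
            "n_repeats": self.n_repeats,
            "seed": self.seed,
        }


def draw_pairs(cohort: Cohort, n_repeats: int, seed: int) -> list:
    """Seeded leave-two-out fold sequence: per repeat, one sample id from
    each prognosis class drawn uniformly."""
    rng = np.random.default_rng(seed)
    ids = np.asarray(cohort.sample_ids, dtype=object)
    labels = cohort.labels
    by_class = [ids[(labels == c).to_numpy()] for c in cohort.classes]
    for c, pool in zip(cohort.classes, by_class):
        if len(pool) < 3:
            raise CohortError(f"class {c!r} needs >=3 samples for leave-two-out CV")
    return [
        (rng.choice(by_class[0]), rng.choice(by_class[1])) for _ in range(n_repeats)
    ]


def all_pairs(cohort: Cohort) -> list:
    """Exhaustive enumeration of one-per-class held-out pairs."""
    ids = np.asarray(cohort.sample_ids, dtype=object)
    labels = cohort.labels
    a = ids[(labels == cohort.classes[0]).to_numpy()]
    b = ids[(labels == cohort.classes[1]).to_numpy()]
    return [(x, y) for x in a for y in b]


class _FoldWorkspace:
    """One training fold; shares components that several methods reuse.

    The full-train DLDA (used by the dlda method and to score held-out
    samples for the integration baselines) and the leave-one-out decision
    scores (the pre-validated vector, which thresholds to the multi-step's
    error vector) are computed at most once per fold.
    """

    def __init__(self, train: Cohort, test: Cohort, k: int):
        self.train, self.test, self.k = train, test, k
        self._dlda = None
        self._prevec = None
        self._test_scores = None

    def dlda_model(self):
        if self._dlda is None:
            genes = select_top_genes(
                self.train.expression, self.train.labels, k=self.k,
                classes=self.train.classes,
            )
            self._dlda = fit_dlda(
                self.train.expression, self.train.labels, genes,
                classes=self.train.classes,
            )
        return self._dlda

    def prevec(self):
        if self._prevec is None:
            self._prevec = prevalidated_vector(self.train, k=self.k)
        return self._prevec

    def error_vector(self):
        from .routing import ErrorVector

        scores = self.prevec().values
        classes = self.train.classes
        predicted = np.where(scores.to_numpy() <= 0, classes[0], classes[1])
        errors = (predicted != self.train.labels.to_numpy()).astype(int)
        return ErrorVector(
            errors=pd.Series(errors, index=scores.index, name="loocv_error"),
            scheme={"cv": "loocv", "classifier": "dlda", "k": self.k},
        )

    def test_dlda_scores(self) -> np.ndarray:
        if self._test_scores is None:
            model = self.dlda_model()
            X = self.test.expression.loc[list(model.genes)].to_numpy(dtype=float)
            self._test_scores = dlda_scores(model, X)
        return self._test_scores


def _fit_and_predict(method, ws: _FoldWorkspace, rf_trees, fit_seed):
    """Train ``method`` on the fold's training cohort and predict its
    held-out samples (in ``test.sample_ids`` order)."""
    train, test = ws.train, ws.test
    classes = train.classes
    if method == "dlda":
        s = ws.test_dlda_scores()
        return list(np.where(s <= 0, classes[0], classes[1]))
    if method == "clinical":
        with warnings.catch_warnings():
            # within-stratum subcohorts make the stratum variable constant
            # by construction; the exclusion is recorded on the model
            warnings.filterwarnings("ignore", message="dropping constant candidate")
            model = fit_stepwise_logistic(
                train.clinical, train.labels, classes=classes, specs=train.variable_specs
            )
        return list(predict_logistic_table(model, test.clinical)["predicted_label"])
    if method == "prevalidation":
        from .integration import PREVALIDATED_SCORE

        model = fit_prevalidation(ws.prevec(), train.clinical, train.labels)
        aug = test.clinical.copy()
        aug[PREVALIDATED_SCORE] = ws.test_dlda_scores()
        return list(predict_logistic_table(model, aug)["predicted_label"])
    if method == "rf":
        model = fit_rf_integration(
            ws.prevec(), train.clinical, train.labels, n_trees=rf_trees, seed=fit_seed
        )
        scores = pd.Series(ws.test_dlda_scores(), index=test.sample_ids)
        X = model.feature_matrix(scores, test.clinical)
        votes = model.forest.predict_proba(X)[:, 1]
        return list(np.where(votes >= 0.5, classes[1], classes[0]))
    if method == "multistep":
        model = fit_multistep(train, k=ws.k, errors=ws.error_vector())
        table = predict_multistep_table(model, test.expression, test.clinical)
        return list(table["predicted_label"])
    raise ValueError(f"unknown method {method!r}; choose from {METHODS}")


def _bootstrap_interval(err0: np.ndarray, err1: np.ndarray, seed: int) -> tuple:
    """Percentile bootstrap over held-out pairs.

    Each repeat holds out exactly one sample per class, so the pooled
    balanced error of a resample is the mean of the two per-class error
    indicator means.
    """
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0x5EED]))
    n = err0.size
    idx = rng.integers(0, n, size=(BOOTSTRAP_RESAMPLES, n))
    errs = 0.5 * (err0[idx].mean(axis=1) + err1[idx].mean(axis=1))
    return float(np.percentile(errs, 2.5)), float(np.percentile(errs, 97.5))


def leave_two_out_evaluate(
    cohort: Cohort,
    method: str,
    n_repeats: int = 200,
    seed: int = 0,
    k: int = 1000,
    rf_trees: int = 500,
    pairs: list | None = None,
    exhaustive: bool = False,
) -> EvaluationResult:
    """Balanced leave-two-out error of one method.

    ``pairs`` may be precomputed (shared folds across methods); otherwise
    ``n_repeats`` pairs are drawn from ``seed``, or every class pair is
    enumerated when ``exhaustive``.
    """
    return _evaluate_methods(
        cohort, (method,), n_repeats=n_repeats, seed=seed, k=k,
        rf_trees=rf_trees, pairs=pairs, exhaustive=exhaustive,
    )[method]


def _evaluate_methods(
    cohort: Cohort,
    methods: tuple,
    n_repeats: int = 200,
    seed: int = 0,
    k: int = 1000,
    rf_trees: int = 500,
    pairs: list | None = None,
    exhaustive: bool = False,
) -> dict:
    """Evaluate several methods on one shared fold sequence.

    Components common to multiple methods (the full-train DLDA and the
    pre-validated vector) are computed once per fold; every method therefore
    sees identical held-out pairs and identical shared fits.
    """
    for method in methods:
        if method not in METHODS:
            raise ValueError(f"unknown method {method!r}; choose from {METHODS}")
    if pairs is None:
        pairs = all_pairs(cohort) if exhaustive else draw_pairs(cohort, n_repeats, seed)
    rows = {m: [] for m in methods}
    err_by_class = {m: [np.empty(len(pairs)) for _ in range(2)] for m in methods}
    for r, pair in enumerate(pairs):
        held = list(pair)
        ws = _FoldWorkspace(cohort.drop_samples(held), cohort.subset(held), k)
        fit_seed = int(np.random.SeedSequence([seed, r]).generate_state(1)[0] % (2**31))
        for method in methods:
            predicted = _fit_and_predict(method, ws, rf_trees, fit_seed)
            for sid, pred in zip(held, predicted):
                truth = cohort.labels.loc[sid]
                err_by_class[method][cohort.classes.index(truth)][r] = float(pred != truth)
                rows[method].append(
                    {"repeat": r, "sample_id": sid, "true": truth, "predicted": pred}
                )
    out = {}
    for method in methods:
        err0, err1 = err_by_class[method]
        # one held-out sample per class per repeat, so the pooled balanced
        # error is the mean of the two per-class indicator means
        per_repeat = 0.5 * (err0 + err1)
        mean_error = float(0.5 * (err0.mean() + err1.mean()))
        lo, hi = _bootstrap_interval(err0, err1, seed)
        out[method] = EvaluationResult(
            method=method,
            per_repeat_errors=per_repeat,
            mean_error=mean_error,
            interval=(min(lo, mean_error), max(hi, mean_error)),
            n_repeats=len(pairs),
            seed=seed,
            held_out=pd.DataFrame(rows[method]),
        )
    return out


def within_stratum_evaluate(
    cohort: Cohort,
    variable: str,
    method: str,
    n_repeats: int = 200,
    seed: int = 0,
    k: int = 1000,
    rf_trees: int = 500,
) -> dict:
    """Run leave-two-out evaluation independently inside every level of a
    binary/categorical clinical variable.

    Levels where either prognosis class retains fewer than 3 samples are
    reported as not evaluable (value ``None``); the rest are computed.
    """
    spec = cohort.variable_specs.get(variable)
    if spec is not None and spec.kind == "continuous":
        raise CohortError(f"variable {variable!r} is continuous; need levels to split on")
    if variable not in cohort.clinical.columns:
        raise CohortError(f"variable {variable!r} not in clinical table")
    out = {}
    for level in pd.unique(cohort.clinical[variable]):
        ids = [s for s in cohort.sample_ids if cohort.clinical.at[s, variable] == level]
        sub_labels = cohort.labels.loc[ids]
        vc = sub_labels.value_counts()
        if any(vc.get(c, 0) < 3 for c in cohort.classes):
            out[level] = None
            continue
        sub = cohort.subset(ids)
        out[level] = leave_two_out_evaluate(
            sub, method, n_repeats=n_repeats, seed=seed, k=k, rf_trees=rf_trees
        )
    return out


def compare_methods(
    cohort: Cohort,
    n_repeats: int = 200,
    seed: int = 0,
    k: int = 1000,
    rf_trees: int = 500,
    methods: tuple = METHODS,
    exhaustive: bool = False,
) -> pd.DataFrame:
    """Evaluate the chosen methods on identical fold sequences and return
    one summary row per method."""
    pairs = all_pairs(cohort) if exhaustive else draw_pairs(cohort, n_repeats, seed)
    results = _evaluate_methods(
        cohort, tuple(methods), seed=seed, k=k, rf_trees=rf_trees, pairs=pairs
    )
    return pd.DataFrame([results[m].summary_row() for m in methods])
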