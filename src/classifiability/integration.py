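"""Integration baselines: pre-validation and random-forest fusion.

Pre-validation builds a leave-one-out, leakage-free DLDA decision score per
sample (each score comes from a model that never saw that sample) and lets it
compete with the clinical variables in a stepwise-AIC logistic regression.
The random-forest variant feeds the same pre-validated score plus the
indicator-expanded clinical table to a seeded forest.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier

from .classifiers import (
    StepwiseLogisticModel,
    build_design,
    fit_stepwise_logistic,
    loo_dlda_scores,
)
from .cohort import Cohort, CohortError

#: name under which the pre-validated score enters second-stage models
PREVALIDATED_SCORE = "prevalidated_score"


@dataclass
class PrevalidatedVector:
    """Per-sample leave-one-out DLDA decision scores.

    ``values[i]`` is the discriminant score (negative favours the first
    prognosis class) from the pipeline — gene selection and DLDA fit —
    trained on every sample except i. ``fold_map[i]`` lists i's training
    fold; it never contains i.
    """

    values: pd.Series
    fold_map: dict
    k: int
    classes: tuple

    def __post_init__(self):
        for sid, fold in self.fold_map.items():
            if sid in fold:
                raise CohortError(f"fold for {sid!r} contains the sample itself")


def prevalidated_vector(cohort: Cohort, k: int = 1000) -> PrevalidatedVector:
    """Construct the pre-validated decision vector by leave-one-out CV.

    The continuous discriminant score (not the hard label) is recorded: it
    preserves information for the downstream logistic fit and avoids ties.
    """
    counts = cohort.class_counts()
    for c, n in counts.items():
        if n < 3:
            raise CohortError(
                f"class {c!r} has {n} samples; leave-one-out refits need >=3"
            )
    scores = loo_dlda_scores(cohort.expression, cohort.labels, k=k, classes=cohort.classes)
    all_ids = cohort.sample_ids
    fold_map = {sid: tuple(s for s in all_ids if s != sid) for sid in all_ids}
    return PrevalidatedVector(scores, fold_map, k, cohort.classes)


def _augmented_clinical(
    prevec: PrevalidatedVector, clinical: pd.DataFrame
) -> tuple[pd.DataFrame, list]:
    clinical = clinical.loc[prevec.values.index]
    if PREVALIDATED_SCORE in clinical.columns:
        raise CohortError(f"clinical table already has a {PREVALIDATED_SCORE!r} column")
    aug = clinical.copy()
    aug[PREVALIDATED_SCORE] = prevec.values
    dropped = []
    if float(prevec.values.std(ddof=0)) == 0.0:
        warnings.warn(
            "pre-validated score is constant (no expression signal); "
            "dropping it from the candidate set",
            stacklevel=3,
        )
        aug = aug.drop(columns=[PREVALIDATED_SCORE])
        dropped.append(PREVALIDATED_SCORE)
    return aug, dropped


def fit_prevalidation(
    prevec: PrevalidatedVector,
    clinical: pd.DataFrame,
    labels: pd.Series,
    direction: str = "both",
) -> StepwiseLogisticModel:
    """Second-stage stepwise-AIC logistic over {pre-validated score} plus the
    clinical variables; the score competes like any other covariate."""
    aug, dropped = _augmented_clinical(prevec, clinical)
    model = fit_stepwise_logistic(
        aug, labels.loc[aug.index], direction=direction, classes=prevec.classes
    )
    model.dropped_constant.extend(dropped)
    return model


@dataclass
class RfIntegrationModel:
    """Seeded random forest over the pre-validated score + clinical data."""

    forest: RandomForestClassifier
    feature_names: list
    terms: dict
    classes: tuple
    n_trees: int
    seed: int

    def feature_matrix(self, prevec_values: pd.Series, clinical: pd.DataFrame) -> np.ndarray:
        clinical = clinical.loc[prevec_values.index]
        X, names, _ = build_design(
            clinical, [v for v in self.terms if v != PREVALIDATED_SCORE], terms=self.terms
        )
        X = X[:, 1:]  # the forest needs no intercept column
        return np.column_stack([prevec_values.to_numpy(dtype=float), X])


def fit_rf_integration(
    prevec: PrevalidatedVector,
    clinical: pd.DataFrame,
    labels: pd.Series,
    n_trees: int = 500,
    seed: int = 0,
) -> RfIntegrationModel:
    """Train a seeded random forest on the pre-validated score and the
    indicator-expanded clinical variables (sqrt(p) features per split)."""
    clinical = clinical.loc[prevec.values.index]
    labels = labels.loc[prevec.values.index]
    present = set(labels.unique())
    if len(present) < 2:
        raise CohortError("random forest needs both prognosis classes")
    X_clin, names, terms = build_design(clinical, list(clinical.columns))
    X = np.column_stack([prevec.values.to_numpy(dtype=float), X_clin[:, 1:]])
    y = (labels == prevec.classes[1]).to_numpy(dtype=int)
    forest = RandomForestClassifier(
        n_estimators=n_trees, max_features="sqrt", random_state=int(seed)
    )
    forest.fit(X, y)
    return RfIntegrationModel(
        forest=forest,
        feature_names=[PREVALIDATED_SCORE] + names[1:],
        terms=terms,
        classes=prevec.classes,
        n_trees=n_trees,
        seed=int(seed),
    )


def predict_rf(
    model: RfIntegrationModel, prevec_value: float, sample_clinical
) -> tuple:
    """Majority-vote label and positive-class vote fraction for one sample."""
    if isinstance(sample_clinical, Mapping):
        sample_clinical = pd.Series(sample_clinical)
    frame = sample_clinical.to_frame().T
    X, _, _ = build_design(
        frame, [v for v in model.terms], terms=model.terms
    )
    x = np.column_stack([[float(prevec_value)], X[:, 1:]])
    vote = float(model.forest.predict_proba(x)[0, 1])
    label = model.classes[1] if vote >= 0.5 else model.classes[0]
    return label, vote
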