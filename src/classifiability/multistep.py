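"""The multi-step classifier: route patients by predicted classifiability,
then apply the expression arm (easy group) or the clinical arm (hard group).

Fitting order: (1) leave-one-out error vector of the expression pipeline on
the training cohort; (2) smallest-AIC univariate classifiability model;
(3) easy/hard partition; (4) gene selection + DLDA refit on the easy group
only; (5) stepwise-AIC logistic on the hard group only. A group too small to
train on (fewer than 3 samples in either prognosis class) makes that arm
fall back to the full training cohort, with a recorded flag.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .classifiers import (
    DldaModel,
    StepwiseLogisticModel,
    fit_dlda,
    fit_stepwise_logistic,
    predict_dlda,
    predict_logistic,
    select_top_genes,
)
from .cohort import Cohort, CohortError
from .routing import (
    EASY,
    HARD,
    ClassifiabilityModel,
    loocv_error_vector,
    partition_cohort,
    select_classifiability_variable,
)

#: minimum training samples per prognosis class per arm
MIN_GROUP_CLASS_SIZE = 3


@dataclass
class MultiStepModel:
    """Classifiability router plus the two downstream arms."""

    classifiability: ClassifiabilityModel
    easy_model: DldaModel
    hard_model: StepwiseLogisticModel
    classes: tuple
    k: int
    fallbacks: dict = field(default_factory=dict)
    partition: pd.Series | None = None  # training-cohort assignment, for audit

    def to_dict(self) -> dict:
        return {
            "type": "multistep",
            "classes": list(self.classes),
            "k": self.k,
            "classifiability": self.classifiability.to_dict(),
            "easy_model": self.easy_model.to_dict(),
            "hard_model": self.hard_model.to_dict(),
            "fallbacks": dict(self.fallbacks),
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "MultiStepModel":
        return cls(
            classifiability=ClassifiabilityModel.from_dict(d["classifiability"]),
            easy_model=DldaModel.from_dict(d["easy_model"]),
            hard_model=StepwiseLogisticModel.from_dict(d["hard_model"]),
            classes=tuple(d["classes"]),
            k=int(d["k"]),
            fallbacks=dict(d.get("fallbacks", {})),
        )


def _trainable(labels: pd.Series, classes: tuple) -> bool:
    vc = labels.value_counts()
    return all(vc.get(c, 0) >= MIN_GROUP_CLASS_SIZE for c in classes)


def fit_multistep(
    cohort: Cohort,
    k: int = 1000,
    direction: str = "both",
    errors=None,
) -> MultiStepModel:
    """Fit the full multi-step pipeline on a training cohort.

    ``errors`` may carry a precomputed LOOCV error vector for this cohort
    (it is recomputed from scratch when omitted).
    """
    if errors is None:
        errors = loocv_error_vector(cohort, k=k)
    cls_model = select_classifiability_variable(
        errors, cohort.clinical, specs=cohort.variable_specs
    )
    assignment = partition_cohort(cls_model, cohort.clinical)

    fallbacks = {"easy": False, "hard": False}
    easy_ids = [s for s in cohort.sample_ids if assignment[s] == EASY]
    hard_ids = [s for s in cohort.sample_ids if assignment[s] == HARD]

    easy_labels = cohort.labels.loc[easy_ids]
    if not easy_ids or not _trainable(easy_labels, cohort.classes):
        fallbacks["easy"] = True
        easy_cohort = cohort
    else:
        easy_cohort = cohort.subset(easy_ids)
    genes = select_top_genes(
        easy_cohort.expression, easy_cohort.labels, k=k, classes=cohort.classes
    )
    easy_model = fit_dlda(
        easy_cohort.expression, easy_cohort.labels, genes, classes=cohort.classes
    )

    hard_labels = cohort.labels.loc[hard_ids]
    if not hard_ids or not _trainable(hard_labels, cohort.classes):
        fallbacks["hard"] = True
        hard_clinical = cohort.clinical
        hard_y = cohort.labels
    else:
        hard_clinical = cohort.clinical.loc[hard_ids]
        hard_y = cohort.labels.loc[hard_ids]
    with warnings.catch_warnings():
        # the routing variable is constant inside the hard group by
        # construction; its exclusion is recorded in dropped_constant
        warnings.filterwarnings("ignore", message="dropping constant candidate")
        hard_model = fit_stepwise_logistic(
            hard_clinical,
            hard_y,
            direction=direction,
            classes=cohort.classes,
            specs=cohort.variable_specs,
        )

    return MultiStepModel(
        classifiability=cls_model,
        easy_model=easy_model,
        hard_model=hard_model,
        classes=cohort.classes,
        k=k,
        fallbacks=fallbacks,
        partition=assignment,
    )


def predict_multistep(
    model: MultiStepModel, sample_expression, sample_clinical
) -> tuple:
    """Classify one test patient; returns ``(label, route, arm_score)``.

    The routing variable decides the arm: easy -> DLDA on the expression
    vector (score = discriminant difference), hard -> the clinical logistic
    model (score = positive-class probability).
    """
    if isinstance(sample_clinical, Mapping):
        sample_clinical = pd.Series(sample_clinical)
    frame = sample_clinical.to_frame().T
    route = partition_cohort(model.classifiability, frame).iloc[0]
    if route == EASY:
        label, score = predict_dlda(model.easy_model, sample_expression)
    else:
        label, score = predict_logistic(model.hard_model, sample_clinical)
    return label, route, score


def predict_multistep_table(
    model: MultiStepModel, expression: pd.DataFrame, clinical: pd.DataFrame
) -> pd.DataFrame:
    """Vectorized :func:`predict_multistep` over aligned expression columns
    and clinical rows; returns sample_id-indexed route/label/score."""
    from .classifiers import dlda_scores, predict_logistic_table

    if list(expression.columns) != list(clinical.index):
        clinical = clinical.loc[list(expression.columns)]
    route = partition_cohort(model.classifiability, clinical)
    labels = pd.Series(index=clinical.index, dtype=object)
    scores = pd.Series(index=clinical.index, dtype=float)
    easy_ids = route.index[route == EASY]
    hard_ids = route.index[route == HARD]
    if len(easy_ids):
        X = expression.loc[list(model.easy_model.genes), easy_ids].to_numpy(dtype=float)
        s = dlda_scores(model.easy_model, X)
        labels.loc[easy_ids] = np.where(s <= 0, model.classes[0], model.classes[1])
        scores.loc[easy_ids] = s
    if len(hard_ids):
        table = predict_logistic_table(model.hard_model, clinical.loc[hard_ids])
        labels.loc[hard_ids] = table["predicted_label"]
        scores.loc[hard_ids] = table["probability"]
    return pd.DataFrame(
        {"route": route, "predicted_label": labels, "arm_score": scores}
    )
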