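"""Classifiability modeling: which patients can the expression biomarker
classify?

The per-patient leave-one-out error of the expression classifier is treated
as a binary response and regressed, one clinical variable at a time, with
logistic regression. The variable whose univariate model has the smallest
AIC becomes the routing variable: patients with predicted error probability
below the threshold are "easy to classify" (expression data informative),
the rest "hard to classify".
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from ._glm import LogisticFit, fit_logistic
from .classifiers import _Term, build_design, loo_dlda_scores
from .cohort import ClinicalVariableSpec, Cohort, CohortError, infer_specs

EASY, HARD = "easy", "hard"


@dataclass
class ErrorVector:
    """Per-sample binary LOOCV misclassification indicator (1 = error)."""

    errors: pd.Series
    scheme: dict = field(default_factory=dict)

    def __post_init__(self):
        vals = set(self.errors.unique().tolist())
        if not vals <= {0, 1}:
            raise CohortError(f"error vector must be 0/1, got {sorted(vals)}")


def loocv_error_vector(cohort: Cohort, k: int = 1000) -> ErrorVector:
    """LOOCV per-patient errors of the expression pipeline (gene selection
    and DLDA both redone without the held-out sample).

    Definitionally identical to thresholding the pre-validated decision
    vector: error[i] = 1 iff the sign of the leave-one-out score disagrees
    with sample i's class (score <= 0 predicts the first listed class).
    """
    scores = loo_dlda_scores(cohort.expression, cohort.labels, k=k, classes=cohort.classes)
    predicted = np.where(scores.to_numpy() <= 0, cohort.classes[0], cohort.classes[1])
    errors = (predicted != cohort.labels.to_numpy()).astype(int)
    return ErrorVector(
        errors=pd.Series(errors, index=scores.index, name="loocv_error"),
        scheme={"cv": "loocv", "classifier": "dlda", "k": k},
    )


@dataclass
class ClassifiabilityModel:
    """Univariate logistic model of LOOCV error on one clinical variable."""

    variable: str | None
    fit: LogisticFit | None
    term: _Term | None
    aic_table: pd.Series
    threshold: float = 0.5
    degenerate: str | None = None   # None | "all_easy" | "all_hard"

    def predict_error_probability(self, clinical: pd.DataFrame) -> pd.Series:
        if self.degenerate == "all_easy":
            return pd.Series(0.0, index=clinical.index)
        if self.degenerate == "all_hard":
            return pd.Series(1.0, index=clinical.index)
        X, _, _ = build_design(clinical, [self.variable], terms={self.variable: self.term})
        return pd.Series(self.fit.predict_proba(X), index=clinical.index)

    def to_dict(self) -> dict:
        d = {
            "type": "classifiability",
            "variable": self.variable,
            "threshold": self.threshold,
            "degenerate": self.degenerate,
            "aic_table": {str(k): float(v) for k, v in self.aic_table.items()},
        }
        if self.fit is not None:
            d["coef"] = self.fit.coef.tolist()
            d["term"] = {"kind": self.term.kind, "levels": list(self.term.levels)}
            d["separation"] = self.fit.separation
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "ClassifiabilityModel":
        fit = None
        term = None
        if "coef" in d:
            fit = LogisticFit(
                coef=np.asarray(d["coef"], dtype=float),
                loglik=float("nan"),
                converged=True,
                separation=bool(d.get("separation", False)),
                n_iter=0,
            )
            term = _Term(d["variable"], d["term"]["kind"], tuple(d["term"]["levels"]))
        return cls(
            variable=d["variable"],
            fit=fit,
            term=term,
            aic_table=pd.Series(d.get("aic_table", {}), dtype=float),
            threshold=float(d.get("threshold", 0.5)),
            degenerate=d.get("degenerate"),
        )


def select_classifiability_variable(
    errors: ErrorVector,
    clinical: pd.DataFrame,
    specs: Mapping[str, ClinicalVariableSpec] | None = None,
    threshold: float = 0.5,
) -> ClassifiabilityModel:
    """Fit ``error ~ variable`` separately for every clinical variable and
    keep the smallest-AIC model; the full AIC table is retained for audit.

    An all-zero (or all-one) error vector admits no model: a flagged
    degenerate result routes every patient easy (respectively hard).
    """
    clinical = clinical.loc[errors.errors.index]
    y = errors.errors.to_numpy(dtype=float)
    if y.sum() == 0:
        return ClassifiabilityModel(None, None, None, pd.Series(dtype=float),
                                    threshold, degenerate="all_easy")
    if y.sum() == len(y):
        return ClassifiabilityModel(None, None, None, pd.Series(dtype=float),
                                    threshold, degenerate="all_hard")
    specs = dict(specs or infer_specs(clinical))
    aics, fits, terms = {}, {}, {}
    for var in clinical.columns:
        if clinical[var].nunique(dropna=True) <= 1:
            continue  # constant column carries no routing information
        X, _, tm = build_design(clinical, [var], specs)
        fit = fit_logistic(X, y)
        aics[var] = fit.aic
        fits[var] = fit
        terms[var] = tm[var]
    if not aics:
        raise CohortError("no usable clinical variable for classifiability")
    aic_table = pd.Series(aics, name="aic")
    best = min(aics, key=lambda v: (aics[v],))  # insertion order breaks ties
    return ClassifiabilityModel(best, fits[best], terms[best], aic_table, threshold)


def partition_cohort(model: ClassifiabilityModel, clinical: pd.DataFrame) -> pd.Series:
    """Assign each sample ``easy`` or ``hard``: hard iff the predicted error
    probability is at or above the model threshold."""
    prob = model.predict_error_probability(clinical)
    assignment = np.where(prob >= model.threshold, HARD, EASY)
    return pd.Series(assignment, index=clinical.index, name="classifiability")
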