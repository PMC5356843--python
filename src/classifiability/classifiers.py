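"""Single-source biomarkers.

Expression arm: fold-change gene selection followed by diagonal linear
discriminant analysis (DLDA) — nearest centroid with per-gene pooled
variances and class priors. Clinical arm: logistic regression with
stepwise-AIC variable selection, categorical variables entering and leaving
as whole indicator blocks.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit

from ._glm import LogisticFit, fit_logistic
from .cohort import ClinicalVariableSpec, CohortError, infer_specs

#: relative floor for degenerate (zero) pooled variances
VARIANCE_FLOOR_FACTOR = 1e-8


def _classes_in_order(labels: pd.Series, classes: tuple | None) -> tuple:
    if classes is None:
        classes = tuple(pd.unique(labels))
    if len(classes) != 2:
        raise CohortError(f"need exactly 2 classes, got {classes}")
    present = set(labels.unique())
    missing = [c for c in classes if c not in present]
    if missing:
        raise CohortError(f"class {missing[0]!r} absent from labels")
    if present - set(classes):
        raise CohortError("labels contain levels outside the declared classes")
    return tuple(classes)


# ---------------------------------------------------------------------------
# gene selection + DLDA
# ---------------------------------------------------------------------------

def select_top_genes(
    expression: pd.DataFrame,
    labels: pd.Series,
    k: int = 1000,
    classes: tuple | None = None,
) -> list:
    """Return the ``k`` gene ids with largest absolute log fold change.

    Fold change is the absolute difference of class mean expression on the
    (already log) scale. Order is descending; ties break by input gene order
    (stable sort). If fewer than ``k`` genes exist, all are returned.
    """
    classes = _classes_in_order(labels.loc[expression.columns], classes)
    y = labels.loc[expression.columns].to_numpy()
    X = expression.to_numpy(dtype=float)
    diff = X[:, y == classes[0]].mean(axis=1) - X[:, y == classes[1]].mean(axis=1)
    order = np.argsort(-np.abs(diff), kind="stable")[: min(k, X.shape[0])]
    return [expression.index[i] for i in order]


@dataclass
class DldaModel:
    """Diagonal LDA over a selected gene set.

    ``means`` has one row per class (ordered as ``class_labels``); the pooled
    within-class variance is shared between classes and floored so degenerate
    genes cannot yield infinite discriminant terms.
    """

    genes: list
    class_labels: tuple
    means: np.ndarray          # (2, n_genes)
    pooled_var: np.ndarray     # (n_genes,)
    priors: np.ndarray         # (2,)
    floor_applied: bool = False

    def to_dict(self) -> dict:
        return {
            "type": "dlda",
            "genes": list(self.genes),
            "class_labels": list(self.class_labels),
            "means": self.means.tolist(),
            "pooled_var": self.pooled_var.tolist(),
            "priors": self.priors.tolist(),
            "floor_applied": self.floor_applied,
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "DldaModel":
        return cls(
            genes=list(d["genes"]),
            class_labels=tuple(d["class_labels"]),
            means=np.asarray(d["means"], dtype=float),
            pooled_var=np.asarray(d["pooled_var"], dtype=float),
            priors=np.asarray(d["priors"], dtype=float),
            floor_applied=bool(d.get("floor_applied", False)),
        )


def _floor_variances(pooled: np.ndarray) -> tuple[np.ndarray, bool]:
    positive = pooled[pooled > 0]
    scale = float(np.median(positive)) if positive.size else 1.0
    floor = VARIANCE_FLOOR_FACTOR * scale
    if np.any(pooled < floor):
        return np.maximum(pooled, floor), True
    return pooled, False


def fit_dlda(
    expression: pd.DataFrame,
    labels: pd.Series,
    genes: Sequence,
    classes: tuple | None = None,
) -> DldaModel:
    """Fit DLDA on ``genes``: per-class means, pooled per-gene variance
    (within-class sums of squares over n - 2) and empirical class priors."""
    missing = [g for g in genes if g not in expression.index]
    if missing:
        raise CohortError(f"selected gene(s) absent from matrix: {missing[:5]}")
    classes = _classes_in_order(labels.loc[expression.columns], classes)
    X = expression.loc[list(genes)].to_numpy(dtype=float)
    y = labels.loc[expression.columns].to_numpy()
    masks = [y == c for c in classes]
    n = X.shape[1]
    for c, m in zip(classes, masks):
        if m.sum() < 2:
            raise CohortError(f"class {c!r} needs >=2 samples to fit DLDA")
    means = np.vstack([X[:, m].mean(axis=1) for m in masks])
    ss = sum(((X[:, m] - means[i][:, None]) ** 2).sum(axis=1) for i, m in enumerate(masks))
    pooled = ss / (n - 2)
    pooled, floored = _floor_variances(pooled)
    priors = np.array([m.sum() / n for m in masks])
    return DldaModel(list(genes), classes, means, pooled, priors, floored)


def dlda_scores(model: DldaModel, X: np.ndarray) -> np.ndarray:
    """Discriminant score D_first - D_second for columns of ``X``
    (genes x samples, rows ordered as ``model.genes``); negative favours the
    first listed class."""
    d = []
    for i in range(2):
        dev = (X - model.means[i][:, None]) ** 2 / model.pooled_var[:, None]
        d.append(dev.sum(axis=0) - 2.0 * np.log(model.priors[i]))
    return d[0] - d[1]


def predict_dlda(model: DldaModel, sample_expression) -> tuple:
    """Classify one sample; returns ``(label, score)``.

    ``score`` is D_first - D_second; a score of exactly 0 is a tie, broken
    toward the first listed class.
    """
    if isinstance(sample_expression, pd.DataFrame):
        x = sample_expression.loc[list(model.genes)].to_numpy(dtype=float)
    elif isinstance(sample_expression, pd.Series):
        missing = [g for g in model.genes if g not in sample_expression.index]
        if missing:
            raise CohortError(f"sample lacks model gene(s): {missing[:5]}")
        x = sample_expression.loc[list(model.genes)].to_numpy(dtype=float)[:, None]
    else:
        x = np.asarray(sample_expression, dtype=float).reshape(len(model.genes), -1)
    if np.isnan(x).any():
        raise CohortError("missing expression value for a model gene")
    score = float(dlda_scores(model, x)[0])
    label = model.class_labels[0] if score <= 0 else model.class_labels[1]
    return label, score


def loo_dlda_scores(
    expression: pd.DataFrame,
    labels: pd.Series,
    k: int = 1000,
    classes: tuple | None = None,
) -> pd.Series:
    """Leave-one-out DLDA score for every sample, with gene selection redone
    inside each fold.

    For each sample i the top-``k`` fold-change genes are re-selected and the
    DLDA refit on all other samples; the returned value is the discriminant
    score D_first - D_second for sample i (negative favours the first class).
    Implemented with rank-one updates of the class sufficient statistics so
    the whole vector costs O(n * p log p).
    """
    classes = _classes_in_order(labels.loc[expression.columns], classes)
    X = expression.to_numpy(dtype=float)
    y = labels.loc[expression.columns].to_numpy()
    p, n = X.shape
    masks = [(y == c).astype(float) for c in classes]
    counts = np.array([m.sum() for m in masks])
    if counts.min() < 3:
        # removing one sample must leave >=2 per class for a pooled variance
        raise CohortError("leave-one-out DLDA needs >=3 samples per class")
    kk = min(k, p)
    Xt = X.T                                       # (n, p)
    X2t = Xt * Xt
    # leave-one-out sufficient statistics, one row per held-out sample,
    # via masked matrix products: row i sums over {j : label_j == c, j != i}
    # with a literal zero weight at j == i, so the float summation order for
    # row i is independent of sample i's own label (bitwise leakage freedom)
    off_diag = 1.0 - np.eye(n)
    W0 = masks[0][None, :] * off_diag              # (n, n)
    W1 = masks[1][None, :] * off_diag
    n0 = counts[0] - masks[0][:, None]             # (n, 1)
    n1 = counts[1] - masks[1][:, None]
    s0, s1 = W0 @ Xt, W1 @ Xt                      # (n, p)
    q0, q1 = W0 @ X2t, W1 @ X2t
    mean0, mean1 = s0 / n0, s1 / n1
    # only set membership of the top-k genes affects the discriminant sum,
    # so an unordered top-k partition suffices here (ties at the boundary
    # are measure-zero for continuous expression data)
    absdiff = np.abs(mean0 - mean1)
    if kk < p:
        sel = np.argpartition(absdiff, p - kk, axis=1)[:, p - kk:]
    else:
        sel = np.broadcast_to(np.arange(p), (n, p))
    ss = (q0 - s0**2 / n0) + (q1 - s1**2 / n1)
    pooled = np.take_along_axis(ss, sel, axis=1) / (n - 1 - 2)
    if not (pooled.min() >= VARIANCE_FLOOR_FACTOR * pooled.max() and pooled.min() > 0):
        positive = np.where(pooled > 0, pooled, np.nan)
        with np.errstate(all="ignore"):
            med = np.nanmedian(positive, axis=1)
        floor = VARIANCE_FLOOR_FACTOR * np.where(np.isnan(med), 1.0, med)
        pooled = np.maximum(pooled, floor[:, None])
    xsel = np.take_along_axis(Xt, sel, axis=1)
    d0 = ((xsel - np.take_along_axis(mean0, sel, axis=1)) ** 2 / pooled).sum(axis=1)
    d1 = ((xsel - np.take_along_axis(mean1, sel, axis=1)) ** 2 / pooled).sum(axis=1)
    prior_term = 2.0 * (np.log(n0[:, 0] / (n - 1)) - np.log(n1[:, 0] / (n - 1)))
    scores = d0 - d1 - prior_term
    return pd.Series(scores, index=expression.columns, name="dlda_score")


# ---------------------------------------------------------------------------
# design matrices for clinical tables
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class _Term:
    variable: str
    kind: str
    levels: tuple  # levels captured at fit time; () for continuous

    @property
    def names(self) -> list[str]:
        if self.kind == "continuous":
            return [self.variable]
        return [f"{self.variable}[{lv}]" for lv in self.levels[1:]]

    def columns(self, values: pd.Series) -> np.ndarray:
        if self.kind == "continuous":
            col = pd.to_numeric(values, errors="coerce").to_numpy(dtype=float)
            if np.isnan(col).any():
                raise CohortError(f"missing/non-numeric value for {self.variable!r}")
            return col[:, None]
        known = set(self.levels)
        unseen = [v for v in pd.unique(values.dropna()) if v not in known]
        if unseen:
            raise CohortError(
                f"unseen level {unseen[0]!r} for variable {self.variable!r}"
            )
        if values.isna().any():
            raise CohortError(f"missing value for {self.variable!r}")
        return np.column_stack(
            [(values == lv).to_numpy(dtype=float) for lv in self.levels[1:]]
        )


def _make_term(name: str, column: pd.Series, spec: ClinicalVariableSpec | None) -> _Term:
    if spec is None:
        from .cohort import infer_variable_spec

        spec = infer_variable_spec(name, column)
    if spec.kind == "continuous":
        return _Term(name, "continuous", ())
    observed = tuple(lv for lv in spec.levels if (column == lv).any())
    levels = observed if len(observed) >= 1 else spec.levels
    if len(levels) < 2:
        levels = spec.levels  # constant column -> all-zero indicator
    return _Term(name, spec.kind, levels)


def build_design(
    clinical: pd.DataFrame,
    variables: Sequence[str],
    specs: Mapping[str, ClinicalVariableSpec] | None = None,
    terms: Mapping[str, _Term] | None = None,
) -> tuple[np.ndarray, list[str], dict]:
    """Expand ``variables`` into an intercept-first design matrix.

    Returns ``(X, column_names, terms)``; pass ``terms`` back in at predict
    time so indicator coding reuses fit-time levels (unseen levels raise).
    """
    specs = specs or {}
    cols = [np.ones((len(clinical), 1))]
    names = ["intercept"]
    out_terms: dict[str, _Term] = {}
    for var in variables:
        if var not in clinical.columns:
            raise CohortError(f"variable {var!r} not in clinical table")
        term = (terms or {}).get(var) or _make_term(var, clinical[var], specs.get(var))
        out_terms[var] = term
        cols.append(term.columns(clinical[var]))
        names.extend(term.names)
    return np.hstack(cols), names, out_terms


# ---------------------------------------------------------------------------
# stepwise-AIC logistic regression
# ---------------------------------------------------------------------------

@dataclass
class StepwiseLogisticModel:
    """Logistic model after stepwise-AIC selection on clinical variables."""

    selected_variables: list
    coefficients: dict            # column name -> value, incl. "intercept"
    aic: float
    classes: tuple                # (negative, positive); positive is modeled
    terms: dict = field(default_factory=dict)   # variable -> _Term
    separation: bool = False
    dropped_constant: list = field(default_factory=list)
    aic_trace: list = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "type": "stepwise_logistic",
            "selected_variables": list(self.selected_variables),
            "coefficients": dict(self.coefficients),
            "aic": self.aic,
            "classes": list(self.classes),
            "terms": {
                v: {"kind": t.kind, "levels": list(t.levels)}
                for v, t in self.terms.items()
            },
            "separation": self.separation,
            "dropped_constant": list(self.dropped_constant),
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "StepwiseLogisticModel":
        terms = {
            v: _Term(v, t["kind"], tuple(t["levels"])) for v, t in d["terms"].items()
        }
        return cls(
            selected_variables=list(d["selected_variables"]),
            coefficients=dict(d["coefficients"]),
            aic=float(d["aic"]),
            classes=tuple(d["classes"]),
            terms=terms,
            separation=bool(d.get("separation", False)),
            dropped_constant=list(d.get("dropped_constant", [])),
        )


def _fit_subset(clinical, y, variables, specs) -> tuple[LogisticFit, list, dict]:
    X, names, terms = build_design(clinical, variables, specs)
    fit = fit_logistic(X, y)
    return fit, names, terms


class _DesignCache:
    """Per-variable design blocks, expanded once per stepwise search."""

    def __init__(self, clinical, candidates, specs):
        n = len(clinical)
        self.intercept = np.ones((n, 1))
        self.blocks, self.names, self.terms = {}, {}, {}
        for var in candidates:
            term = _make_term(var, clinical[var], specs.get(var))
            self.blocks[var] = term.columns(clinical[var])
            self.names[var] = term.names
            self.terms[var] = term

    def matrix(self, variables):
        cols = [self.intercept] + [self.blocks[v] for v in variables]
        names = ["intercept"]
        for v in variables:
            names.extend(self.names[v])
        return np.hstack(cols), names


def fit_stepwise_logistic(
    clinical: pd.DataFrame,
    labels: pd.Series,
    direction: str = "both",
    classes: tuple | None = None,
    specs: Mapping[str, ClinicalVariableSpec] | None = None,
) -> StepwiseLogisticModel:
    """Stepwise-AIC logistic regression of the positive class on clinical
    variables.

    ``both``/``forward`` start from the intercept-only model, ``backward``
    from the full model; each step applies the single add/drop that most
    decreases AIC and the search stops when no move improves it. Constant
    (zero-variance) candidates are dropped up front with a warning.
    """
    if direction not in {"both", "forward", "backward"}:
        raise ValueError(f"unknown direction {direction!r}")
    clinical = clinical.loc[labels.index] if not clinical.index.equals(labels.index) else clinical
    if clinical.isna().any().any():
        raise CohortError("stepwise logistic requires complete clinical data")
    classes = _classes_in_order(labels, classes)
    y = (labels == classes[1]).to_numpy(dtype=float)
    specs = dict(specs or infer_specs(clinical))

    candidates, dropped = [], []
    for var in clinical.columns:
        if clinical[var].nunique(dropna=True) <= 1:
            dropped.append(var)
        else:
            candidates.append(var)
    if dropped:
        warnings.warn(
            f"dropping constant candidate variable(s): {dropped}", stacklevel=2
        )

    cache = _DesignCache(clinical, candidates, specs)
    current = list(candidates) if direction == "backward" else []

    def fit_subset(subset, beta0=None):
        X, names = cache.matrix(subset)
        return fit_logistic(X, y, beta0=beta0), names

    def warm_start(fit, subset, add=None, drop=None):
        # pad with zeros for an added block / cut a dropped block; the
        # current fit is a near-optimal Newton start for its neighbours
        widths = [1] + [len(cache.names[v]) for v in subset]
        if add is not None:
            return np.concatenate([fit.coef, np.zeros(len(cache.names[add]))])
        pos = 1 + subset.index(drop)
        start = sum(widths[:pos])
        return np.delete(fit.coef, slice(start, start + widths[pos]))

    fit, names = fit_subset(current)
    aic = fit.aic
    trace = [(tuple(current), aic)]
    while True:
        moves: list[tuple[list, np.ndarray]] = []
        if direction in {"both", "forward"}:
            moves += [
                (current + [v], warm_start(fit, current, add=v))
                for v in candidates
                if v not in current
            ]
        if direction in {"both", "backward"} and current:
            moves += [
                ([v for v in current if v != drop], warm_start(fit, current, drop=drop))
                for drop in current
            ]
        best = None
        for subset, beta0 in moves:
            f, nm = fit_subset(subset, beta0=beta0)
            if best is None or f.aic < best[0] - 1e-12:
                best = (f.aic, subset, f, nm)
        if best is None or best[0] >= aic - 1e-10:
            break
        aic, current, fit, names = best
        trace.append((tuple(current), aic))

    coefficients = dict(zip(names, fit.coef.tolist()))
    return StepwiseLogisticModel(
        selected_variables=list(current),
        coefficients=coefficients,
        aic=float(aic),
        classes=classes,
        terms={v: cache.terms[v] for v in current},
        separation=fit.separation,
        dropped_constant=dropped,
        aic_trace=trace,
    )


def _logistic_prob(model: StepwiseLogisticModel, clinical: pd.DataFrame) -> np.ndarray:
    X, names, _ = build_design(
        clinical, model.selected_variables, terms=model.terms
    )
    beta = np.array([model.coefficients[nm] for nm in names])
    return expit(X @ beta)


def predict_logistic(
    model: StepwiseLogisticModel,
    sample_clinical,
    threshold: float = 0.5,
) -> tuple:
    """Return ``(label, probability)`` for one sample record (Mapping or
    Series); probability is for the positive class, assigned when
    ``probability >= threshold``."""
    if isinstance(sample_clinical, Mapping):
        sample_clinical = pd.Series(sample_clinical)
    frame = sample_clinical.to_frame().T
    prob = float(_logistic_prob(model, frame)[0])
    label = model.classes[1] if prob >= threshold else model.classes[0]
    return label, prob


def predict_logistic_table(
    model: StepwiseLogisticModel,
    clinical: pd.DataFrame,
    threshold: float = 0.5,
) -> pd.DataFrame:
    """Vectorized :func:`predict_logistic` over a clinical table."""
    prob = _logistic_prob(model, clinical)
    labels = np.where(prob >= threshold, model.classes[1], model.classes[0])
    return pd.DataFrame(
        {"predicted_label": labels, "probability": prob}, index=clinical.index
    )
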