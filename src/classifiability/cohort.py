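"""Cohort data model and delimited-text I/O.

A cohort bundles a log-scale expression matrix (genes x samples), a clinical
table (samples x variables) and a binary prognosis label per sample. Clinical
variables are kept in their source encoding; categorical expansion to
indicator columns happens only inside model fitting.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: strings treated as missing in clinical tables (case-insensitive "NA"
#: handled at read time; empty cells become NaN via pandas)
NA_STRINGS = ["", "NA", "na", "Na", "nA", "NaN", "nan"]

VALID_KINDS = ("binary", "categorical", "continuous")


class CohortError(ValueError):
    """Raised for invalid or inconsistent cohort inputs."""


@dataclass(frozen=True)
class ClinicalVariableSpec:
    """Type information for one clinical variable.

    Parameters
    ----------
    name : str
        Column name in the clinical table.
    kind : str
        One of ``binary``, ``categorical``, ``continuous``.
    levels : tuple
        Ordered observed levels (empty for continuous variables).
    n_missing : int
        Count of missing entries at the time the spec was built.
    """

    name: str
    kind: str
    levels: tuple = ()
    n_missing: int = 0

    def __post_init__(self):
        if self.kind not in VALID_KINDS:
            raise CohortError(f"unknown variable kind {self.kind!r} for {self.name!r}")
        if self.kind == "binary" and len(self.levels) != 2:
            raise CohortError(
                f"binary variable {self.name!r} must have exactly 2 levels, "
                f"got {list(self.levels)}"
            )
        if self.kind == "categorical" and len(self.levels) < 2:
            raise CohortError(
                f"categorical variable {self.name!r} needs >=2 levels, "
                f"got {list(self.levels)}"
            )


def infer_variable_spec(name: str, column: pd.Series, kind: str | None = None) -> ClinicalVariableSpec:
    """Infer (or validate) the spec for one clinical column.

    Inference rule: <=2 distinct non-missing values -> binary; non-numeric
    -> categorical; otherwise continuous.
    """
    observed = column.dropna()
    numeric = pd.api.types.is_numeric_dtype(observed)
    if kind is None:
        if observed.nunique() <= 2:
            kind = "binary"
        elif not numeric:
            kind = "categorical"
        else:
            kind = "continuous"
    if kind == "continuous":
        if not numeric:
            raise CohortError(f"variable {name!r} declared continuous but is non-numeric")
        return ClinicalVariableSpec(name, "continuous", (), int(column.isna().sum()))
    levels = tuple(sorted(observed.unique().tolist(), key=lambda v: (str(type(v)), v)))
    if kind == "binary" and len(levels) == 1:
        # constant column: keep as binary with a synthetic complement level so
        # downstream code can treat it uniformly; it carries no information
        levels = (levels[0], f"__not_{levels[0]}__") if levels else ("0", "1")
    return ClinicalVariableSpec(name, kind, levels, int(column.isna().sum()))


def infer_specs(
    clinical: pd.DataFrame, declared: Mapping[str, str] | None = None
) -> dict[str, ClinicalVariableSpec]:
    """Build specs for every clinical column, honouring declared kinds."""
    declared = declared or {}
    for name in declared:
        if name not in clinical.columns:
            raise CohortError(f"declared variable {name!r} not in clinical table")
    return {
        name: infer_variable_spec(name, clinical[name], declared.get(name))
        for name in clinical.columns
    }


@dataclass(frozen=True)
class Cohort:
    """Aligned expression matrix, clinical table and prognosis labels.

    ``classes`` orders the two prognosis levels; the second entry is the
    positive (event / poor-prognosis) class. Expression columns, clinical
    rows and labels share the same sample order.
    """

    expression: pd.DataFrame
    clinical: pd.DataFrame
    labels: pd.Series
    classes: tuple
    variable_specs: dict = field(default_factory=dict)

    def __post_init__(self):
        expr, clin, labels = self.expression, self.clinical, self.labels
        if not (list(expr.columns) == list(clin.index) == list(labels.index)):
            raise CohortError("expression columns, clinical rows and labels must align")
        if expr.columns.has_duplicates:
            raise CohortError("duplicate sample ids")
        if expr.index.has_duplicates:
            raise CohortError("duplicate gene ids")
        if len(self.classes) != 2:
            raise CohortError(f"need exactly 2 prognosis classes, got {self.classes}")
        counts = labels.value_counts()
        for c in self.classes:
            if counts.get(c, 0) == 0:
                raise CohortError(f"prognosis class {c!r} has no samples")
        bad = set(labels.unique()) - set(self.classes)
        if bad:
            raise CohortError(f"labels contain unknown level(s): {sorted(map(str, bad))}")
        if expr.isna().any().any():
            raise CohortError("expression matrix contains missing values")
        if not self.variable_specs:
            object.__setattr__(self, "variable_specs", infer_specs(clin))

    # -- convenience views -------------------------------------------------
    @property
    def sample_ids(self) -> list:
        return list(self.expression.columns)

    @property
    def gene_ids(self) -> list:
        return list(self.expression.index)

    @property
    def n_samples(self) -> int:
        return self.expression.shape[1]

    @property
    def n_genes(self) -> int:
        return self.expression.shape[0]

    def class_counts(self) -> dict:
        vc = self.labels.value_counts()
        return {c: int(vc.get(c, 0)) for c in self.classes}

    @classmethod
    def _unchecked(cls, expression, clinical, labels, classes, variable_specs) -> "Cohort":
        # fast path for subsetting an already-validated cohort
        obj = object.__new__(cls)
        object.__setattr__(obj, "expression", expression)
        object.__setattr__(obj, "clinical", clinical)
        object.__setattr__(obj, "labels", labels)
        object.__setattr__(obj, "classes", classes)
        object.__setattr__(obj, "variable_specs", variable_specs)
        return obj

    def subset(self, sample_ids: Sequence) -> "Cohort":
        """Return the cohort restricted to ``sample_ids`` (given order kept)."""
        sample_ids = list(sample_ids)
        missing = set(sample_ids) - set(self.sample_ids)
        if missing:
            raise CohortError(f"unknown sample ids: {sorted(map(str, missing))}")
        return Cohort._unchecked(
            expression=self.expression[sample_ids],
            clinical=self.clinical.loc[sample_ids],
            labels=self.labels.loc[sample_ids],
            classes=self.classes,
            variable_specs=dict(self.variable_specs),
        )

    def drop_samples(self, sample_ids: Sequence) -> "Cohort":
        drop = set(sample_ids)
        return self.subset([s for s in self.sample_ids if s not in drop])


@dataclass(frozen=True)
class MissingnessReport:
    """What :func:`apply_missingness_policy` removed."""

    dropped_variables: tuple
    dropped_samples: tuple
    max_missing: int


def _read_table(path: Path, index_col: int = 0) -> pd.DataFrame:
    sep = "\t" if path.suffix.lower() in {".tsv", ".txt"} else ","
    return pd.read_csv(
        path, sep=sep, index_col=index_col, na_values=NA_STRINGS, keep_default_na=False
    )


def read_cohort(
    expression_path: str | Path,
    clinical_path: str | Path,
    label_column: str,
    positive_label,
    declared_kinds: Mapping[str, str] | None = None,
) -> Cohort:
    """Read a cohort from two delimited files.

    ``expression_path``: genes x samples, gene ids in the first column,
    header row of sample ids. ``clinical_path``: samples x variables, sample
    ids in the first column; must contain ``label_column``, which is removed
    from the clinical table and stored as the prognosis labels. Samples are
    the intersection of the two files, in expression-file order.
    """
    expression_path, clinical_path = Path(expression_path), Path(clinical_path)
    expr = _read_table(expression_path)
    clin = _read_table(clinical_path)

    if expr.index.has_duplicates:
        dups = expr.index[expr.index.duplicated()].unique().tolist()
        raise CohortError(f"duplicate gene ids in {expression_path.name}: {dups[:5]}")
    if expr.columns.has_duplicates or clin.index.has_duplicates:
        raise CohortError("duplicate sample ids")
    if label_column not in clin.columns:
        raise CohortError(f"label column {label_column!r} not in {clinical_path.name}")

    # expression must be fully numeric; name the first offending cell
    for col in expr.columns:
        if not pd.api.types.is_numeric_dtype(expr[col]):
            coerced = pd.to_numeric(expr[col], errors="coerce")
            bad = expr.index[coerced.isna() & expr[col].notna()]
            row = bad[0] if len(bad) else expr.index[expr[col].isna()][0]
            raise CohortError(
                f"non-numeric expression value at gene {row!r}, sample {col!r}"
            )
    if expr.isna().any().any():
        gene = expr.index[expr.isna().any(axis=1)][0]
        raise CohortError(f"missing expression value at gene {gene!r}")

    shared = [s for s in expr.columns if s in set(clin.index)]
    if not shared:
        raise CohortError("no samples shared between expression and clinical files")
    n_expr_only = expr.shape[1] - len(shared)
    n_clin_only = clin.shape[0] - len(shared)
    if n_expr_only or n_clin_only:
        logger.warning(
            "sample sets differ: %d expression-only and %d clinical-only samples dropped",
            n_expr_only,
            n_clin_only,
        )
        warnings.warn(
            f"sample sets differ; keeping {len(shared)} shared samples", stacklevel=2
        )
    expr = expr[shared]
    clin = clin.loc[shared]

    labels = clin[label_column]
    if labels.isna().any():
        raise CohortError("missing prognosis labels are not allowed")
    levels = set(labels.unique())
    if positive_label not in levels:
        raise CohortError(
            f"positive label {positive_label!r} absent from {label_column!r} "
            f"(levels: {sorted(map(str, levels))})"
        )
    extra = levels - {positive_label}
    if len(extra) != 1:
        raise CohortError(
            f"label column {label_column!r} must have exactly 2 levels; "
            f"found {sorted(map(str, levels))}"
        )
    negative_label = extra.pop()
    clin = clin.drop(columns=[label_column])

    return Cohort(
        expression=expr,
        clinical=clin,
        labels=labels,
        classes=(negative_label, positive_label),
        variable_specs=infer_specs(clin, declared_kinds),
    )


def apply_missingness_policy(
    cohort: Cohort, max_missing: int = 5
) -> tuple[Cohort, MissingnessReport]:
    """Apply the missing-data selection rule.

    Clinical variables missing in more than ``max_missing`` samples are
    dropped; afterwards every sample with any remaining missing clinical
    entry is removed. Expression and labels are subset consistently.
    """
    clin = cohort.clinical
    n_missing = clin.isna().sum()
    dropped_vars = tuple(n_missing.index[n_missing > max_missing])
    kept = clin.drop(columns=list(dropped_vars))
    if kept.shape[1] == 0:
        raise CohortError(
            f"no clinical variables remain after dropping those missing in "
            f"more than {max_missing} samples"
        )
    incomplete = kept.index[kept.isna().any(axis=1)]
    dropped_samples = tuple(incomplete)
    retained = [s for s in cohort.sample_ids if s not in set(dropped_samples)]
    labels = cohort.labels.loc[retained]
    for c in cohort.classes:
        if (labels == c).sum() == 0:
            raise CohortError(
                f"missingness policy removed every sample of class {c!r}"
            )
    out = Cohort(
        expression=cohort.expression[retained],
        clinical=kept.loc[retained],
        labels=labels,
        classes=cohort.classes,
        variable_specs=infer_specs(
            kept.loc[retained],
            {s.name: s.kind for s in cohort.variable_specs.values() if s.name in kept.columns},
        ),
    )
    return out, MissingnessReport(dropped_vars, dropped_samples, max_missing)


def write_cohort(cohort: Cohort, out_dir: str | Path, label_column: str = "prognosis") -> dict:
    """Write a cohort as expression.tsv + clinical.tsv (labels included).

    Round-trips exactly through :func:`read_cohort` (floats are written with
    full repr precision).
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    expr_path = out_dir / "expression.tsv"
    clin_path = out_dir / "clinical.tsv"
    expr = cohort.expression.copy()
    expr.index.name = "gene_id"
    expr.to_csv(expr_path, sep="\t")
    clin = cohort.clinical.copy()
    clin[label_column] = cohort.labels
    clin.index.name = "sample_id"
    clin.to_csv(clin_path, sep="\t")
    return {"expression": expr_path, "clinical": clin_path, "label_column": label_column}
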