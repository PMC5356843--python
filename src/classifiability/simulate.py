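"""Synthetic cohorts with stratum-specific prognostic signal.

The generator emulates the structure the multi-step classifier targets: a
binary clinical variable ``z`` splits the cohort into a stratum where the
prognosis signal lives in gene expression (z = 0) and a stratum where it
lives in the clinical variables (z = 1). Defaults match a moderate two-class
cohort (22 good / 23 poor prognosis) with 2000 genes of which 200 carry a
one-standard-deviation class shift inside the expression-informative
stratum, plus 8 clinical variables: ``z``, two binary variables associated
with outcome at 2.0 log-odds inside z = 1 only, and a mix of binary and
continuous noise.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import expit

from .cohort import Cohort, CohortError, infer_specs

STRATUM_VARIABLE = "z"


@dataclass(frozen=True)
class SimulationConfig:
    """Cohort-generation parameters (defaults = the study conditions)."""

    n_good: int = 22
    n_poor: int = 23
    n_genes: int = 2000
    n_informative_genes: int = 200
    expr_effect: float = 1.0          # class mean shift, in units of expr_noise_sd
    expr_noise_sd: float = 1.0
    stratum_prevalence: float = 0.5   # P(z = 1)
    n_clinical: int = 8               # including z
    clinical_effect: float = 2.0      # log-odds per informative variable in z = 1
    n_informative_clinical: int = 2
    missing_rate: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.n_good < 2 or self.n_poor < 2:
            raise CohortError("need at least 2 samples per prognosis class")
        if self.n_informative_genes > self.n_genes:
            raise CohortError("n_informative_genes exceeds n_genes")
        if self.n_informative_clinical > self.n_clinical - 1:
            raise CohortError("n_informative_clinical exceeds n_clinical - 1")


@dataclass(frozen=True)
class SyntheticTruth:
    """Ground truth of a simulated cohort, for recovery studies."""

    stratum: pd.Series
    stratum_variable: str
    informative_genes: tuple
    informative_clinical: tuple


def simulate_cohort(config: SimulationConfig) -> tuple[Cohort, SyntheticTruth]:
    """Draw one cohort; fully determined by ``config`` (including seed).

    Expression: gene-wise Gaussian noise; inside stratum z = 0 the
    informative genes are shifted by +/- ``expr_effect``/2 per class with a
    random per-gene direction. Clinical: ``z`` plus informative binary
    variables (class-linked only inside z = 1, at ``clinical_effect``
    log-odds) plus fair-coin binary and standard-Gaussian continuous noise.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_good + config.n_poor
    sample_ids = [f"s{i + 1:03d}" for i in range(n)]
    gene_ids = [f"g{i + 1:04d}" for i in range(config.n_genes)]

    labels = np.array(["good"] * config.n_good + ["poor"] * config.n_poor, dtype=object)
    rng.shuffle(labels)
    y = labels == "poor"

    z = (rng.random(n) < config.stratum_prevalence).astype(int)

    X = rng.normal(0.0, config.expr_noise_sd, size=(config.n_genes, n))
    informative_genes = np.sort(
        rng.choice(config.n_genes, size=config.n_informative_genes, replace=False)
    )
    signs = rng.choice([-1.0, 1.0], size=config.n_informative_genes)
    shift = 0.5 * config.expr_effect * config.expr_noise_sd
    in_stratum0 = z == 0
    for row, sign in zip(informative_genes, signs):
        X[row, in_stratum0 & y] += sign * shift
        X[row, in_stratum0 & ~y] -= sign * shift

    clinical = pd.DataFrame(index=pd.Index(sample_ids, name="sample_id"))
    clinical[STRATUM_VARIABLE] = z
    informative_clinical = []
    n_noise = config.n_clinical - 1 - config.n_informative_clinical
    for j in range(config.n_informative_clinical):
        name = f"c{j + 1:02d}"
        p1 = expit(np.where(y, 0.5, -0.5) * config.clinical_effect)
        values = (rng.random(n) < np.where(z == 1, p1, 0.5)).astype(int)
        clinical[name] = values
        informative_clinical.append(name)
    for j in range(n_noise):
        name = f"c{config.n_informative_clinical + j + 1:02d}"
        if j % 2 == 0:
            clinical[name] = (rng.random(n) < 0.5).astype(int)
        else:
            clinical[name] = rng.normal(0.0, 1.0, size=n)

    if config.missing_rate > 0:
        mask = rng.random(clinical.shape) < config.missing_rate
        clinical = clinical.mask(mask)

    expression = pd.DataFrame(X, index=gene_ids, columns=sample_ids)
    cohort = Cohort(
        expression=expression,
        clinical=clinical,
        labels=pd.Series(labels, index=sample_ids, name="prognosis"),
        classes=("good", "poor"),
        variable_specs=infer_specs(clinical),
    )
    truth = SyntheticTruth(
        stratum=pd.Series(z, index=sample_ids, name=STRATUM_VARIABLE),
        stratum_variable=STRATUM_VARIABLE,
        informative_genes=tuple(gene_ids[i] for i in informative_genes),
        informative_clinical=tuple(informative_clinical),
    )
    return cohort, truth


def null_config(seed: int = 0, **overrides) -> SimulationConfig:
    """Defaults with every effect zeroed (labels independent of all data)."""
    overrides.setdefault("expr_effect", 0.0)
    overrides.setdefault("clinical_effect", 0.0)
    return SimulationConfig(seed=seed, **overrides)


def replicate_seeds(seed: int, n: int) -> list[int]:
    """Derive ``n`` independent sub-seeds (< 2**31) from a master seed."""
    state = np.random.SeedSequence(seed).generate_state(n, dtype=np.uint64)
    return [int(s % (2**31)) for s in state]


def recovery_study(
    config_grid: list,
    n_replicates: int = 100,
    seed: int = 0,
    n_cv_repeats: int = 50,
    include_error_comparison: bool = False,
    k: int = 1000,
) -> pd.DataFrame:
    """Monte-Carlo recovery of the planted structure.

    Per config: the fraction of replicates in which (a) the classifiability
    step selects the planted stratum variable by smallest AIC, and — when
    ``include_error_comparison`` — (b) the multi-step balanced leave-two-out
    error is strictly below both single-source baselines on shared folds.
    """
    from dataclasses import replace

    from .evaluation import draw_pairs, leave_two_out_evaluate
    from .routing import loocv_error_vector, select_classifiability_variable

    rows = []
    for cfg_idx, config in enumerate(config_grid):
        seeds = replicate_seeds(
            int(np.random.SeedSequence([seed, cfg_idx]).generate_state(1)[0] % (2**31)),
            n_replicates,
        )
        picked = 0
        superior = 0
        evaluated = 0
        for rep_seed in seeds:
            cohort, truth = simulate_cohort(replace(config, seed=rep_seed))
            errors = loocv_error_vector(cohort, k=k)
            model = select_classifiability_variable(
                errors, cohort.clinical, specs=cohort.variable_specs
            )
            if model.variable == truth.stratum_variable:
                picked += 1
            if include_error_comparison:
                pairs = draw_pairs(cohort, n_cv_repeats, rep_seed)
                errs = {
                    m: leave_two_out_evaluate(cohort, m, seed=rep_seed, k=k, pairs=pairs).mean_error
                    for m in ("multistep", "dlda", "clinical")
                }
                evaluated += 1
                if errs["multistep"] < min(errs["dlda"], errs["clinical"]):
                    superior += 1
        row = {
            "config": cfg_idx,
            "n_replicates": n_replicates,
            "stratum_recovery": picked / n_replicates,
            "expr_effect": config.expr_effect,
            "clinical_effect": config.clinical_effect,
            "n_samples": config.n_good + config.n_poor,
        }
        if include_error_comparison:
            row["multistep_superiority"] = superior / max(evaluated, 1)
        rows.append(row)
    return pd.DataFrame(rows)


def write_truth(truth: SyntheticTruth, path: str | Path) -> None:
    payload = {
        "stratum_variable": truth.stratum_variable,
        "stratum": {k: int(v) for k, v in truth.stratum.items()},
        "informative_genes": list(truth.informative_genes),
        "informative_clinical": list(truth.informative_clinical),
    }
    Path(path).write_text(json.dumps(payload, indent=2))
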