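"""Shared fixtures: all test data is generated programmatically."""

import numpy as np
import pandas as pd
import pytest

from classifiability.cohort import Cohort, infer_specs
from classifiability.simulate import SimulationConfig, simulate_cohort


def make_cohort(
    n_per_class=8,
    n_genes=60,
    seed=0,
    signal=0.0,
    n_clinical=3,
    classes=("good", "poor"),
):
    """Small random cohort; ``signal`` shifts the first 10 genes by class."""
    rng = np.random.default_rng(seed)
    n = 2 * n_per_class
    samples = [f"s{i}" for i in range(n)]
    genes = [f"g{i}" for i in range(n_genes)]
    labels = np.array([classes[0]] * n_per_class + [classes[1]] * n_per_class, dtype=object)
    X = rng.normal(size=(n_genes, n))
    if signal:
        X[:10, labels == classes[1]] += signal
    clinical = pd.DataFrame(index=pd.Index(samples, name="sample_id"))
    clinical["b1"] = rng.integers(0, 2, n)
    if n_clinical > 1:
        clinical["x1"] = rng.normal(size=n)
    for j in range(2, n_clinical):
        clinical[f"b{j}"] = rng.integers(0, 2, n)
    expression = pd.DataFrame(X, index=genes, columns=samples)
    return Cohort(
        expression=expression,
        clinical=clinical,
        labels=pd.Series(labels, index=samples, name="prognosis"),
        classes=classes,
        variable_specs=infer_specs(clinical),
    )


@pytest.fixture(scope="session")
def default_cohort():
    """One default-parameter synthetic cohort plus its ground truth."""
    return simulate_cohort(SimulationConfig(seed=42))


@pytest.fixture(scope="session")
def strong_cohort():
    """Cohort with a strong, cohort-wide expression signal (no stratum)."""
    cfg = SimulationConfig(seed=7, expr_effect=5.0, stratum_prevalence=0.0)
    return simulate_cohort(cfg)


@pytest.fixture
def small_cohort():
    return make_cohort(seed=1)
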