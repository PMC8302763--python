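"""Shared fixtures: small panels and cohorts generated at test time."""

import numpy as np
import pandas as pd
import pytest

import postgwas as pg


@pytest.fixture(scope="session")
def small_panel():
    spec = pg.PanelSpec(
        n_haplotypes=4000, n_variants=40, block_size=10,
        within_block_rho=0.8, seed=11,
    )
    return pg.simulate_panel(spec)


@pytest.fixture(scope="session")
def null_cohort(small_panel):
    """One study, no causal effects, 400 cases / 400 controls."""
    model = pg.DiseaseModel(causal_effects={}, k=0.005)
    cohorts, truth = pg.simulate_cohort(small_panel, model, 400, 400, 1, seed=21)
    return cohorts[0]


@pytest.fixture(scope="session")
def causal_cohorts(small_panel):
    """Three studies with one causal variant (OR 1.5) for power at small n."""
    causal = small_panel.variants["id"][5]
    model = pg.DiseaseModel(causal_effects={causal: float(np.log(1.5))}, k=0.005)
    cohorts, truth = pg.simulate_cohort(small_panel, model, 1000, 1000, 3, seed=31)
    return cohorts, truth, causal


@pytest.fixture()
def toy_matrix():
    """Deterministic 6-sample, 3-variant cohort for bookkeeping tests."""
    dosage = np.array(
        [
            [0, 1, 2],
            [1, 1, 0],
            [2, 0, 1],
            [0, 2, 1],
            [1, 0, 0],
            [2, 1, 1],
        ],
        dtype=float,
    )
    variants = pd.DataFrame(
        {
            "id": ["v1", "v2", "v3"],
            "chrom": "1",
            "pos": [100, 200, 300],
            "a1": ["A", "A", "A"],
            "a2": ["G", "G", "G"],
        }
    )
    cov = pd.DataFrame({"center": ["S1"] * 6}, index=[f"s{i}" for i in range(6)])
    return pg.CohortMatrix(
        dosage=dosage,
        phenotype=np.array([1, 1, 1, 0, 0, 0]),
        covariates=cov,
        variants=variants,
    )
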