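import logging
import warnings

import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from burdenml import Cohort, SimulationConfig, simulate_cohort

settings.register_profile("suite", deadline=None, max_examples=30, derandomize=True)
settings.load_profile("suite")

# sklearn 1.9 deprecation chatter from SVC(probability=True) is not useful
# in test output
warnings.filterwarnings("ignore", category=FutureWarning, module="sklearn")
logging.getLogger("burdenml").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def default_cohort() -> Cohort:
    """The study-scale cohort: n = 637, 100 genes (10 causal), 200 replicates."""
    return simulate_cohort(SimulationConfig(seed=1))


@pytest.fixture(scope="session")
def small_config() -> SimulationConfig:
    return SimulationConfig(
        n_individuals=120,
        n_pedigrees=6,
        n_genes=12,
        n_causal_genes=4,
        n_replicates=24,
        seed=11,
    )


@pytest.fixture(scope="session")
def small_cohort(small_config) -> Cohort:
    return simulate_cohort(small_config)


def toy_cohort(
    genotypes: pd.DataFrame,
    gene_of: dict[str, str],
    expression: pd.DataFrame | None = None,
    n_replicates: int = 4,
    seed: int = 0,
) -> Cohort:
    """Hand-assembled cohort around a given genotype block, for oracle tests."""
    rng = np.random.default_rng(seed)
    n = genotypes.shape[0]
    idx = genotypes.index
    genes = sorted(set(gene_of.values()))
    if expression is None:
        expression = pd.DataFrame(
            rng.normal(size=(n, len(genes))), index=idx, columns=genes
        )
    covariates = pd.DataFrame(
        {
            "pedigree_id": ["P1"] * (n // 2) + ["P2"] * (n - n // 2),
            "sex": rng.integers(0, 2, n),
            "age": rng.uniform(20, 70, n).round(1),
            "smoke": rng.integers(0, 2, n),
        },
        index=idx,
    )
    reps = pd.DataFrame(
        rng.integers(0, 2, size=(n, n_replicates)),
        index=idx,
        columns=[f"SIMPHEN.{i + 1}" for i in range(n_replicates)],
    ).astype(np.int8)
    ann = pd.DataFrame(
        {"gene_id": [gene_of[v] for v in genotypes.columns]},
        index=pd.Index(genotypes.columns, name="variant_id"),
    )
    return Cohort(
        genotypes=genotypes.astype(np.int8),
        variant_annotations=ann,
        expression=expression,
        covariates=covariates,
        phenotype_replicates=reps,
    )
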