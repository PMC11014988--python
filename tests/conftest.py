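import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

import ersurf as es
from ersurf.qc import IntensityMatrix

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def small_config():
    return es.GeneratorConfig(n_proteins=80, n_shifted=8, seed=7)


@pytest.fixture(scope="session")
def small_experiment(small_config):
    """One small simulated experiment shared across read-only tests."""
    rng = np.random.default_rng(small_config.seed)
    catalog = es.generate_catalog(small_config, rng)
    matrix, truth = es.generate_experiment(catalog, small_config, rng=rng)
    return catalog, matrix, truth


def make_matrix(values, baits=None, genotypes=None, replicates=None, batches=None,
                peptides=None, scale="raw"):
    """Small IntensityMatrix builder for hand-constructed fixtures."""
    values = pd.DataFrame(values)
    n_p, n_s = values.shape
    names = [f"s{j}" for j in range(n_s)]
    values.columns = names
    samples = pd.DataFrame(
        {
            "bait": baits or ["B"] * n_s,
            "genotype": genotypes or ["G"] * n_s,
            "replicate": replicates or list(range(1, n_s + 1)),
            "batch": batches or ["b1"] * n_s,
        },
        index=names,
    )
    if peptides is None:
        peptides = pd.Series(5, index=values.index)
    else:
        peptides = pd.Series(peptides, index=values.index)
    return IntensityMatrix(
        values=values, samples=samples, unique_peptides=peptides, scale=scale
    )
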