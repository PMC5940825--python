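import numpy as np
import pytest

from sumxcan.simulate import SimScenario, simulate_study


@pytest.fixture(scope="session")
def null_study():
    """Small null-phenotype cohort shared by read-only tests."""
    return simulate_study(
        SimScenario(
            seed=101,
            n_individuals=400,
            n_genes=20,
            snps_per_gene=10,
            n_causal_snps=2,
            architecture="null",
        )
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
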