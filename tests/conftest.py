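import numpy as np
import pytest

from growthgwas.nmm import NMMParams, NonlinearMixedModel
from growthgwas.simulate import SimulationConfig, simulate_cohort, solve_b_through


@pytest.fixture(scope="session")
def default_params():
    """Reference NMM parameters at the defaults of the generator."""
    return NMMParams(
        beta_A=[2615.45, 0.0],
        beta_K=[0.054, 0.0],
        b=15.35,
        Sigma=np.array([[210.0**2, 0.0], [0.0, 0.0054**2]]),
        sigma2_e=60.0**2,
    )


@pytest.fixture(scope="session")
def small_bundle():
    """Standard small fixture: 5 individuals, 7 time points."""
    return simulate_cohort(SimulationConfig(n_individuals=5, n_snps=4, seed=11))


@pytest.fixture(scope="session")
def cohort400():
    """Mid-size cohort at generator defaults (no SNP effects)."""
    return simulate_cohort(SimulationConfig(n_individuals=400, n_snps=60, seed=42))


@pytest.fixture(scope="session")
def m0_fit_400(cohort400):
    """Null-model ML fit on the 400-individual cohort, shared across tests."""
    return NonlinearMixedModel(snp_target="none").fit(cohort400.cohort)


@pytest.fixture(scope="session")
def solved_mu_b():
    """Time-scale solved so the default mean curve passes through the
    day-35 population mean of 788.05 g."""
    return solve_b_through(2615.45, 0.054, 35.0, 788.05)
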