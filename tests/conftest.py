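import numpy as np
import pytest

from countcompare import (
    CovariateSpec,
    TrueModel,
    generate_counts,
    generate_covariates,
)


@pytest.fixture(scope="session")
def design_50():
    """Fixed 50-row design matrix with the study covariate distribution."""
    return generate_covariates(CovariateSpec(n=50), seed=101).X


@pytest.fixture(scope="session")
def design_2000():
    return generate_covariates(CovariateSpec(n=2000), seed=202).X


def make_dataset(family, n, seed, beta=(2.1, -0.001, 0.03), alpha=None, phi=None):
    cov = generate_covariates(CovariateSpec(n=n), seed)
    truth = TrueModel(family=family, beta=tuple(beta), alpha=alpha, phi=phi)
    return generate_counts(truth, cov.X, seed)


@pytest.fixture(scope="session")
def nb_dataset_50(design_50):
    """Overdispersed 50-row sample (interior optima for every family)."""
    return generate_counts(TrueModel("nb", alpha=1.0), design_50, seed=303)


@pytest.fixture(scope="session")
def zinb_dataset_50(design_50):
    return generate_counts(TrueModel("zinb", alpha=1.0, phi=0.4), design_50, seed=404)
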