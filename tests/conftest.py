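import numpy as np
import pytest

from misclasso import Dataset, ModelSpec, make_true_beta, sample_design, sample_labels


@pytest.fixture(scope="session")
def small_logistic_data():
    """A well-conditioned n > p dataset from the logistic single-index model."""
    beta = np.array([0.5, 1.0, -1.0, 0.0, 0.0, 0.5])
    spec = ModelSpec(p=5, beta=beta, link="logistic", rho=0.5)
    X = sample_design(400, spec, seed=7)
    y = sample_labels(X, spec, seed=8)
    return Dataset(X=X, y=y, seed=7), spec


@pytest.fixture(scope="session")
def scenario1_spec_p10():
    """Scenario-1 style model at p=10 (all predictors relevant)."""
    beta = make_true_beta(10, 10, seed=5)
    return ModelSpec(p=10, beta=beta, link="logistic", rho=0.5)


@pytest.fixture(scope="session")
def scenario2_spec_p10():
    beta = make_true_beta(10, 10, seed=5)
    return ModelSpec(p=10, beta=beta, link="arctan", rho=0.5)


def tiny_dataset(n, p, seed, link="logistic", k=None, rho=0.5):
    """Seeded helper for small solver problems."""
    k = p if k is None else k
    beta = make_true_beta(p, k, seed)
    spec = ModelSpec(p=p, beta=beta, link=link, rho=rho)
    X = sample_design(n, spec, seed=seed + 1)
    y = sample_labels(X, spec, seed=seed + 2)
    return Dataset(X=X, y=y, seed=seed), spec
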