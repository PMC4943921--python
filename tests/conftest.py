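import numpy as np
import pytest

import epbayes as ep


@pytest.fixture(scope="session")
def table1():
    return ep.load_dataset("table1")


@pytest.fixture(scope="session")
def device():
    return ep.load_dataset("device")


@pytest.fixture(scope="session")
def transistor():
    return ep.load_dataset("transistor")


@pytest.fixture(scope="session")
def table1_logpost(table1):
    return ep.LogPosterior(table1)


@pytest.fixture(scope="session")
def table1_laplace(table1_logpost):
    return ep.laplace_approximation(table1_logpost)


@pytest.fixture(scope="session")
def table1_reference_chain(table1_logpost, table1_laplace):
    """The 10,000-iteration, thinning-10 reproduction chain."""
    return ep.run_im_chain(
        table1_logpost,
        table1_laplace,
        iterations=10000,
        thinning=10,
        seed=1,
        acceptance_rule="reference",
    )


class GaussianTarget:
    """A multivariate normal log-density usable as a mock posterior."""

    def __init__(self, mean, cov):
        self.mean = np.asarray(mean, dtype=float)
        self.cov = np.asarray(cov, dtype=float)
        self.prec = np.linalg.inv(self.cov)
        self.dim = self.mean.size
        self.names = [f"p{i}" for i in range(self.dim)]
        self.layout = None

    def __call__(self, u):
        r = np.asarray(u, dtype=float) - self.mean
        return -0.5 * float(r @ self.prec @ r)

    def loglik(self, u):
        return self(u)

    def deviance(self, u):
        return -2.0 * self(u)


@pytest.fixture
def gaussian_target():
    cov = np.array([[1.0, 0.6], [0.6, 2.0]])
    return GaussianTarget([0.7, -1.2], cov)
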