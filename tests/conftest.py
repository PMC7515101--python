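import numpy as np
import pytest

from mescore import LogisticDesign, load_dataset

SEED = 0


@pytest.fixture
def rng():
    return np.random.default_rng(SEED)


@pytest.fixture(scope="session")
def normal_sample():
    return load_dataset("normal_ex1").response


@pytest.fixture(scope="session")
def poisson_sample():
    return load_dataset("poisson_ex2").response


@pytest.fixture(scope="session")
def gamma_sample():
    return load_dataset("gamma_ex3").response


@pytest.fixture(scope="session")
def finney_design():
    ds = load_dataset("finney")
    return LogisticDesign.from_predictors(
        np.log(ds.predictors.to_numpy(dtype=float)), ds.response
    )


@pytest.fixture(scope="session")
def iris_design():
    ds = load_dataset("iris_binary")
    return LogisticDesign.from_predictors(ds.predictors.to_numpy(dtype=float), ds.response)


def make_separated_design(rng, n=20, p=1):
    """A completely separated binary dataset: a threshold on the first predictor."""
    x = rng.standard_normal((n, p))
    order = np.argsort(x[:, 0])
    y = np.zeros(n)
    y[order[n // 2 :]] = 1.0
    # enforce a strict gap so separation is complete, not quasi
    x[order[n // 2 :], 0] += 0.5
    return LogisticDesign.from_predictors(x, y)
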