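import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from promethex.io import CountMatrix
from promethex.model import PromoterMethylationModel
from promethex.simulate import worked_example_fixture

settings.register_profile(
    "suite", derandomize=True, max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


def make_tmm_nb_counts() -> CountMatrix:
    """4 samples x 200 NB genes, 10% of genes 4-fold inflated in sample A.

    Deterministic; the reference TMM factors for this exact matrix were
    computed once with an independent implementation and frozen in
    tests/test_acceptance.py.
    """
    rng = np.random.default_rng(42)
    mu = rng.uniform(20, 500, 200)
    base = rng.negative_binomial(10, 10 / (10 + mu), (4, 200)).T
    x = base.astype(float)
    x[:20, 0] *= 4
    return CountMatrix(
        pd.DataFrame(x.astype(np.int64),
                     index=[f"g{i}" for i in range(200)],
                     columns=list("ABCD"))
    )


@pytest.fixture(scope="session")
def tmm_nb_counts() -> CountMatrix:
    return make_tmm_nb_counts()


@pytest.fixture(scope="session")
def worked_cohort():
    return worked_example_fixture()


@pytest.fixture(scope="session")
def worked_results(worked_cohort):
    return PromoterMethylationModel.from_cohort(worked_cohort).fit()
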