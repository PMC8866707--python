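import numpy as np
import pandas as pd
import pytest

from ldlkit.simulate import CohortParams, FactorModel, generate_cohort


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20220210)


@pytest.fixture(scope="session")
def random_panels(rng):
    """10,000 random valid lipid panels as a cohort frame."""
    n = 10_000
    tc = rng.uniform(90, 350, n)
    hdl = np.minimum(rng.uniform(20, 110, n), tc * rng.uniform(0.1, 0.6, n))
    tg = rng.uniform(0, 600, n)
    return pd.DataFrame({"tc": tc, "hdl": hdl, "tg": tg})


@pytest.fixture(scope="session")
def small_cohort():
    """20k-record synthetic cohort with the default TG-dependent factor."""
    return generate_cohort(CohortParams(n=20_000, seed=42))


@pytest.fixture(scope="session")
def noiseless_constant_cohort():
    """Constant divisor 5 and no assay noise: Friedewald is exact."""
    fm = FactorModel(base=5.0, amplitude=0.0, nonhdl_slope=0.0)
    return generate_cohort(CohortParams(n=2_000, seed=7, factor_model=fm, assay_noise_sd=0.0))
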