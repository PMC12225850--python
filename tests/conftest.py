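import numpy as np
import pandas as pd
import pytest

from ldlratio.synthetic import generate_cohort, preset


def random_panels(rng: np.random.Generator, n: int) -> pd.DataFrame:
    """Random valid lipid panels with measured LDL-C and positive VLDL-C."""
    hdl = rng.uniform(25, 90, n)
    ldl = rng.uniform(30, 220, n)
    vldl = rng.uniform(5, 42, n)
    tg = vldl * rng.uniform(1.5, 9.4, n)  # keeps TG < 400
    return pd.DataFrame(
        {
            "id": [f"r{i}" for i in range(n)],
            "tc": hdl + ldl + vldl,
            "hdl_c": hdl,
            "tg": tg,
            "ldl_d": ldl,
        }
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260923)


@pytest.fixture(scope="session")
def pop1_cohort() -> pd.DataFrame:
    return generate_cohort(preset("population1", n=11930, seed=11))


@pytest.fixture(scope="session")
def combined_cohort() -> pd.DataFrame:
    return generate_cohort(preset("combined", n=18322, seed=11))
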