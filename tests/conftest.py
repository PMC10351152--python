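import numpy as np
import pandas as pd
import pytest

from livermet.datatypes import CountMatrix, SignatureSet
from livermet.simulate import CohortConfig, simulate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """A small matched cohort with planted liver/colon programs."""
    cfg = CohortConfig(
        seed=11,
        n_genes=600,
        n_liver_program=20,
        n_colon_program=20,
        groups={"CC": 8, "LM1": 8, "AL": 6},
        n_patients=8,
    )
    return simulate_cohort(cfg)


@pytest.fixture()
def toy_counts():
    rng = np.random.default_rng(7)
    x = rng.negative_binomial(5, 0.01, size=(100, 6))
    return CountMatrix(
        pd.DataFrame(
            x,
            index=[f"g{i:03d}" for i in range(100)],
            columns=[f"s{j}" for j in range(6)],
        )
    )


@pytest.fixture()
def toy_signature():
    return SignatureSet("toy", up=tuple(f"SG{i:02d}" for i in range(21)))
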