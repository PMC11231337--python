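import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from emtstrat import ExpressionMatrix

settings.register_profile("ci", derandomize=True, max_examples=200)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(20240915)


@pytest.fixture
def small_matrix(rng):
    genes = [f"G{i:02d}" for i in range(30)]
    samples = [f"S{i}" for i in range(8)]
    return ExpressionMatrix(
        pd.DataFrame(rng.normal(5.0, 1.0, size=(30, 8)), index=genes, columns=samples)
    )
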