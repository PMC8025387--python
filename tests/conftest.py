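import numpy as np
import pandas as pd
import pytest

from ewasmed.qc import MethylationMatrix


@pytest.fixture
def rng():
    return np.random.default_rng(20260928)


@pytest.fixture
def small_m_matrix(rng):
    """30 CpGs x 40 samples on the M scale, no missingness."""
    vals = rng.normal(0.0, 1.0, size=(30, 40))
    return MethylationMatrix(
        vals,
        [f"cg{i:08d}" for i in range(30)],
        [f"S{j:05d}" for j in range(40)],
        scale="M",
    )


@pytest.fixture
def binary_treatments(rng):
    n = 400
    return pd.DataFrame(
        {
            "alkylating": rng.integers(0, 2, n),
            "anthracycline": rng.integers(0, 2, n),
            "brain_rt": rng.integers(0, 2, n),
        }
    )
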