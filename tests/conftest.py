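import numpy as np
import pandas as pd
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def toy_survival():
    """Six-record table whose product-limit curve is computable by hand."""
    return pd.DataFrame(
        {
            "patient_id": [f"p{i}" for i in range(6)],
            "time": [1.0, 2.0, 3.0, 3.0, 4.0, 5.0],
            "event": [1, 0, 1, 1, 0, 1],
        }
    )


@pytest.fixture
def small_expression(rng):
    """40-gene, 8-sample log-expression matrix."""
    genes = [f"g{i}" for i in range(40)]
    samples = [f"s{j}" for j in range(8)]
    return pd.DataFrame(
        rng.normal(5.0, 2.0, size=(40, 8)), index=genes, columns=samples
    )
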