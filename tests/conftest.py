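import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def small_expression():
    """4 genes x 5 arrays, fully observed."""
    from goiseek.types import ExpressionMatrix

    data = np.array(
        [
            [1.0, 2.0, 3.0, 4.0, 5.0],
            [2.0, 4.0, 6.0, 8.0, 10.0],
            [5.0, 4.0, 3.0, 2.0, 1.0],
            [1.0, 1.5, 2.0, 2.5, 3.5],
        ]
    )
    return ExpressionMatrix(
        pd.DataFrame(data, index=["G1", "G2", "G3", "G4"], columns=list("abcde"))
    )


def write_tsv(path, frame):
    frame.to_csv(path, sep="\t", na_rep="", index_label="")
    return path
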