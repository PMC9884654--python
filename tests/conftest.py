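import numpy as np
import pandas as pd
import pytest

from urbansoilrisk import synthetic
from urbansoilrisk.types import SampleTable


@pytest.fixture(scope="session")
def survey():
    """Default background-only synthetic survey (121 samples)."""
    return synthetic.generate_survey(synthetic.SurveySpec(seed=42))


@pytest.fixture(scope="session")
def kernel_survey():
    """Survey with one anthropogenic Hg+Pb+Sn anomaly kernel."""
    spec = synthetic.SurveySpec(
        seed=11,
        kernels=[synthetic.AnomalyKernel(
            center=(2300.0, 2300.0), radius=400.0,
            elements=["Hg", "Pb", "Sn"], enrichment=10.0)])
    return synthetic.generate_survey(spec)


@pytest.fixture()
def tiny_survey():
    """Hand-built 5-sample survey for exact-arithmetic checks."""
    df = pd.DataFrame({
        "sample_id": ["a", "b", "c", "d", "e"],
        "x": [0.0, 100.0, 0.0, 100.0, 50.0],
        "y": [0.0, 0.0, 100.0, 100.0, 50.0],
        "Cu": [100.0, 200.0, 300.0, 400.0, 500.0],
        "Pb": [10.0, 20.0, 30.0, 40.0, 50.0],
        "Fe": [30000.0, 31000.0, 32000.0, 33000.0, 34000.0],
        "ph": [6.5, 7.0, 7.5, 8.0, 8.5],
    })
    return SampleTable(df, ["Cu", "Pb", "Fe"])


def make_constant_survey(value=7.0, n=25, seed=0):
    return synthetic.generate_toy_grid_field(
        "constant", {"value": value, "n": n}, seed=seed)
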