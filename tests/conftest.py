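import numpy as np
import pandas as pd
import pytest

from enterotyper.datasets import load_twin_example
from enterotyper.io_core import AbundanceTable
from enterotyper.synthetic_data import CohortSpec, generate_twin_cohort


@pytest.fixture(scope="session")
def default_cohort():
    """Default 10-pair cohort (36 samples), fixed seed."""
    return generate_twin_cohort(CohortSpec(seed=0))


@pytest.fixture(scope="session")
def truth_labels(default_cohort):
    return default_cohort.truth.set_index("sample_id")["enterotype"]


@pytest.fixture(scope="session")
def twin_example():
    """Worked-example design + enterotype + functional-cluster labels."""
    return load_twin_example()


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def make_table(values, sample_ids=None, feature_ids=None, level="genus"):
    values = np.asarray(values, dtype=float)
    n, p = values.shape
    sample_ids = sample_ids or [f"S{i}" for i in range(n)]
    feature_ids = feature_ids or [f"F{j}" for j in range(p)]
    return AbundanceTable(
        pd.DataFrame(values, index=sample_ids, columns=feature_ids), level=level
    )
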