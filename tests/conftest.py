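import warnings

import numpy as np
import pandas as pd
import pytest

from pltr_immuno.cohort import CohortTable, VariableSpec
from pltr_immuno.simulate import SimConfig, generate_cohort


@pytest.fixture(scope="session")
def default_cohort():
    """Study-sized cohort (n=125) from the default configuration."""
    cohort, truth = generate_cohort(SimConfig(n=125, seed=42))
    return cohort, truth


@pytest.fixture(scope="session")
def medium_cohort():
    """Moderate cohort for model-fitting tests."""
    cohort, truth = generate_cohort(SimConfig(n=600, seed=7))
    return cohort, truth


def make_binary_cohort(y, columns, levels=("no", "yes"), specs_extra=()):
    """Cohort from a 0/1 outcome array and {name: 0/1 array} covariates."""
    data = {"inhibitor": np.where(np.asarray(y) == 1, "inh+", "inh-")}
    specs = [VariableSpec("inhibitor", "outcome", "binary", ("inh-", "inh+"))]
    for name, col in columns.items():
        data[name] = np.where(np.asarray(col) == 1, levels[1], levels[0])
        specs.append(VariableSpec(name, "tree", "binary", levels))
    specs.extend(specs_extra)
    return CohortTable(pd.DataFrame(data), specs)


@pytest.fixture(autouse=True)
def _quiet_separation_warnings():
    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", message="possible separation")
        yield
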