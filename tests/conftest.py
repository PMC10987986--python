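import numpy as np
import pytest

from motorhyst.choice_model import EXPERIMENT_PARAMS
from motorhyst.synthetic_data import default_error_table, make_cohort


@pytest.fixture(scope="session")
def exp1_cohort():
    """Moderate experiment-1 cohort at the fitted mean parameters."""
    rng = np.random.default_rng(101)
    return make_cohort(
        30, EXPERIMENT_PARAMS[1], rng, experiment=1,
        error_table=default_error_table(1), seed=101,
    )


@pytest.fixture(scope="session")
def exp1_choices(exp1_cohort):
    from motorhyst.behavior_stats import preprocess_choices

    trials = exp1_cohort.trials
    return preprocess_choices(trials[trials["block_type"] == "experimental"])
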