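import numpy as np
import pandas as pd
import pytest

from antdrift import cohort, hierarchical as hm


@pytest.fixture(scope="session")
def small_cohort():
    """Reduced cohort (5 subjects/group, 3 runs) with ground truth."""
    table, truth = cohort.generate_cohort(
        cohort.default_groups(), 5, schedule=cohort.ScheduleConfig(n_runs=3), seed=11
    )
    return table, truth


@pytest.fixture(scope="session")
def small_fit(small_cohort):
    """Short hierarchical fit of the reduced cohort (both v and a vary)."""
    table, truth = small_cohort
    data = table[table["response"].isin([0, 1])].reset_index(drop=True)
    model = hm.build_model(hm.ModelSpec(varies_by_condition=("v", "a")), data)
    samples = hm.sample_posterior(
        model, hm.MCMCConfig(n_samples=1500, n_burn_in=600, n_chains=2, seed=5)
    )
    return model, samples, data, truth
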