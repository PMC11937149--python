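import numpy as np
import pytest

import trialcea as tc


@pytest.fixture(scope="session")
def small_complete_trial():
    """Small complete trial (no missingness, no deaths): 6 clusters/arm."""
    cfg = tc.SimConfig(seed=101, n_clusters_per_arm=6, cluster_size_mean=7,
                       missing_utility_rate=0.0, missing_cost_rate=0.0,
                       death_rate=0.0)
    return tc.simulate_trial(cfg)


@pytest.fixture(scope="session")
def masked_trial():
    """Trial-scale dataset with MAR missingness and deaths."""
    cfg = tc.SimConfig(seed=202, n_clusters_per_arm=12, cluster_size_mean=8)
    return tc.apply_missingness(tc.simulate_trial(cfg), cfg)


@pytest.fixture(scope="session")
def zero_iv_spec():
    """Intervention delivery priced at zero (parameter-recovery setting)."""
    return tc.InterventionCostSpec(0.0, 0.0, 1)


@pytest.fixture(scope="session")
def quick_pipeline_config(zero_iv_spec):
    """Pipeline configuration small enough for unit tests."""
    return tc.PipelineConfig(intervention_cost=zero_iv_spec,
                             m_imputations=3, b_bootstrap=40,
                             n_monte_carlo=200,
                             methods=("parametric", "monte_carlo"), seed=7)


@pytest.fixture(scope="session")
def value_set():
    return tc.synthetic_value_set()
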