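import pytest

import tobaccopolicy as tp
from tobaccopolicy.panel import POLICY_COLUMNS


@pytest.fixture(scope="session")
def small_config():
    """A compact single-stratum generator setup used across test modules."""
    return tp.GeneratorConfig(
        n_countries=40, strata=[("both", "15plus")], seed=7
    )


@pytest.fixture(scope="session")
def small_tables(small_config):
    policies, prevalence, truth = tp.generate_panel_data(small_config)
    return policies, prevalence, truth


@pytest.fixture(scope="session")
def small_panel(small_tables):
    policies, prevalence, _ = small_tables
    panel, log = tp.lag_merge(policies[POLICY_COLUMNS], prevalence)
    return panel, log


@pytest.fixture(scope="session")
def small_fit(small_panel):
    panel, _ = small_panel
    sub = tp.select_stratum(panel, "both", "15plus")
    from tobaccopolicy.model import PolicyMixedModel

    return PolicyMixedModel(sub, stratum=("both", "15plus")).fit()


def make_results(params, cov=None):
    """Results carrier with chosen coefficients, for engine-level tests."""
    import json

    import numpy as np

    from tobaccopolicy.model import FIXED_TERMS, PolicyMixedResults

    k = len(FIXED_TERMS)
    cov = np.zeros((k, k)) if cov is None else np.asarray(cov)
    payload = {
        "stratum": None,
        "params": dict(zip(FIXED_TERMS, map(float, params))),
        "bse": dict(zip(FIXED_TERMS, np.sqrt(np.diag(cov)).tolist())),
        "cov_params": cov.tolist(),
        "sd_intercept": 0.1, "sd_slope": 0.001, "re_correlation": 0.0,
        "sd_resid": 0.05, "llf": 0.0, "method": "reml",
        "re_structure": "unstructured", "converged": True,
        "df_method": "normal",
        "pvalues": dict(zip(FIXED_TERMS, [0.0] * k)),
        "n_obs": 100, "n_countries": 20,
    }
    return PolicyMixedResults.from_json(json.dumps(payload))


@pytest.fixture(scope="session")
def results_builder():
    return make_results


@pytest.fixture(scope="session")
def multi_stratum_run():
    """Four male strata (three age bands + the 15+ envelope), fitted."""
    from tobaccopolicy.model import PolicyMixedModel

    strata = [("male", a) for a in ("15-29", "30-49", "50plus", "15plus")]
    config = tp.GeneratorConfig(n_countries=50, strata=strata, seed=21)
    policies, prevalence, truth = tp.generate_panel_data(config)
    panel, _ = tp.lag_merge(policies[POLICY_COLUMNS], prevalence)
    results = {
        s: PolicyMixedModel(tp.select_stratum(panel, *s), stratum=s).fit()
        for s in strata
    }
    return policies, prevalence, truth, results
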