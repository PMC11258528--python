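import numpy as np
import pytest

import bnscreen as b

TRUE_EDGES = {
    frozenset(e)
    for e in [
        ("balance_problem", "DS"),
        ("age_felt", "DS"),
        ("DS", "sleep_meds"),
        ("DS", "usual_activities"),
        ("back_pain", "sleep_meds"),
        ("chest_pain", "usual_activities"),
    ]
}


@pytest.fixture(scope="session")
def example_network():
    return b.make_ground_truth_network(b.example_spec(seed=1))


@pytest.fixture(scope="session")
def survey_20k(example_network):
    return b.sample_survey(example_network, 20000, seed=100)


@pytest.fixture(scope="session")
def prepped_20k(survey_20k):
    return b.prepare(survey_20k, b.PrepConfig(seed=3))


def observed_discrete_frame(network, n, seed):
    """Feature codes + recorded outcome, bypassing the preparation pipeline."""
    data = b.sample_survey(network, n, seed=seed)
    items = data.frame[data.phq9_columns].to_numpy()
    df = data.frame[list(network.spec.feature_cardinalities)].astype(int).copy()
    df["DS"] = (items.sum(axis=1) >= 10).astype(int)
    return df


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(2024)
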