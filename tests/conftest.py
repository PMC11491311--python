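import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_cohort():
    """One cached synthetic cohort draw (n=300, no missingness)."""
    from symptomnet.synthetic import default_cohort_spec, generate_cohort

    spec = default_cohort_spec(n=300, seed=11, missing_rate=0.0)
    responses, truth = generate_cohort(spec)
    return responses, truth


@pytest.fixture(scope="session")
def pair_net():
    from symptomnet.validation import equal_edges_network

    return equal_edges_network()


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
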