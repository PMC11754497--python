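import numpy as np
import pytest

import ocrnet as oc


@pytest.fixture(scope="session")
def bundle() -> oc.CohortBundle:
    """The canonical simulated matched-cohort study."""
    return oc.default_fixture()


@pytest.fixture(scope="session")
def network_result(bundle) -> oc.ConsensusNetworkResult:
    """Consensus network built once on the canonical fixture."""
    return oc.build_consensus_network(bundle.datasets)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20240101)


def random_survival(rng, n, event_scale=20.0, censor_max=60.0):
    """Exchangeable null survival data: exponential events, uniform censoring."""
    event_t = rng.exponential(event_scale, n)
    censor_t = rng.uniform(0, censor_max, n)
    times = np.minimum(event_t, censor_t)
    events = (event_t <= censor_t).astype(int)
    return times, events
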