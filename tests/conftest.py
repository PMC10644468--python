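import numpy as np
import pytest

from symptomnet import default_model, generate_cohort, ground_truth_from_partials


@pytest.fixture(scope="session")
def chain_model():
    """7-node chain graph with all partial correlations 0.3.

    Thresholds are balanced (well-populated categories) so rank-based
    estimation attenuates the latent structure only mildly.
    """
    p = 7
    P = np.zeros((p, p))
    for i in range(p - 1):
        P[i, i + 1] = P[i + 1, i] = 0.3
    labels = [f"ISI{i+1}" for i in range(p)]
    thresholds = {lab: np.array([-1.2, -0.4, 0.4, 1.2]) for lab in labels}
    return ground_truth_from_partials(P, node_labels=labels, item_thresholds=thresholds)


@pytest.fixture(scope="session")
def reference_model():
    return default_model()


@pytest.fixture(scope="session")
def small_cohort():
    """Default synthetic cohort at the study's size, shared across tests."""
    return generate_cohort(1101, seed=11)
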