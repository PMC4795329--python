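import numpy as np
import pytest

from pcmcat import Item, ItemBank, default_nhs_bank, demo_routing_bank


@pytest.fixture(scope="session")
def bank():
    """The bundled 24-item inpatient-experience pool."""
    return default_nhs_bank()


@pytest.fixture(scope="session")
def routing_bank():
    """Pool plus synthetic skip-logic demo items 39-41."""
    return demo_routing_bank()


@pytest.fixture
def dichotomous_item():
    """A single 1-step (two-category) item at difficulty 0.7."""
    return Item.from_difficulty(1, 0.7, 1)


@pytest.fixture
def two_step_item():
    """A 2-step item with thresholds (-0.5, +0.5), difficulty 0."""
    return Item.from_difficulty(2, 0.0, 2)


def random_response_vector(bank, rng, theta_range=(-3.0, 3.0)):
    """A model-consistent response map at a random ability (may be extreme)."""
    from pcmcat import category_probabilities

    theta = rng.uniform(*theta_range)
    out = {}
    for item in bank.pool_items():
        p = category_probabilities(theta, item)
        out[item.item_id] = int((rng.random() > np.cumsum(p)[:-1]).sum())
    return out, theta
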