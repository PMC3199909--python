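import numpy as np
import pytest

from psychocat import (
    generate_item_bank,
    generate_population,
    generate_responses,
    score_criterion,
)


@pytest.fixture(scope="session")
def small_bank():
    """11-item, 3-category bank: 5 core items + 2 in each short block."""
    return generate_item_bank(
        n_core=5, n_short=2, n_categories=3, location_low=-2, location_high=2,
        spread=0.8, seed=42,
    )


@pytest.fixture(scope="session")
def small_cohort(small_bank):
    persons = generate_population(n_persons=300, seed=7)
    responses = generate_responses(small_bank, persons, design="four_block", seed=8)
    persons = score_criterion(responses, small_bank, persons)
    return persons, responses


@pytest.fixture(scope="session")
def core_bank():
    """20 core-only items, useful for complete-design calibration tests."""
    bank = generate_item_bank(
        n_core=20, n_short=1, n_categories=3, location_low=-2, location_high=2,
        spread=1.0, seed=5,
    )
    return bank.subset(np.asarray(bank.blocks) == "A")


@pytest.fixture(scope="session")
def calibrated_cohort(core_bank):
    """Complete responses from a roughly centered latent distribution."""
    persons = generate_population(
        n_persons=1000, theta_shift=-1.2, lognorm_mu=0.0, lognorm_sigma=0.6, seed=3
    )
    responses = generate_responses(core_bank, persons, design="complete", seed=4)
    return persons, responses
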