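import numpy as np
import pytest

from okrsphere import (
    SeedConfiguration,
    StimulusSpec,
    default_cohort,
    default_truth,
    generate_dataset,
    place_stimulus_centres,
)


@pytest.fixture(scope="session")
def centres():
    """The 38 relaxed stimulus centres (deterministic default seeds)."""
    return place_stimulus_centres(SeedConfiguration())


@pytest.fixture(scope="session")
def default_spec():
    return StimulusSpec()


@pytest.fixture(scope="session")
def noisy_gain_table(centres):
    """Position-tuning cohort at 20%-of-peak gain noise, gains only."""
    truth = default_truth(gain_noise_sd=0.06)
    cohort = default_cohort(n_fish=7, truth=truth, centres=centres, rng_seed=11)
    table, _ = generate_dataset(cohort, truth, with_traces=False)
    return table, truth
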