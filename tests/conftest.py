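import math

import pytest

from paleoscan import demography as dm


@pytest.fixture(scope="session")
def small_model():
    """A lambda-10 rescaled time-transect model with a short genome,
    cheap enough for repeated simulation in unit tests."""
    return dm.rescale_model(
        dm.prh_model(sequence_length=5e4, sample_size=10), 10.0
    )


@pytest.fixture(scope="session")
def one_pop_model():
    """Single constant-size population, the textbook neutral case."""

    def build(n=500.0, sample_size=10, L=2e5, mu=2.5e-7):
        pops = [
            dm.PopulationSpec(
                "POP", (dm.Epoch(0.0, math.inf, n),), sampling_time=0.0,
                sample_size=sample_size,
            )
        ]
        return dm.DemographicModel(
            populations=pops, splits=[], admixture=None,
            mutation_rate=mu, recombination_rate=mu, sequence_length=L,
        )

    return build
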