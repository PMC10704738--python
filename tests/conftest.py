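import numpy as np
import pytest

from rosscreen.synthetic_data import SyntheticSpec, generate_library


@pytest.fixture(scope="session")
def small_spec():
    """A small but non-trivial synthetic screen (fast to generate)."""
    return SyntheticSpec(
        n_compounds=1200,
        n_features=40,
        n_informative=5,
        modulator_fraction=0.05,
        noise_sd=0.2,
        seed=11,
    )


@pytest.fixture(scope="session")
def small_library(small_spec):
    return generate_library(small_spec)


@pytest.fixture(scope="session")
def paper_scale_library():
    """Synthetic stand-in at the scale of the motivating screen."""
    return generate_library(SyntheticSpec())


@pytest.fixture()
def rng():
    return np.random.default_rng(20240917)
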