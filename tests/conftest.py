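import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from paralign import FamilyModel, default_params, gen_family

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def protein_params():
    return default_params("protein")


@pytest.fixture(scope="session")
def dna_params():
    return default_params("dna")


@pytest.fixture(scope="session")
def small_family():
    """Eight related protein sequences, short enough for fast pipelines."""
    return gen_family(FamilyModel(
        n_sequences=8, mean_length=60, min_length=30, max_length=120,
        sigma_log=0.3, seed=11,
    ))


@pytest.fixture()
def rng():
    return np.random.default_rng(20260917)
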