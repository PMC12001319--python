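import numpy as np
import pytest

from ddlseg.grids import Mask, StructureSet, Volume
from ddlseg.meta_training import TrainConfig
from ddlseg.metrics import LossSchedule
from ddlseg.network import ArchSpec, init_state
from ddlseg.phantom import generate_cohort, generate_subject

UNIT_SPACING = (1.0, 1.0, 1.0)


def random_mask(rng, shape, p=0.2):
    return Mask(rng.random(shape) < p, UNIT_SPACING)


@pytest.fixture(scope="session")
def small_cohort():
    """Twelve phantom subjects at the reference grid, shared across tests."""
    return generate_cohort(12, seed=100)


@pytest.fixture(scope="session")
def one_subject():
    return generate_subject(0)


@pytest.fixture(scope="session")
def tiny_arch():
    """Smallest architecture exercised end-to-end in unit tests."""
    return ArchSpec(base_features=4)


@pytest.fixture(scope="session")
def tiny_state(tiny_arch):
    return init_state(tiny_arch, seed=7)


@pytest.fixture(scope="session")
def tiny_config():
    """Fast config for training-mechanics tests (not the reference run)."""
    return TrainConfig(
        iterations=5,
        base_features=4,
        shape=(16, 16, 16),
        n_subjects=12,
        seed=3,
        schedule=LossSchedule(),
    )


@pytest.fixture(scope="session")
def tiny_cohort(tiny_config):
    return generate_cohort(
        tiny_config.n_subjects,
        seed=500,
        shape=tiny_config.shape,
        spacing=tiny_config.spacing,
        noise_sd=tiny_config.noise_sd,
    )
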