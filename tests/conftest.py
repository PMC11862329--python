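import dataclasses

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from bufferscape import (
    LinearPredictorSpec,
    build_kernel_sequence,
    generate_driver_matrix,
    make_reference_species,
)

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def reference_species():
    """The fixed one-driver reference species (n_mesh = 60)."""
    return make_reference_species()


@pytest.fixture(scope="session")
def small_species():
    """A coarse-mesh variant of the reference species for cheap landscape tests."""
    return make_reference_species(n_mesh=20)


@pytest.fixture(scope="session")
def constant_fertility_species():
    """Reference species with environment-independent fertility.

    Only the progression subkernel varies in time, so P/F subkernel
    elasticities partition the whole-kernel sum exactly.
    """
    ipm = make_reference_species()
    return dataclasses.replace(
        ipm,
        offspring=LinearPredictorSpec(
            intercept=2.0, terms=(("size", 0.15),), link="log"
        ),
    )


def make_sequence(ipm, phi=0.0, sigma2_prop=1.0, T=300, seed=1):
    env = generate_driver_matrix(ipm, phi, sigma2_prop, T, seed=seed)
    return build_kernel_sequence(ipm, env)


@pytest.fixture(scope="session")
def reference_sequence(reference_species):
    """A 300-step baseline kernel sequence of the reference species."""
    return make_sequence(reference_species, T=300, seed=1)
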