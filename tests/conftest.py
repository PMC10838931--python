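"""Shared fixtures: a small synthetic head, sensor array and forward
model reused across the inversion-level tests."""

import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from opmlesion import (
    ConductorModel,
    build_array,
    brain_shell,
    generate_patient,
    make_head,
    normal_oriented_sources,
    single_shell_leadfield,
)


@pytest.fixture(scope="session")
def head_small():
    """Order-3 cortex (642 vertices), spherical scalp."""
    return make_head(order=3, seed=1, scalp_order=3)


@pytest.fixture(scope="session")
def array_small(head_small):
    return build_array(head_small.scalp, spacing=45.0, seed=0)


@pytest.fixture(scope="session")
def sources_small(head_small):
    return normal_oriented_sources(head_small.cortex)


@pytest.fixture(scope="session")
def leadfield_small(head_small, array_small, sources_small):
    shell = ConductorModel(
        kind="shell", mesh=brain_shell(head_small), order=8
    )
    return single_shell_leadfield(array_small, sources_small, shell)


@pytest.fixture(scope="session")
def patient_two_lesions(head_small):
    """Two well-separated lesions on the small head."""
    return generate_patient(
        head_small, 2, area_range=(400.0, 900.0), separation=(60.0, None), seed=7
    )


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(0)
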