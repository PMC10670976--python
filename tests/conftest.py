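import dataclasses

import pytest
from hypothesis import HealthCheck, settings

from stilbex import datasets
from stilbex.engine import EngineParams
from stilbex.sigma import ComponentRecord
from stilbex.synth import ProfileSpec, make_profile

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

#: cm^3/mol -> A^3 per molecule
CM3MOL_TO_A3 = 1.6605390671


def synth_component(
    name: str,
    bumps,
    molar_volume: float = 100.0,
    molar_mass: float = 100.0,
    density=None,
) -> ComponentRecord:
    """Component with a Gaussian-bump profile sized to its molar volume."""
    profile = dataclasses.replace(
        make_profile(ProfileSpec(name, tuple(bumps))),
        volume=molar_volume * CM3MOL_TO_A3,
    )
    return ComponentRecord(
        name,
        molar_mass,
        molar_volume,
        density=density,
        sigma_profile=profile,
    )


@pytest.fixture(scope="session")
def registry():
    return datasets.load_registry()


@pytest.fixture(scope="session")
def params():
    return EngineParams()


@pytest.fixture(scope="session")
def apolar_solvent():
    return synth_component("apolar_solvent", [(0.0, 0.004, 200.0)], 120.0, 90.0)


@pytest.fixture(scope="session")
def polar_solvent():
    return synth_component(
        "polar_solvent",
        [(-0.015, 0.003, 90.0), (0.015, 0.003, 90.0)],
        100.0,
        80.0,
    )
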