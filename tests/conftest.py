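import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from particokinetics import Medium, ParticleSpec

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def culture_medium() -> Medium:
    """Serum-free culture medium at 37 C (the shared simulation conditions)."""
    return Medium(temperature=310.0, viscosity=6.9e-4, density=1000.0)


@pytest.fixture(scope="session")
def serum_medium() -> Medium:
    """Serum-containing DMEM used for the silica transport comparison."""
    return Medium(temperature=310.0, viscosity=7.4e-4, density=1000.0)


@pytest.fixture(scope="session")
def polystyrene_24nm() -> ParticleSpec:
    return ParticleSpec(diameter=24e-9, density=1050.0, label="polystyrene 24 nm")


@pytest.fixture(scope="session")
def counting_exposure_kwargs() -> dict:
    """Geometry of the microscopy counting experiment (SI)."""
    return dict(
        concentration=3.7e8 * 1e6,  # 3.7e8 particles/mL
        basis="number",
        duration=500.0,
        media_height=0.31e-2,
        deposition_area=3.717e-5 * 1e-4,
    )
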