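import pytest
from hypothesis import settings, HealthCheck

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

from pineloc import CameraModel


@pytest.fixture(scope="session")
def cam() -> CameraModel:
    """Reference device: 64/41 degree FOV, 1920x1080, 6 mm range bias."""
    return CameraModel()


@pytest.fixture(scope="session")
def indoor_table():
    from pineloc.io import load_indoor_table

    return load_indoor_table()


@pytest.fixture(scope="session")
def outdoor_table():
    from pineloc.io import load_outdoor_table

    return load_outdoor_table()
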