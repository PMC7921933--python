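import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

from punctfem import table_params  # noqa: E402

# the nine measured (storage day, velocity, bioyield force N, deformation mm)
# conditions of the packaged puncture table, reused across tests
MEASURED_PAIRS = [
    (0, 1.5, 17.81, 1.5),
    (0, 2.0, 17.87, 1.67),
    (0, 2.5, 18.36, 1.8),
    (4, 1.5, 14.87, 1.21),
    (4, 2.0, 15.31, 1.35),
    (4, 2.5, 16.42, 1.45),
    (7, 1.5, 13.20, 1.22),
    (7, 2.0, 13.43, 1.38),
    (7, 2.5, 13.55, 1.43),
]


@pytest.fixture(scope="session")
def avg_materials():
    return {"skin": table_params("skin", "avg"), "flesh": table_params("flesh", "avg")}
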