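import pytest
from hypothesis import HealthCheck, settings

from dcacheam import (
    builtin_motif,
    choline_reference_protocol,
    make_reference_template,
)

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def template():
    return make_reference_template(seed=0)


@pytest.fixture(scope="session")
def am_motif():
    return builtin_motif("AM")


@pytest.fixture(scope="session")
def aa_motif():
    return builtin_motif("AA")


@pytest.fixture(scope="session")
def reference_protocol():
    return choline_reference_protocol()
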