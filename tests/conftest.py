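import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "deterministic",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("deterministic")

from toxinkg import fixtures  # noqa: E402
from toxinkg.study_model import ProfileRegistry  # noqa: E402
from toxinkg.toxrtool import Rulebook  # noqa: E402


@pytest.fixture(scope="session")
def registry():
    return ProfileRegistry.builtin()


@pytest.fixture(scope="session")
def profile_408(registry):
    return registry.get("OECD_408")


@pytest.fixture(scope="session")
def profile_401(registry):
    return registry.get("OECD_401")


@pytest.fixture(scope="session")
def rulebook():
    return Rulebook.builtin()


@pytest.fixture(scope="session")
def table2():
    return fixtures.load_table2()


@pytest.fixture(scope="session")
def kg_dataset():
    return fixtures.load_kg_dataset()


@pytest.fixture()
def complete_study(registry):
    """A fully evidenced synthetic 90-day study (every checklist question
    answerable from structured fields)."""
    cfg = fixtures.GeneratorConfig(seed=11, n_studies=1)
    return fixtures.generate_studies(cfg)[0]
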