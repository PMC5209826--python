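import json
from pathlib import Path

import pytest
from hypothesis import HealthCheck, settings

from depclaims import generate, calibrated_params, tiny_fixture

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")

DATA_DIR = Path(__file__).parent / "data"


@pytest.fixture(scope="session")
def fixture_bundle():
    return tiny_fixture()


@pytest.fixture(scope="session")
def fixture_truth():
    with open(DATA_DIR / "tiny_fixture_truth.json") as fh:
        return json.load(fh)


@pytest.fixture(scope="session")
def small_bundle():
    """A 1,000-person synthetic bundle with the calibrated structure."""
    return generate(calibrated_params(1000, seed=1))


@pytest.fixture(scope="session")
def medium_bundle():
    """A 20,000-person bundle, large enough for rate comparisons."""
    return generate(calibrated_params(20_000, seed=4))
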