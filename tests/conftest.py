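import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from sahitval.synthetic import (
    load_packaged_bundle,
    load_preset,
    make_fixture_bundle,
    reference_cohort,
)

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def bundle():
    return load_packaged_bundle()


@pytest.fixture(scope="session")
def pa_preset():
    return load_preset("pa")


@pytest.fixture(scope="session")
def ref_cohort():
    return reference_cohort()


@pytest.fixture(scope="session")
def fixture_paths(tmp_path_factory):
    """Deterministic fixture bundle (cohort CSV, model JSONs, frozen metrics)."""
    out = tmp_path_factory.mktemp("fixtures")
    return make_fixture_bundle(seed=7, out_dir=out)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
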