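import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=30,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def tscale():
    from bitterx.receptors import load_tscale

    return load_tscale()


@pytest.fixture(scope="session")
def small_molecules():
    """Thirty distinct standardized synthetic molecules."""
    from bitterx.synthetic import synth_molecules

    return synth_molecules(30, seed=7)


@pytest.fixture(scope="session")
def demo_bundle(tmp_path_factory):
    """A trained synthetic model bundle, saved and reloaded from disk."""
    from bitterx.fixtures import build_demo_bundle
    from bitterx.pipeline import ModelBundle

    d = tmp_path_factory.mktemp("bundle")
    build_demo_bundle(d, seed=11)
    return ModelBundle.load(d)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
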