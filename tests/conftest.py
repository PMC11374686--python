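import numpy as np
import pytest

from batmap.frames import build_frames
from batmap.synth import fixture_params, generate_session

FIXTURE_SEED = 0


@pytest.fixture(scope="session")
def fixture_bundle():
    """Canonical desk-scale session with the four reference units."""
    session, bundle, truth = generate_session(fixture_params(), FIXTURE_SEED)
    return session, bundle, truth


@pytest.fixture(scope="session")
def fixture_frames(fixture_bundle):
    session, _, _ = fixture_bundle
    return build_frames(session, seed=FIXTURE_SEED)


@pytest.fixture(scope="session")
def fixture_units(fixture_bundle):
    session, _, _ = fixture_bundle
    return {u.unit_id: u for u in session.units}


@pytest.fixture(scope="session")
def jitterfree_bundle():
    """Small session with zero path jitter and zero tracking noise."""
    params = fixture_params(n_blocks=2, n_traverses=4)
    params.path_jitter_m = 0.0
    params.rest_noise_m = 0.0
    params.traverse_jitter_m = 0.0
    session, bundle, truth = generate_session(params, FIXTURE_SEED)
    return session, bundle, truth


@pytest.fixture(scope="session")
def jitterfree_frames(jitterfree_bundle):
    session, _, _ = jitterfree_bundle
    return build_frames(session, seed=FIXTURE_SEED)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
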