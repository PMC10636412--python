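import numpy as np
import pytest

from neurodyad import RunConfig, SimParams, generate_session
from neurodyad.calibration import run_recovery_batch, small_montage
from neurodyad.montage import build_grid_montage, default_montage


@pytest.fixture(scope="session")
def montage128():
    return default_montage()


@pytest.fixture(scope="session")
def montage48():
    return small_montage()


def fast_params(**kwargs) -> SimParams:
    """250 Hz / 48-channel defaults used by tests that need a full session."""
    base = dict(n_channels=48, sample_rate=250.0, seed=0)
    base.update(kwargs)
    return SimParams(**base)


@pytest.fixture(scope="session")
def clean_session(montage48):
    """One artifact-free session with known asymmetry, analyzed lazily by
    tests via the pipeline."""
    params = fast_params(
        asymmetry_per_action=(0.0, 0.0, 0.3, 0.3), jitter_sd=200.0, seed=11
    )
    rec, sched, truth = generate_session(params, montage48)
    return params, rec, sched, truth


@pytest.fixture(scope="session")
def full_session_128(montage128):
    """A full-size (128-channel) session with artifacts and bad channels."""
    params = SimParams(
        sample_rate=250.0,
        asymmetry_per_action=(0.1, 0.1, 0.4, 0.4),
        jitter_sd=300.0,
        artifact_rate=2.0,
        n_bad_channels=3,
        seed=21,
    )
    rec, sched, truth = generate_session(params, montage128)
    return params, rec, sched, truth


@pytest.fixture(scope="session")
def recovery_batch():
    """The 50-seed ground-truth recovery batch (shared across acceptance
    criteria 4 and 5 and the property tests; ~1 min)."""
    return run_recovery_batch(n_seeds=50, base_seed=0)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
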