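import numpy as np
import pytest

from connectofp import CohortConfig, generate_cohort


@pytest.fixture(scope="session")
def small_config():
    """Desk-scale cohort with a clear subject fingerprint."""
    return CohortConfig(
        n_subjects=5, n_sessions=4, n_regions=20, n_frames=120, seed=11
    )


@pytest.fixture(scope="session")
def small_cohort(small_config):
    return generate_cohort(small_config)


@pytest.fixture()
def rng():
    return np.random.default_rng(42)


def random_spd(rng, n, cond=None):
    """Random SPD matrix; if cond is given, with that condition number."""
    q, _ = np.linalg.qr(rng.standard_normal((n, n)))
    if cond is None:
        w = rng.uniform(0.5, 2.0, size=n)
    else:
        w = np.geomspace(1.0, cond, n)
    return (q * w) @ q.T
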