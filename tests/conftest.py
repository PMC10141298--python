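import numpy as np
import pytest

from wearfit import SimConfig, build_features, generate_cohort


@pytest.fixture(scope="session")
def cohort200():
    """Default-condition cohort at n=200, fixed seed, with features."""
    bundle, truth = generate_cohort(SimConfig(n_patients=200, seed=0))
    features, log = build_features(bundle, detect_anomalies=False)
    return bundle, truth, features


@pytest.fixture(scope="session")
def cohort500():
    """Large cohort for generator-fidelity checks (moments, sums, gaps)."""
    bundle, truth = generate_cohort(SimConfig(n_patients=500, seed=0))
    return bundle, truth


@pytest.fixture(scope="session")
def failure_mode_cohort():
    """Small cohort with the observed device failure modes forced:
    exactly one on-clip patient and two no-night-wear patients."""
    cfg = SimConfig(n_patients=8, seed=11, n_on_clip=1, n_no_night=2)
    bundle, truth = generate_cohort(cfg)
    return bundle, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
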