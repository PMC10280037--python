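import numpy as np
import pytest

from pulsepair.signals import Segment, apply_norm, fit_norm_stats
from pulsepair.synthetic import SimConfig, generate_cohort


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_cohort():
    """60-patient labelled cohort shared by read-only tests."""
    cfg = SimConfig(n_patients=60, seed=11)
    profiles, recordings = generate_cohort(cfg)
    return cfg, profiles, recordings


@pytest.fixture(scope="session")
def normalized_recordings(small_cohort):
    _, _, recordings = small_cohort
    stats = fit_norm_stats(recordings)
    return [apply_norm(r, stats) for r in recordings]


def make_segment(samples: np.ndarray, pid: str = "p0", idx: int = 0) -> Segment:
    return Segment(pid, f"{pid}_r", idx, samples)


@pytest.fixture
def random_segment(rng):
    return make_segment(rng.normal(size=(800, 2)))
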