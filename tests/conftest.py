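import logging

import numpy as np
import pytest

from mindeeg.montage import make_compact_montage
from mindeeg.preprocess import PreprocConfig, cohort_to_trialset
from mindeeg.simulate import SimConfig, simulate_cohort

logging.disable(logging.WARNING)  # silence the artifact-removal no-op notice


@pytest.fixture(scope="session")
def compact_montage():
    return make_compact_montage(16)


@pytest.fixture(scope="session")
def small_trialset(compact_montage):
    """Homogeneous 3-subject cohort on the 16-channel montage, 60-s segments
    (12 five-second trials per condition and subject)."""
    cfg = SimConfig(raw_rate=250.0, segment_duration=60.0, rng_seed=11)
    recs = simulate_cohort(3, cfg, dispersion=0.0, montage=compact_montage)
    return cohort_to_trialset(recs, PreprocConfig(bad_channels=()))


@pytest.fixture(scope="session")
def hetero_trialset(compact_montage):
    """Heterogeneous 4-subject cohort (dispersion 0.8) with 2-s trials,
    sized for quick network training."""
    cfg = SimConfig(raw_rate=250.0, segment_duration=40.0, rng_seed=29)
    recs = simulate_cohort(4, cfg, dispersion=0.8, montage=compact_montage)
    pre = PreprocConfig(bad_channels=(), trial_len=501, trial_hop=500)
    return cohort_to_trialset(recs, pre)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
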