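import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for tests.oracles as `oracles`

from netsig import pipeline, synth


@pytest.fixture(scope="session")
def mini_cohort():
    """A small but complete two-group cohort (4/group, 60 s)."""
    cfg = synth.CohortConfig(n_per_group=4, duration=60.0, seed=123)
    recordings, clinical, truth = synth.gen_cohort(cfg)
    return cfg, recordings, clinical, truth


@pytest.fixture(scope="session")
def mini_features(mini_cohort):
    cfg, recordings, clinical, truth = mini_cohort
    features = pipeline.extract_features(recordings, epoch_target=60.0,
                                         epoch_tol=10.0)
    return features


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
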