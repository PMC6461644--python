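import sys
import warnings
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # tests/oracles.py

from gbmprog import synth
from gbmprog.survstats import SurvivalSample

# lifelines emits convergence chatter on tiny dichotomized fits
warnings.filterwarnings("ignore", module="lifelines")


def random_sample(rng, n, censor_p=0.2, tie_p=0.0):
    """A random right-censored survival sample, optionally with tied times."""
    times = rng.exponential(12.0, size=n) + 0.1
    if tie_p > 0:
        ties = rng.uniform(size=n) < tie_p
        times[ties] = np.round(times[ties])
        times = np.maximum(times, 0.5)
    events = rng.uniform(size=n) > censor_p
    if events.sum() < 2:
        events[:2] = True
    return SurvivalSample(times, events)


@pytest.fixture(scope="session")
def discovery_cohort():
    """Default-sized discovery cohort, shared across tests (read-only)."""
    cfg = synth.CohortConfig(seed=11)
    X, rec = synth.generate_cohort(cfg)
    return cfg, X, synth.cohort_to_sample(rec)


@pytest.fixture(scope="session")
def small_cohort():
    cfg = synth.CohortConfig(n_patients=80, seed=7, n_noise_features=4)
    X, rec = synth.generate_cohort(cfg)
    return cfg, X, synth.cohort_to_sample(rec)
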