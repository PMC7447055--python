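import numpy as np
import pytest

from musicphys.stimuli import load_stimulus_table
from musicphys.synth import MEASURES, GeneratorConfig, simulate_cohort


@pytest.fixture(scope="session")
def stimuli():
    return load_stimulus_table()


@pytest.fixture(scope="session")
def small_cohort():
    """Rendered cohort, reduced size: 3 participants x 8 stimuli, full trial
    length and sampling rate, moderate task effect on every measure."""
    cfg = GeneratorConfig(
        n_participants=3,
        n_stimuli=8,
        seed=42,
        task_effect={m: 0.3 for m in MEASURES},
    )
    return simulate_cohort(cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
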