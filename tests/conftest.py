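import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from hippus.synthetic import CohortSpec, adhd_preset, simulate_cohort, td_preset


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_cohort():
    """4 TD-like + 4 ADHD-like subjects, 20 s each: enough epochs to drive
    every pipeline stage while staying fast."""
    spec = CohortSpec(
        groups=[td_preset(4, duration_s=20.0), adhd_preset(4, duration_s=20.0)],
        seed=7,
    )
    return simulate_cohort(spec)
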