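import numpy as np
import pytest

from tonelearn import synthgen
from tonelearn.types import PitchTrack, StimulusSpec


@pytest.fixture(scope="session")
def catalog():
    return synthgen.make_stimulus_catalog()


@pytest.fixture(scope="session")
def small_cohort():
    """A compact cohort (4/group, 3 blocks) shared by behavioral tests."""
    cfg = synthgen.CohortConfig(n_per_group=4, n_blocks=3, seed=42)
    return synthgen.simulate_learner_cohort(cfg)


def linear_stimulus(tone: str, f0_start: float, f0_end: float, duration: float = 0.4):
    """Stimulus with an analytically linear F0 contour (test oracle input)."""
    t = np.linspace(0.0, duration, 41)
    return StimulusSpec(
        syllable="syn",
        talker="talker1",
        tone=tone,
        duration=duration,
        f0=PitchTrack(t, np.linspace(f0_start, f0_end, 41)),
    )


@pytest.fixture(scope="session")
def t2_stimulus():
    return linear_stimulus("T2", 110.0, 200.0)
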