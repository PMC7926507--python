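import numpy as np
import pytest

from accelvo2 import (
    GroundTruth,
    MinuteWindow,
    features_table,
    generate_session,
    segment_minutes,
)


def make_window(rng: np.random.Generator, n: int = 240, scale: float = 0.2,
                label: str = "Mopping the floor", vo2: float = 6.0) -> MinuteWindow:
    """A random but valid four-channel window around 1 g."""
    x = rng.normal(0.0, scale, n)
    y = 0.2 + rng.normal(0.0, scale, n) + 0.1 * np.sin(np.arange(n) / 5.0)
    z = 0.9 + rng.normal(0.0, 0.5 * scale, n)
    rv = np.sqrt(x**2 + y**2 + z**2)
    return MinuteWindow(x=x, y=y, z=z, rv=rv, label=label, type="Housework",
                        vo2=vo2, participant_id="P01")


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20210222)


@pytest.fixture(scope="session")
def random_window():
    return make_window(np.random.default_rng(7))


@pytest.fixture(scope="session")
def small_session():
    """One synthetic session at 10 Hz (600-sample windows), noiseless VO2."""
    return generate_session("P01", rate=10.0, seed=11,
                            truth=GroundTruth(noise_sd=0.0))


@pytest.fixture(scope="session")
def small_feature_table(small_session):
    return features_table(segment_minutes(small_session))
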