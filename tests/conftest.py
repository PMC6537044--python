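import numpy as np
import pytest

from anchorscreen import ScreenSimSpec, score_plates, simulate_screen


@pytest.fixture(scope="session")
def small_screen():
    """A 200-compound duplicate screen with planted truth (session-cached)."""
    spec = ScreenSimSpec(n_compounds=200, seed=11)
    plates, truth = simulate_screen(spec)
    return spec, plates, truth


@pytest.fixture(scope="session")
def small_scores(small_screen):
    _, plates, _ = small_screen
    return score_plates(plates)
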