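import numpy as np
import pytest

from primemeg import synthetic


@pytest.fixture(scope="session")
def layout32():
    return synthetic.generate_layout(32, seed=0)


@pytest.fixture(scope="session")
def shell_grid():
    return synthetic.default_source_grid()


@pytest.fixture(scope="session")
def leadfield32(layout32, shell_grid):
    pos, labels = shell_grid
    return synthetic.generate_lead_field(layout32, pos, labels)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def make_trials(rows):
    """Build a trial table from (subject, condition, prime, target, hand, rt,
    correct, tone2_class, loudness_response) tuples."""
    import pandas as pd

    frame = pd.DataFrame(rows, columns=synthetic.TRIAL_COLUMNS)
    frame.index.name = "trial"
    return frame
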