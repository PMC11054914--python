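import numpy as np
import pytest

import pupilgrid as pg


@pytest.fixture(scope="session")
def easy_lowres_samples():
    """A small easy-profile 20x15 dataset shared across tests."""
    return pg.generate_dataset(60, "easy", 20, 15, seed=7)


@pytest.fixture(scope="session")
def toy_spec():
    """The hand-checkable input(1x4) -> dense(2) -> softmax(3) network."""
    from pupilgrid.netspec import Dense, Input, NetworkSpec, Softmax

    return NetworkSpec((Input(1, 4), Dense(2), Softmax(3)))
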