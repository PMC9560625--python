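import numpy as np
import pytest
from hypothesis import settings

from zooms_screen.marker_db import example_database

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def db():
    """The illustrative marker database shipped with the package."""
    return example_database()


@pytest.fixture
def rng():
    return np.random.default_rng(20220913)
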