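import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for the reference oracle

from animats.environment import TaskSpec
from animats.examples import xor_loop_system


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def task1():
    return TaskSpec.task(1)


@pytest.fixture(scope="session")
def xor_example():
    return xor_loop_system()
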