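import os
import sys

import numpy as np
import pytest
from hypothesis import settings

sys.path.insert(0, os.path.dirname(__file__))  # makes helpers.py importable

settings.register_profile("repro", derandomize=True, deadline=None)
settings.load_profile("repro")

from dagvalid import bone_dag, bone_sem_spec, simulate_sem


@pytest.fixture(scope="session")
def bone():
    return bone_dag()


@pytest.fixture(scope="session")
def bone_study_large():
    """Faithful draw from the bone SEM at large n, standard-normal exposure."""
    spec = bone_sem_spec(n=2_000, seed=20260923, beta=0.5,
                         exposure_design="continuous_gaussian")
    return simulate_sem(spec)


@pytest.fixture
def rng():
    return np.random.default_rng(20260923)
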