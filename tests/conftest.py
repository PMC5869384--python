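import sys
import warnings
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from toxannot.simulate import SimulationConfig


@pytest.fixture(scope="session")
def small_config() -> SimulationConfig:
    """A reduced benchmark used by pipeline-level tests: fast but complete."""
    return SimulationConfig(seed=11, n_families=3, leaves_per_family=(6, 10))


@pytest.fixture(scope="session")
def small_run(small_config):
    from toxannot.pipeline import run_synthetic
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return run_synthetic(small_config)


@pytest.fixture(scope="session")
def study_df():
    """The 50-seed end-to-end replicate study under default conditions.

    Shared session-wide: several acceptance properties and the clade-filter
    containment invariant are all read off the same replicates.
    """
    from toxannot.study import replicate_study
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return replicate_study(n_seeds=50)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
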