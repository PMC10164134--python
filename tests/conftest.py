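import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for oracles.py

from wntgct.cohort_io import load_cohort
from wntgct.synthetic_cohort import SimulationConfig, generate_cohort


@pytest.fixture(scope="session")
def small_cohort_dir(tmp_path_factory):
    """A small simulated cohort on disk, shared across tests."""
    d = tmp_path_factory.mktemp("cohort")
    cfg = SimulationConfig(n_samples=30, seed=11)
    truth = generate_cohort(cfg, d)
    return d, truth, cfg


@pytest.fixture(scope="session")
def small_cohort(small_cohort_dir):
    d, truth, cfg = small_cohort_dir
    return load_cohort(d), truth, cfg
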