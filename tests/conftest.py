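import numpy as np
import pandas as pd
import pytest

from mitoage.simulate import SimConfig, simulate_study


@pytest.fixture(scope="session")
def small_study():
    """One simulated 4-cohort study reused across read-only tests."""
    cfg = SimConfig(n_per_cohort=(200, 200, 200, 200), seed=11)
    return simulate_study(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def make_calls(rows):
    """Build a call table from (sample, pos, ref, alt, vaf, depth) tuples."""
    return pd.DataFrame(
        rows, columns=["sample_id", "position", "ref", "alt", "vaf", "depth"]
    )
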