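import dataclasses

import numpy as np
import pandas as pd
import pytest

from cordmrs.simulate import SimConfig, simulate_cohort, simulate_discovery_sumstats


@pytest.fixture(scope="session")
def small_config() -> SimConfig:
    return SimConfig(
        n_samples=150, n_cpgs=200, n_causal=8, seed=101, structure_seed=7,
    )


@pytest.fixture(scope="session")
def small_bundle(small_config):
    return simulate_cohort(small_config, population="european")


@pytest.fixture(scope="session")
def small_sumstats(small_config, small_bundle):
    return simulate_discovery_sumstats(small_config, small_bundle.truth, n_discovery=5000)


@pytest.fixture(scope="session")
def complete_bundle():
    """A cohort without missing entries (for stages requiring complete data)."""
    cfg = SimConfig(
        n_samples=150, n_cpgs=200, n_causal=8, missing_rate=0.0, seed=101,
        structure_seed=7,
    )
    return simulate_cohort(cfg, population="european")


@pytest.fixture()
def tiny_beta():
    return pd.DataFrame(
        [[0.1, 0.2], [0.8, 0.9]],
        index=["cg000001", "cg000002"],
        columns=["s1", "s2"],
    )
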