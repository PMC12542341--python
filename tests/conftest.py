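import numpy as np
import pandas as pd
import pytest

from methmir import SampleSheet, SimulationConfig, simulate_study


@pytest.fixture(scope="session")
def default_study():
    """One full synthetic study at the default configuration."""
    return simulate_study(SimulationConfig(seed=1))


@pytest.fixture(scope="session")
def small_config():
    """A miniature configuration for fast CLI / round-trip tests."""
    return SimulationConfig(
        n_probes=300,
        n_features_pri=40,
        n_features_mature=40,
        n_cnt=6,
        n_idcm=8,
        n_true_dmps=20,
        n_sex_probes=5,
        n_true_de=4,
        seed=7,
    )


@pytest.fixture(scope="session")
def small_study(small_config):
    return simulate_study(small_config)


@pytest.fixture
def toy_sheet():
    """Six samples, balanced groups, mixed sex."""
    return SampleSheet(
        pd.DataFrame(
            {
                "group": ["CNT", "CNT", "CNT", "iDCM", "iDCM", "iDCM"],
                "sex": ["M", "F", "M", "F", "M", "F"],
            },
            index=pd.Index([f"S{i}" for i in range(6)], name="sample_id"),
        )
    )
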