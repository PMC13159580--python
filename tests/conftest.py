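import pytest

from pretermcast import SyntheticConfig, generate_study_bundle
from pretermcast import datasets


@pytest.fixture(scope="session")
def config_seed1():
    return SyntheticConfig(seed=1)


@pytest.fixture(scope="session")
def bundle_seed1(config_seed1):
    """Noise-free synthetic study bundle, seed 1 (session-wide)."""
    return generate_study_bundle(config_seed1)


@pytest.fixture(scope="session")
def kz_vitals():
    return datasets.load_vital_series()


@pytest.fixture(scope="session")
def kz_pairs():
    return datasets.load_backtest_pairs()
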