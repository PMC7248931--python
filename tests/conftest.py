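import numpy as np
import pytest

from acdimer import default_config, simulate_fep_ensemble

# generator defaults: the acetic-acid experimental estimates
TRUE_DH = -15.4
TRUE_DS = -36.6
TRUE_DELTA_M = 3.76
TRUE_DELTA_D = 10.55


@pytest.fixture(scope="session")
def small_ensemble():
    """A modest 4-temperature synthetic ensemble plus its configuration."""
    cfg = default_config(seed=1234, n_points=600)
    datasets, truths = simulate_fep_ensemble(cfg)
    return cfg, datasets, truths


@pytest.fixture()
def rng():
    return np.random.default_rng(20260924)
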