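import numpy as np
import pytest

from pabreast import experiments


@pytest.fixture
def rng():
    return np.random.default_rng(20240)


@pytest.fixture(scope="session")
def reduced_sweep():
    """Desk-scale reduced sweep shared by the slower end-to-end checks.

    757 and 1064 nm, one ITA per skin tone category, four target diameters,
    DAS and SLSC beamforming, fixed master seed.
    """
    cfg = experiments.SweepConfig(wavelengths=(757, 1064),
                                  methods=("DAS", "SLSC"),
                                  master_seed=12345)
    table, agg = experiments.run_sweep(cfg)
    return cfg, table, agg
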