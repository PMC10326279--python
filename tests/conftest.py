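import numpy as np
import pytest

from somnoscore.network import ModelConfig, TwoBranchNet
from somnoscore.simulator import SimConfig, simulate_dataset


@pytest.fixture(scope="session")
def tiny_cfg() -> ModelConfig:
    return ModelConfig.tiny()


@pytest.fixture()
def tiny_net(tiny_cfg) -> TwoBranchNet:
    return TwoBranchNet(tiny_cfg, seed=0).eval_mode()


@pytest.fixture(scope="session")
def small_dataset():
    """Three short simulated records shared by I/O and trainer tests."""
    cfg = SimConfig(n_records=3, epochs_per_record=40, seed=123, ambiguity=0.5)
    ds, hyps = simulate_dataset(cfg)
    return ds, hyps


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(2024)
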