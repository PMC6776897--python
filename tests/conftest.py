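import numpy as np
import pytest

from xcikit.pipeline import PipelineConfig, run_synthetic_demo
from xcikit.simulate import SimulationConfig, simulate_annotation


@pytest.fixture(scope="session")
def demo_report():
    """Full synthetic demo at the default study conditions (seed 0)."""
    return run_synthetic_demo(PipelineConfig(seed=0))


@pytest.fixture(scope="session")
def small_annotation():
    """A small toy genome for annotation-level tests."""
    cfg = SimulationConfig(
        n_autosomes=2,
        autosome_length=2_000_000,
        chrx_length=2_000_000,
        n_genes=60,
        n_anchor_windows=30,
    )
    return cfg, simulate_annotation(cfg, seed=0)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
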