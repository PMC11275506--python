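import numpy as np
import pytest

from founderscan import SimConfig, simulate_panel
from founderscan.synthdata import core_site_of, emit_vcf


@pytest.fixture(scope="session")
def small_panel():
    """A small selected founder panel shared by I/O and pipeline tests."""
    cfg = SimConfig(
        n_diploids=80,
        n_sites=250,
        region_bp=1_000_000,
        selection_s=0.08,
        seed=11,
    )
    hm, mm, truth = simulate_panel(cfg)
    return hm, mm, truth, core_site_of(mm), cfg


@pytest.fixture(scope="session")
def small_vcf(small_panel, tmp_path_factory):
    hm, mm, truth, core, cfg = small_panel
    prefix = tmp_path_factory.mktemp("vcf") / "panel"
    paths = emit_vcf(hm, mm, truth, prefix, seed=cfg.seed)
    return paths, hm, mm, core


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
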