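import numpy as np
import pytest

from mrlink.harmonize import HarmonizedInstrument, harmonize
from mrlink.simulate import SimConfig, simulate_pair, ra_instruments_fixture


def make_inst(snp_id="rs1", gamma=0.5, sx=0.01, Gamma=0.1, sy=0.02, eaf=0.3):
    return HarmonizedInstrument(
        snp_id=snp_id, gamma_hat=gamma, sigma_x=sx, Gamma_hat=Gamma, sigma_y=sy,
        eaf_exposure=eaf,
    )


def sim_insts(seed=0, **overrides):
    """Harmonized instruments from one synthetic paired dataset."""
    config = SimConfig(seed=seed, **overrides)
    result = simulate_pair(config)
    insts, excluded = harmonize(result.exposure, result.outcome)
    assert not excluded
    return insts, result.truth


@pytest.fixture
def ra_instruments():
    return ra_instruments_fixture()


@pytest.fixture
def default_insts():
    insts, _ = sim_insts(seed=11)
    return insts
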