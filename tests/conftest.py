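import numpy as np
import pytest

from sexlinkage import simulate


@pytest.fixture
def xy_noisefree():
    """Noise-free XY population with all three sex-linked locus classes."""
    params = simulate.PopSimParams(
        n_males=20,
        n_females=20,
        n_loci=1000,
        system="XY",
        prop_sexlinked=0.1,
        prop_y_snp=0.5,
        prop_sex_limited=0.25,
        prop_x_hemizygous=0.25,
        error_rate=0.0,
        missing_rate=0.0,
        seed=42,
    )
    gm, tags, truth = simulate.simulate_population(params)
    return gm, tags, truth, simulate.sample_sheet_for(gm)


@pytest.fixture
def none_system():
    """Population with no sex linkage at all."""
    params = simulate.PopSimParams(
        n_males=10, n_females=10, n_loci=2000, system="NONE", seed=7
    )
    gm, tags, truth = simulate.simulate_population(params)
    return gm, tags, truth, simulate.sample_sheet_for(gm)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
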