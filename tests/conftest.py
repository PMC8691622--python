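import numpy as np
import pytest

from gammasf import model as gm
from gammasf import spectral as sp
from gammasf import synthetic as syn


@pytest.fixture(scope="session")
def gt3() -> syn.GroundTruth:
    """Default three-component ground truth."""
    return syn.make_ground_truth("three_gamma_default", seed=1)


@pytest.fixture(scope="session")
def noiseless_grid(gt3) -> sp.SpectrumGrid:
    """Exact model evaluation on the default SF sampling, 1 Hz bins."""
    sfs = np.asarray(syn.DEFAULT_SFS)
    freqs = np.linspace(20.0, 120.0, 101)
    return sp.SpectrumGrid(
        frequencies=freqs,
        sfs=sfs,
        power=gm.eval_model(gt3.model_params, sfs, freqs),
        blank_power=gm.eval_baseline(gt3.model_params.baseline, freqs),
    )


@pytest.fixture(scope="session")
def lg_optimal_lfp(gt3):
    """200 stimulus-window LFP trials at the LG-optimal SF (~0.33 cpd)."""
    rng = np.random.default_rng(42)
    sf = 0.33
    lfp = np.array(
        [syn.simulate_lfp_trial(gt3, sf, duration=2.0, rate=500.0, rng=rng) for _ in range(200)]
    )
    return sf, lfp
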