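import numpy as np
import pytest

from hrvdbs import synthetic_data as sd
from hrvdbs.ecg_rr import RRISeries


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def constant_rr():
    """Constant 1000 ms series, 61 beats."""
    return RRISeries.from_beat_times(np.arange(61, dtype=float))


@pytest.fixture
def modulated_rr():
    """10-minute IPFM realization with LF and HF modulation."""
    params = sd.IPFMParams(a_LF=0.05, a_HF=0.05, noise_sd=0.02, seed=7)
    return sd.simulate_rr_ipfm(params, 600.0)


@pytest.fixture(scope="session")
def small_cohort():
    """2-subject, 1-block cohort reused across paradigm tests."""
    spec = sd.CohortSpec(
        n_subjects=2, n_improved=1, n_blocks=1,
        effect=sd.EffectModel(outcome_effect=2.0), seed=11,
    )
    return sd.simulate_cohort(spec)
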