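import numpy as np
import pytest

from copsway.core import CoPTrial
from copsway.synthetic_data import SynthSignalParams, gen_cop_trial


@pytest.fixture(scope="session", autouse=True)
def _warm_numba():
    """Compile the numba kernels once so per-test timings stay honest."""
    from copsway.nonlinear_features import _diag_line_stats, _sampen_counts, _vert_line_stats

    x = np.random.default_rng(0).standard_normal(64)
    _sampen_counts(x, 2, 0.2)
    rec = np.zeros((8, 8), dtype=bool)
    _diag_line_stats(rec, 1, 2)
    _vert_line_stats(rec, 2)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def cop_trial():
    """A realistic filtered synthetic trial shared by feature tests."""
    from copsway.preprocess import filter_cop

    return filter_cop(gen_cop_trial(SynthSignalParams(seed=7, periodic_fraction=0.15)))


def make_trial(ap, ml, fs=100.0, condition="EO_firm"):
    return CoPTrial(
        participant_id="T", condition=condition, trial_index=1, fs=fs,
        cop_ap=np.asarray(ap, float), cop_ml=np.asarray(ml, float),
    )
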