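import numpy as np
import pytest
from hypothesis import settings

from infant_pa import EpochRecord, ScalarSeries

settings.register_profile("default", derandomize=True, max_examples=50)
settings.load_profile("default")


def make_epochs(values, labels, subject_id="t"):
    """Epoch records whose both-leg totals equal ``values`` for both
    quantities (each leg carries half), for threshold/evaluation tests."""
    return [
        EpochRecord(
            subject_id=subject_id,
            window_start=2.0 * i,
            window_end=2.0 * i + 2.0,
            gold_label=lab,
            c_a_left=v / 2,
            c_a_right=v / 2,
            c_j_left=v / 2,
            c_j_right=v / 2,
        )
        for i, (v, lab) in enumerate(zip(values, labels))
    ]


def scalar(values, dt=0.05, role="a_ADJ", start_time=0.0):
    return ScalarSeries(np.asarray(values, dtype=float), dt, role, start_time)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
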