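import numpy as np
import pytest

from restmetrics.containers import BoldSeries


@pytest.fixture
def rng():
    return np.random.default_rng(20260920)


def make_bold(data, tr_s=2.17, mask=None, subject_id="sub-test"):
    data = np.asarray(data, dtype=float)
    if mask is None:
        mask = np.ones(data.shape[:3], dtype=bool)
    return BoldSeries(data=data, tr_s=tr_s, mask=mask, subject_id=subject_id)


def series_bold(series, tr_s=2.17):
    """Wrap a 1D time series into a single-voxel BoldSeries."""
    return make_bold(np.asarray(series, dtype=float).reshape(1, 1, 1, -1), tr_s=tr_s)
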