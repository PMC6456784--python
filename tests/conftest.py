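import numpy as np
import pytest

from dynfc import Cohort, RoiTimeSeriesSet


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_set(rng):
    """A 4-region, 200-sample random set at TR 0.72 s."""
    return RoiTimeSeriesSet(
        subject_id="s1",
        region_labels=["A", "B", "C", "D"],
        tr_seconds=0.72,
        data=rng.normal(size=(4, 200)),
    )


@pytest.fixture
def small_cohort(rng):
    subjects = [
        RoiTimeSeriesSet(
            subject_id=f"s{k}",
            region_labels=["A", "B", "C", "D"],
            tr_seconds=0.72,
            data=rng.normal(size=(4, 200)),
        )
        for k in range(5)
    ]
    return Cohort(subjects)
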