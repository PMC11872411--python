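import numpy as np
import pandas as pd
import pytest

from cgps.containers import CellMatrix, Cohort


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_sample(values, markers, sid="s0", batch="b0", transformed=True):
    return CellMatrix(values=np.asarray(values, dtype=float),
                      markers=list(markers), sample_id=sid, subject_id=sid,
                      batch=batch, transformed=transformed)


def make_cohort(samples, groups, outcomes=None):
    rows = []
    for s, g in zip(samples, groups):
        out = None
        if outcomes is not None:
            out = outcomes.get(s.subject_id)
        rows.append({"subject_id": s.subject_id, "group": g,
                     "batch": s.batch, "outcome": out})
    return Cohort(samples=samples, subjects=pd.DataFrame(rows))


@pytest.fixture
def small_cohort(rng):
    """Two tiny samples (HD and cGVHD), three markers, transformed."""
    markers = ["CD19", "CD20", "CD27"]
    s1 = make_sample(rng.normal(3.0, 0.4, (50, 3)), markers, sid="hd0")
    s2 = make_sample(rng.normal(3.0, 0.4, (50, 3)), markers, sid="gv0")
    return make_cohort([s1, s2], ["HD", "cGVHD"])
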