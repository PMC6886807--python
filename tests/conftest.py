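import numpy as np
import pandas as pd
import pytest

from glycoregress.io import CgmTrace
from glycoregress.windowing import WindowedDataset, assign_pseudolabels

EPOCH = pd.Timestamp("2022-01-01 00:00:00")


def make_trace(glucose, gaps_after=(), patient_id="p1", start=EPOCH):
    """Build a 5-min-spaced trace; ``gaps_after`` lists 0-based reading
    indices after which an extra 30-min hole is inserted."""
    glucose = np.asarray(glucose, dtype=float)
    offsets = np.full(len(glucose), 5.0)
    offsets[0] = 0.0
    for idx in gaps_after:
        offsets[idx + 1] += 30.0
    times = start + pd.to_timedelta(np.cumsum(offsets), unit="m")
    return CgmTrace(patient_id=patient_id, times=pd.DatetimeIndex(times), glucose=glucose)


def make_windowed(X, y, patient_id="p1"):
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    return WindowedDataset(
        X=X, y=y, pseudolabel=assign_pseudolabels(y), patient_id=patient_id
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_trace(rng, n=120, gap_prob=0.08, start=EPOCH):
    """Random-walk trace with random 10–120 min gaps, for oracle tests."""
    glucose = np.clip(140 + np.cumsum(rng.normal(0, 4, size=n)), 40, 400)
    offsets = np.full(n, 5.0)
    offsets[0] = 0.0
    gap_mask = rng.random(n - 1) < gap_prob
    offsets[1:][gap_mask] += rng.integers(10, 121, size=gap_mask.sum())
    times = start + pd.to_timedelta(np.cumsum(offsets), unit="m")
    return CgmTrace(patient_id="rand", times=pd.DatetimeIndex(times), glucose=glucose)


def brute_force_window_count(trace, window_len=24, horizon_steps=6, stride=1):
    """Independent oracle: scan every start position, check all consecutive
    steps in the span are within tolerance."""
    span = window_len + horizon_steps
    ok = trace.contiguous_steps()
    count = 0
    for start in range(0, len(trace) - span + 1, stride):
        if all(ok[start : start + span - 1]):
            count += 1
    return count
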