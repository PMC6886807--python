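"""Data model and CSV I/O for timestamped CGM traces.

A continuous glucose monitor (CGM) reports interstitial glucose in mg/dl at a
nominal 5-minute cadence. Real traces contain gaps (sensor swaps, missed
swipes); this module represents a trace faithfully — gaps are kept, never
imputed — and enforces the sensor's physical reporting range of 40–400 mg/dl.

The canonical on-disk format is a two-column CSV with header
``timestamp,glucose_mgdl``, ISO-8601 timestamps, one reading per row.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

GLUCOSE_MIN = 40.0
GLUCOSE_MAX = 400.0

#: Default sensor cadence.
NOMINAL_INTERVAL = pd.Timedelta(minutes=5)
#: Clock-jitter allowance: consecutive readings within nominal ± tolerance are
#: treated as contiguous; larger deltas are gaps.
SPACING_TOLERANCE = pd.Timedelta(seconds=60)

CSV_HEADER = ("timestamp", "glucose_mgdl")


class ValidationError(ValueError):
    """A trace or reading violates a structural invariant."""


def _check_glucose_range(values: np.ndarray) -> None:
    if values.size and (np.any(values < GLUCOSE_MIN) or np.any(values > GLUCOSE_MAX)):
        bad = values[(values < GLUCOSE_MIN) | (values > GLUCOSE_MAX)][0]
        raise ValidationError(
            f"glucose reading {bad:g} mg/dl outside sensor range "
            f"[{GLUCOSE_MIN:g}, {GLUCOSE_MAX:g}]"
        )


@dataclass(frozen=True)
class CgmTrace:
    """An ordered gap-preserving glucose record for one patient.

    Parameters
    ----------
    patient_id
        Free-form identifier carried through windowing and benchmarking.
    times
        Strictly increasing timestamps (minute resolution is sufficient).
    glucose
        Readings in mg/dl, same length as ``times``, each in [40, 400].
    nominal_interval, tolerance
        Cadence and jitter allowance used to decide which consecutive pairs
        are contiguous; a delta above ``nominal_interval + tolerance`` is a
        gap, a delta below ``nominal_interval - tolerance`` (e.g. a duplicate
        timestamp) is invalid.
    """

    patient_id: str
    times: pd.DatetimeIndex
    glucose: np.ndarray
    nominal_interval: pd.Timedelta = NOMINAL_INTERVAL
    tolerance: pd.Timedelta = SPACING_TOLERANCE

    def __post_init__(self) -> None:
        times = pd.DatetimeIndex(self.times)
        glucose = np.asarray(self.glucose, dtype=float)
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "glucose", glucose)
        if len(times) != len(glucose):
            raise ValidationError(
                f"{len(times)} timestamps but {len(glucose)} glucose values"
            )
        if glucose.size and not np.all(np.isfinite(glucose)):
            raise ValidationError("non-finite glucose value")
        _check_glucose_range(glucose)
        if len(times) > 1:
            deltas = np.diff(times.asi8)
            if np.any(deltas <= 0):
                raise ValidationError("timestamps must be strictly increasing")
            min_ns = (self.nominal_interval - self.tolerance).value
            if np.any(deltas < min_ns):
                raise ValidationError(
                    "consecutive readings closer than nominal interval minus "
                    "tolerance (duplicate or over-dense sampling)"
                )

    def __len__(self) -> int:
        return len(self.glucose)

    def contiguous_steps(self) -> np.ndarray:
        """Boolean array of length ``len(self) - 1``; True where consecutive
        readings are within the spacing tolerance (no gap between them)."""
        if len(self) < 2:
            return np.zeros(0, dtype=bool)
        deltas = np.diff(self.times.asi8)
        max_ns = (self.nominal_interval + self.tolerance).value
        return deltas <= max_ns

    def n_gaps(self) -> int:
        return int((~self.contiguous_steps()).sum())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"timestamp": self.times, "glucose_mgdl": self.glucose}
        )

    def replace(self, **kwargs) -> "CgmTrace":
        return dataclasses.replace(self, **kwargs)


@dataclass(frozen=True)
class PatientDataset:
    """Chronological train/test pair for one patient; test strictly follows
    train, mirroring the six-weeks-train / two-weeks-test protocol."""

    train: CgmTrace
    test: CgmTrace

    def __post_init__(self) -> None:
        if len(self.train) == 0 or len(self.test) == 0:
            raise ValidationError("train and test traces must be non-empty")
        if self.train.times[-1] >= self.test.times[0]:
            raise ValidationError(
                "test data must start strictly after the last training reading"
            )

    @property
    def patient_id(self) -> str:
        return self.train.patient_id


def read_trace(path, patient_id: str | None = None) -> CgmTrace:
    """Read a CGM trace from canonical CSV.

    Rows are sorted by timestamp before validation, so out-of-order files are
    accepted; duplicate timestamps and out-of-range glucose are rejected.
    """
    frame = pd.read_csv(path)
    missing = set(CSV_HEADER) - set(frame.columns)
    if missing:
        raise ValidationError(f"CSV missing required columns: {sorted(missing)}")
    try:
        times = pd.to_datetime(frame["timestamp"], format="ISO8601")
    except (ValueError, TypeError) as exc:
        raise ValidationError(f"unparseable timestamp in {path}: {exc}") from exc
    glucose = pd.to_numeric(frame["glucose_mgdl"], errors="raise").to_numpy(float)
    order = np.argsort(times.to_numpy(), kind="stable")
    times = pd.DatetimeIndex(times.to_numpy()[order])
    if times.has_duplicates:
        raise ValidationError(f"duplicate timestamps in {path}")
    if patient_id is None:
        patient_id = _stem(path)
    return CgmTrace(patient_id=patient_id, times=times, glucose=glucose[order])


def write_trace(trace: CgmTrace, path) -> None:
    """Write a trace to canonical CSV (glucose printed to 1 decimal)."""
    trace.to_frame().to_csv(
        path, index=False, float_format="%.1f", date_format="%Y-%m-%dT%H:%M:%S"
    )


def split_chronological(trace: CgmTrace, test_fraction: float = 0.25) -> PatientDataset:
    """Split a trace into a chronological train/test pair.

    The split index is ``floor((1 - test_fraction) * n)``; the default 0.25
    matches the benchmark's ~6-week-train / ~2-week-test ratio.
    """
    if not 0.0 < test_fraction < 1.0:
        raise ValueError("test_fraction must be in (0, 1)")
    n = len(trace)
    if n < 2:
        raise ValidationError("need at least 2 readings to split")
    cut = int(np.floor((1.0 - test_fraction) * n))
    if cut == 0 or cut == n:
        raise ValidationError("split leaves an empty side")
    train = trace.replace(times=trace.times[:cut], glucose=trace.glucose[:cut])
    test = trace.replace(times=trace.times[cut:], glucose=trace.glucose[cut:])
    return PatientDataset(train=train, test=test)


def _stem(path) -> str:
    import os

    return os.path.splitext(os.path.basename(str(path)))[0]
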