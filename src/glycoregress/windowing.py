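"""Sliding-window featurization of CGM traces.

Each supervised example is 24 consecutive readings (120 min at the 5-min
cadence) with the reading 30 min (6 steps) after the window's end as the
regression target bg_{t+30}. Windows containing a gap — between any feature
pair or between the window end and the target — are discarded rather than
imputed. Each example also carries a glycemic *pseudolabel* discretizing the
target (hypo < 70, normal 70–180, hyper > 180 mg/dl); the pseudolabel exists
only so classification-style oversamplers can be applied and is dropped
before any regressor sees the data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import CgmTrace, GLUCOSE_MAX, GLUCOSE_MIN, ValidationError

L_HYPO = "L_<70"
L_NORMAL = "L_normal"
L_HYPER = "L_>180"
PSEUDOLABELS = (L_HYPO, L_NORMAL, L_HYPER)

WINDOW_LEN = 24
HORIZON_STEPS = 6


@dataclass(frozen=True)
class GlycemicThresholds:
    """Level-1 glycemic range boundaries in mg/dl.

    Boundary readings are normal: hypoglycemia is strictly below ``hypo`` and
    hyperglycemia strictly above ``hyper``.
    """

    hypo: float = 70.0
    hyper: float = 180.0

    def __post_init__(self) -> None:
        if not GLUCOSE_MIN < self.hypo < self.hyper < GLUCOSE_MAX:
            raise ValidationError(
                f"thresholds must satisfy {GLUCOSE_MIN:g} < hypo < hyper < "
                f"{GLUCOSE_MAX:g}, got ({self.hypo}, {self.hyper})"
            )


DEFAULT_THRESHOLDS = GlycemicThresholds()


def assign_pseudolabel(bg: float, thresholds: GlycemicThresholds = DEFAULT_THRESHOLDS) -> str:
    """Discretize one target value into its glycemic pseudolabel."""
    if bg < thresholds.hypo:
        return L_HYPO
    if bg > thresholds.hyper:
        return L_HYPER
    return L_NORMAL


def assign_pseudolabels(
    bg: np.ndarray, thresholds: GlycemicThresholds = DEFAULT_THRESHOLDS
) -> np.ndarray:
    """Vectorized :func:`assign_pseudolabel`."""
    bg = np.asarray(bg, dtype=float)
    out = np.full(bg.shape, L_NORMAL, dtype=object)
    out[bg < thresholds.hypo] = L_HYPO
    out[bg > thresholds.hyper] = L_HYPER
    return out


@dataclass
class WindowedDataset:
    """Feature matrix + targets + pseudolabels for one patient.

    ``X`` has one row per window (columns x_1..x_24 oldest→newest), ``y`` is
    the 30-min-ahead target, ``pseudolabel`` its glycemic class. ``end_times``
    marks each window's last feature timestamp (NaT for synthetic rows).
    ``provenance`` records, for rows created by a synthetic oversampler, the
    parent rows and interpolation coefficient that generated them.
    """

    X: np.ndarray
    y: np.ndarray
    pseudolabel: np.ndarray
    patient_id: str = ""
    thresholds: GlycemicThresholds = DEFAULT_THRESHOLDS
    end_times: np.ndarray | None = None
    provenance: list = field(default_factory=list)

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        self.pseudolabel = np.asarray(self.pseudolabel, dtype=object)
        if self.X.ndim != 2:
            raise ValidationError("X must be 2-D")
        if not (len(self.X) == len(self.y) == len(self.pseudolabel)):
            raise ValidationError("X, y and pseudolabel lengths differ")
        expected = assign_pseudolabels(self.y, self.thresholds)
        if len(self.y) and not np.array_equal(expected, self.pseudolabel):
            raise ValidationError("pseudolabels inconsistent with targets")

    def __len__(self) -> int:
        return len(self.y)

    @property
    def n_features(self) -> int:
        return self.X.shape[1]

    def class_counts(self) -> dict[str, int]:
        return {c: int(np.sum(self.pseudolabel == c)) for c in PSEUDOLABELS}

    def class_indices(self, label: str) -> np.ndarray:
        return np.flatnonzero(self.pseudolabel == label)

    def to_frame(self) -> pd.DataFrame:
        cols = {f"x{i + 1}": self.X[:, i] for i in range(self.X.shape[1])}
        cols["target"] = self.y
        cols["pseudolabel"] = self.pseudolabel
        return pd.DataFrame(cols)

    @classmethod
    def from_frame(
        cls,
        frame: pd.DataFrame,
        patient_id: str = "",
        thresholds: GlycemicThresholds = DEFAULT_THRESHOLDS,
    ) -> "WindowedDataset":
        xcols = sorted(
            (c for c in frame.columns if c.startswith("x") and c[1:].isdigit()),
            key=lambda c: int(c[1:]),
        )
        X = frame[xcols].to_numpy(float)
        y = frame["target"].to_numpy(float)
        return cls(
            X=X,
            y=y,
            pseudolabel=assign_pseudolabels(y, thresholds),
            patient_id=patient_id,
            thresholds=thresholds,
        )


def build_windows(
    trace: CgmTrace,
    window_len: int = WINDOW_LEN,
    horizon_steps: int = HORIZON_STEPS,
    stride: int = 1,
    thresholds: GlycemicThresholds = DEFAULT_THRESHOLDS,
) -> WindowedDataset:
    """Emit every gap-free window of ``window_len`` features plus a target
    ``horizon_steps`` readings after the window end.

    A window starting at reading ``i`` spans ``window_len + horizon_steps``
    consecutive readings; it is emitted iff every one of the
    ``window_len + horizon_steps - 1`` consecutive steps inside that span is
    within the trace's spacing tolerance. Candidate starts advance by
    ``stride`` readings. An unproductive trace yields an empty dataset.
    """
    if window_len < 1 or horizon_steps < 1 or stride < 1:
        raise ValueError("window_len, horizon_steps and stride must be >= 1")
    span = window_len + horizon_steps
    n = len(trace)
    starts: list[int] = []
    if n >= span:
        ok = trace.contiguous_steps().astype(np.int64)
        # run_ok[i] == True iff all span-1 steps starting at i are contiguous
        csum = np.concatenate(([0], np.cumsum(ok)))
        candidate = np.arange(0, n - span + 1, stride)
        run_ok = (csum[candidate + span - 1] - csum[candidate]) == span - 1
        starts = candidate[run_ok].tolist()
    if not starts:
        return WindowedDataset(
            X=np.empty((0, window_len)),
            y=np.empty(0),
            pseudolabel=np.empty(0, dtype=object),
            patient_id=trace.patient_id,
            thresholds=thresholds,
            end_times=np.empty(0, dtype="datetime64[ns]"),
        )
    starts_arr = np.asarray(starts)
    idx = starts_arr[:, None] + np.arange(window_len)[None, :]
    X = trace.glucose[idx]
    y = trace.glucose[starts_arr + span - 1]
    end_times = trace.times.to_numpy()[starts_arr + window_len - 1]
    return WindowedDataset(
        X=X,
        y=y,
        pseudolabel=assign_pseudolabels(y, thresholds),
        patient_id=trace.patient_id,
        thresholds=thresholds,
        end_times=end_times,
    )


def expand_polynomial(features: np.ndarray) -> np.ndarray:
    """Degree-2 polynomial expansion of a feature vector or matrix.

    Output order is fixed: all linear terms in index order, then all squares,
    then pairwise products x_i·x_j for i < j in lexicographic order. No
    intercept column — the learner supplies its own. For d inputs the output
    has d + d(d+1)/2 columns (324 for the 24-reading window).
    """
    arr = np.asarray(features, dtype=float)
    single = arr.ndim == 1
    if single:
        arr = arr[None, :]
    d = arr.shape[1]
    if d < 1:
        raise ValueError("need at least one feature")
    i_idx, j_idx = np.triu_indices(d, k=1)
    out = np.concatenate([arr, arr**2, arr[:, i_idx] * arr[:, j_idx]], axis=1)
    return out[0] if single else out


def standardize(
    train_X: np.ndarray, apply_X: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Column-wise standardization fitted on training data only.

    Returns ``(standardized apply_X, means, sds)``. Columns with zero
    variance on the training data are centred but divided by 1.
    """
    train_X = np.asarray(train_X, dtype=float)
    apply_X = np.asarray(apply_X, dtype=float)
    if train_X.ndim != 2 or train_X.shape[0] == 0:
        raise ValueError("train_X must be a non-empty 2-D matrix")
    if apply_X.shape[-1] != train_X.shape[1]:
        raise ValueError(
            f"column mismatch: train has {train_X.shape[1]}, "
            f"apply has {apply_X.shape[-1]}"
        )
    means = train_X.mean(axis=0)
    sds = train_X.std(axis=0)
    sds = np.where(sds == 0.0, 1.0, sds)
    return (apply_X - means) / sds, means, sds
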