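"""Pseudolabel-based oversampling for imbalanced glucose regression.

CGM data is dominated by normoglycemic readings (roughly 3–5% hypo / ~60%
normal / ~35% hyper), so regressors trained on it are biased toward the
normal range. These oversamplers balance a windowed training set across the
three glycemic pseudolabel classes. Unlike classification oversampling, the
numeric regression target is synthesized *together with* the features: a
synthetic example is the same convex combination

    x_new = x_i + λ (x_j − x_i),   λ ∈ [0, 1]

applied to both the 24 feature readings and the target, with x_j drawn from
the seed example's k nearest same-class neighbours. Because each glycemic
class is an interval of mg/dl, the interpolated target provably keeps its
parents' pseudolabel. Three variants are provided:

- :func:`random_oversample` — duplicate minority rows at random;
- :func:`smote_regression` — interpolate, seed examples chosen uniformly;
- :func:`adasyn_regression` — interpolate, synthesis effort allocated in
  proportion to each minority example's neighbourhood "difficulty".

Oversampling is only ever applied to training data; the benchmark pipeline
enforces this.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.neighbors import NearestNeighbors

from .windowing import PSEUDOLABELS, WindowedDataset

DEFAULT_K = 5


class OversampleWarning(UserWarning):
    """A degenerate class (empty or singleton) limited oversampling."""


@dataclass(frozen=True)
class OversamplePlan:
    """How many examples each class needs to reach the majority count."""

    counts: dict[str, int]
    majority_class: str
    majority_count: int
    deficits: dict[str, int]
    empty_classes: tuple[str, ...]


@dataclass(frozen=True)
class SyntheticExample:
    """Provenance of one interpolated row: global indices of the two parents
    in the *original* dataset and the shared interpolation coefficient."""

    row: int
    seed_index: int
    neighbor_index: int
    lam: float
    pseudolabel: str


def make_plan(ds: WindowedDataset) -> OversamplePlan:
    """Per-class deficit relative to the majority class.

    Classes with zero members get deficit 0 and are flagged (nothing can be
    synthesized from nothing) with a warning.
    """
    if len(ds) == 0:
        raise ValueError("cannot plan oversampling of an empty dataset")
    counts = ds.class_counts()
    majority_class = max(PSEUDOLABELS, key=lambda c: counts[c])
    majority_count = counts[majority_class]
    deficits = {}
    empty = []
    for c in PSEUDOLABELS:
        if counts[c] == 0:
            deficits[c] = 0
            empty.append(c)
        else:
            deficits[c] = majority_count - counts[c]
    if empty:
        warnings.warn(
            f"classes with no examples cannot be oversampled: {empty}",
            OversampleWarning,
            stacklevel=2,
        )
    return OversamplePlan(
        counts=counts,
        majority_class=majority_class,
        majority_count=majority_count,
        deficits=deficits,
        empty_classes=tuple(empty),
    )


def _append(
    ds: WindowedDataset,
    new_X: np.ndarray,
    new_y: np.ndarray,
    new_labels: np.ndarray,
    provenance: list,
) -> WindowedDataset:
    X = np.vstack([ds.X, new_X]) if len(new_y) else ds.X.copy()
    y = np.concatenate([ds.y, new_y])
    labels = np.concatenate([ds.pseudolabel, new_labels])
    end_times = None
    if ds.end_times is not None:
        pad = np.full(len(new_y), np.datetime64("NaT"), dtype="datetime64[ns]")
        end_times = np.concatenate([ds.end_times, pad])
    return WindowedDataset(
        X=X,
        y=y,
        pseudolabel=labels,
        patient_id=ds.patient_id,
        thresholds=ds.thresholds,
        end_times=end_times,
        provenance=provenance,
    )


def random_oversample(ds: WindowedDataset, seed: int) -> WindowedDataset:
    """Balance classes by duplicating minority rows uniformly at random
    (with replacement) until every non-empty class matches the majority."""
    plan = make_plan(ds)
    rng = np.random.default_rng(seed)
    pieces_X, pieces_y, pieces_l = [], [], []
    for c in PSEUDOLABELS:
        deficit = plan.deficits[c]
        if deficit <= 0:
            continue
        idx = ds.class_indices(c)
        picks = rng.choice(idx, size=deficit, replace=True)
        pieces_X.append(ds.X[picks])
        pieces_y.append(ds.y[picks])
        pieces_l.append(ds.pseudolabel[picks])
    if not pieces_X:
        return _append(ds, np.empty((0, ds.n_features)), np.empty(0),
                       np.empty(0, dtype=object), [])
    return _append(
        ds,
        np.vstack(pieces_X),
        np.concatenate(pieces_y),
        np.concatenate(pieces_l),
        [],
    )


def _same_class_neighbors(X_class: np.ndarray, k: int) -> np.ndarray:
    """Indices (within the class) of each member's k nearest same-class
    neighbours, self excluded; Euclidean distance on raw mg/dl features."""
    n = len(X_class)
    k_eff = min(k, n - 1)
    nn = NearestNeighbors(n_neighbors=k_eff + 1).fit(X_class)
    neigh = nn.kneighbors(X_class, return_distance=False)
    # drop self (always present since distance 0 ranks first; ties with an
    # exact duplicate row are harmless — any same-class duplicate is as good)
    out = np.empty((n, k_eff), dtype=np.int64)
    for i in range(n):
        row = neigh[i]
        row = row[row != i][:k_eff]
        if len(row) < k_eff:  # exact-duplicate tie ate the self slot
            extras = [j for j in neigh[i] if j != i]
            row = np.asarray(extras[:k_eff])
        out[i] = row
    return out


def _synthesize(
    ds: WindowedDataset,
    label: str,
    seed_rows: np.ndarray,
    k: int,
    rng: np.random.Generator,
    provenance: list,
    out_X: list,
    out_y: list,
    out_l: list,
    row_offset: int,
) -> int:
    """Interpolate one synthetic row per entry of ``seed_rows`` (global row
    indices). Returns the updated row offset."""
    idx = ds.class_indices(label)
    local = {g: i for i, g in enumerate(idx)}
    neighbors = _same_class_neighbors(ds.X[idx], k)
    for g in seed_rows:
        li = local[g]
        j_local = int(rng.choice(neighbors[li]))
        j = int(idx[j_local])
        lam = float(rng.uniform(0.0, 1.0))
        out_X.append(ds.X[g] + lam * (ds.X[j] - ds.X[g]))
        out_y.append(ds.y[g] + lam * (ds.y[j] - ds.y[g]))
        out_l.append(label)
        provenance.append(
            SyntheticExample(
                row=row_offset,
                seed_index=int(g),
                neighbor_index=j,
                lam=lam,
                pseudolabel=label,
            )
        )
        row_offset += 1
    return row_offset


def _fallback_duplicate(
    ds: WindowedDataset,
    label: str,
    deficit: int,
    rng: np.random.Generator,
    out_X: list,
    out_y: list,
    out_l: list,
    row_offset: int,
) -> int:
    warnings.warn(
        f"class {label!r} has a single member; falling back to random "
        "duplication (interpolation needs two parents)",
        OversampleWarning,
        stacklevel=3,
    )
    idx = ds.class_indices(label)
    picks = rng.choice(idx, size=deficit, replace=True)
    for g in picks:
        out_X.append(ds.X[g].copy())
        out_y.append(ds.y[g])
        out_l.append(label)
        row_offset += 1
    return row_offset


def smote_regression(
    ds: WindowedDataset, k: int = DEFAULT_K, seed: int = 0
) -> WindowedDataset:
    """SMOTE adapted to regression via pseudolabels and target synthesis.

    For every deficit slot of a minority class: draw a seed example uniformly
    from the class, draw x_j uniformly from its k nearest same-class
    neighbours, draw λ ~ U[0,1], and emit the shared convex combination of
    features and target. Classes with one member fall back to duplication.
    """
    plan = make_plan(ds)
    rng = np.random.default_rng(seed)
    out_X: list = []
    out_y: list = []
    out_l: list = []
    provenance: list = []
    offset = len(ds)
    for c in PSEUDOLABELS:
        deficit = plan.deficits[c]
        if deficit <= 0:
            continue
        idx = ds.class_indices(c)
        if len(idx) < 2:
            offset = _fallback_duplicate(
                ds, c, deficit, rng, out_X, out_y, out_l, offset
            )
            continue
        seeds = rng.choice(idx, size=deficit, replace=True)
        offset = _synthesize(
            ds, c, seeds, k, rng, provenance, out_X, out_y, out_l, offset
        )
    return _append(
        ds,
        np.asarray(out_X).reshape(-1, ds.n_features),
        np.asarray(out_y, dtype=float),
        np.asarray(out_l, dtype=object),
        provenance,
    )


def allocate_largest_remainder(weights: np.ndarray, total: int) -> np.ndarray:
    """Integer allocation of ``total`` proportional to ``weights`` using
    largest-remainder rounding; uniform when all weights are zero.

    Allocations sum exactly to ``total``; remainder ties are broken by lowest
    index for determinism.
    """
    weights = np.asarray(weights, dtype=float)
    if total < 0:
        raise ValueError("total must be >= 0")
    if len(weights) == 0:
        raise ValueError("need at least one weight")
    if np.any(weights < 0):
        raise ValueError("weights must be non-negative")
    s = weights.sum()
    shares = (
        np.full(len(weights), total / len(weights))
        if s == 0
        else total * weights / s
    )
    base = np.floor(shares).astype(np.int64)
    leftover = int(total - base.sum())
    if leftover:
        remainders = shares - base
        # stable sort descending on remainder -> ties to lowest index
        order = np.argsort(-remainders, kind="stable")
        base[order[:leftover]] += 1
    return base


def adasyn_difficulty(
    ds: WindowedDataset, label: str, k: int = DEFAULT_K
) -> np.ndarray:
    """Difficulty r_i of each member of ``label``: the fraction of its k
    nearest neighbours in the FULL dataset carrying a different pseudolabel."""
    idx = ds.class_indices(label)
    k_eff = min(k, len(ds) - 1)
    if k_eff < 1:
        return np.zeros(len(idx))
    nn = NearestNeighbors(n_neighbors=k_eff + 1).fit(ds.X)
    neigh = nn.kneighbors(ds.X[idx], return_distance=False)
    r = np.empty(len(idx))
    for i, g in enumerate(idx):
        row = [j for j in neigh[i] if j != g][:k_eff]
        if len(row) < k_eff:
            row = [j for j in neigh[i] if j != g]
        labels = ds.pseudolabel[np.asarray(row, dtype=int)]
        r[i] = np.mean(labels != label)
    return r


def adasyn_regression(
    ds: WindowedDataset, k: int = DEFAULT_K, seed: int = 0
) -> WindowedDataset:
    """ADASYN adapted to regression: like :func:`smote_regression` but the
    number of synthetic rows seeded from each minority example is
    proportional to its difficulty (largest-remainder rounding, uniform
    fallback when every difficulty is zero)."""
    plan = make_plan(ds)
    rng = np.random.default_rng(seed)
    out_X: list = []
    out_y: list = []
    out_l: list = []
    provenance: list = []
    offset = len(ds)
    for c in PSEUDOLABELS:
        deficit = plan.deficits[c]
        if deficit <= 0:
            continue
        idx = ds.class_indices(c)
        if len(idx) < 2:
            offset = _fallback_duplicate(
                ds, c, deficit, rng, out_X, out_y, out_l, offset
            )
            continue
        r = adasyn_difficulty(ds, c, k)
        alloc = allocate_largest_remainder(r, deficit)
        seeds = np.repeat(idx, alloc)
        offset = _synthesize(
            ds, c, seeds, k, rng, provenance, out_X, out_y, out_l, offset
        )
    return _append(
        ds,
        np.asarray(out_X).reshape(-1, ds.n_features),
        np.asarray(out_y, dtype=float),
        np.asarray(out_l, dtype=object),
        provenance,
    )


OVERSAMPLERS = {
    "none": None,
    "random": random_oversample,
    "smote": smote_regression,
    "adasyn": adasyn_regression,
}


def apply_oversampler(
    ds: WindowedDataset, method: str, seed: int, k: int = DEFAULT_K
) -> WindowedDataset:
    """Dispatch by name; ``"none"`` returns the dataset unchanged."""
    if method not in OVERSAMPLERS:
        raise ValueError(f"unknown oversampler {method!r}; choose from {sorted(OVERSAMPLERS)}")
    if method == "none":
        return ds
    if method == "random":
        return random_oversample(ds, seed=seed)
    fn = OVERSAMPLERS[method]
    return fn(ds, k=k, seed=seed)
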