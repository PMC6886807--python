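"""Model × oversampler × patient benchmark grid and its statistics.

One *experiment* is the full pipeline on one patient: window the training
trace, balance it with one oversampler (training data only — test windows
are never touched), fit one registry model, predict the test windows, and
score with range-conditioned MARD and Clarke EGA. The *grid* runs every
(model, oversampler, patient) cell — 10 × 4 × n patients — into a tidy
result table; combinations are then ranked by patient-averaged metric and
compared with a Friedman omnibus test on within-patient ranks, a Nemenyi
post hoc, and paired t-tests.

Undefined subrange metrics (e.g. a patient whose test weeks contain no
hypoglycemia) are stored as NaN and excluded pairwise from means, ranks and
tests, with the remaining count reported — never treated as zero.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io import GLUCOSE_MAX, GLUCOSE_MIN, PatientDataset
from .metrics import EGA_ZONES, EgaReport, MardReport, ega_report, mard_by_range
from .models import ModelSpec, registry, train
from .oversample import OVERSAMPLERS, apply_oversampler
from .windowing import DEFAULT_THRESHOLDS, GlycemicThresholds, build_windows

OVERSAMPLER_NAMES = ("none", "random", "smote", "adasyn")

#: Ranking direction: True = lower is better. Zone A is the benign zone, so
#: more of it is better; everything else (errors) is minimized. Zones C and E
#: are reported but considered unreliable for model selection (a constant
#: predictor scores 0 there).
LOWER_IS_BETTER = {
    "mard_all": True,
    "mard_hypo": True,
    "mard_norm": True,
    "mard_hyper": True,
    "pct_A": False,
    "pct_B": True,
    "pct_C": True,
    "pct_D": True,
    "pct_E": True,
}

METRIC_COLUMNS = tuple(LOWER_IS_BETTER)


class DegenerateRanksError(ValueError):
    """All combinations are tied in every block; the test is undefined."""


def cell_seed(master_seed: int, patient_id: str, model_name: str, os_name: str) -> int:
    """Deterministic per-cell sub-seed derived from the cell's identity (not
    its grid position), so any cell can be re-run in isolation and results
    do not depend on iteration order; always below 2**31."""
    import hashlib

    digest = hashlib.sha256(
        f"{master_seed}|{patient_id}|{model_name}|{os_name}".encode()
    ).digest()
    return int.from_bytes(digest[:4], "big") % 2**31


def run_experiment(
    data: PatientDataset,
    spec: ModelSpec,
    oversampler: str = "none",
    seed: int = 0,
    thresholds: GlycemicThresholds = DEFAULT_THRESHOLDS,
) -> tuple[MardReport, EgaReport]:
    """Train/test pipeline for one grid cell."""
    if oversampler not in OVERSAMPLERS:
        raise ValueError(f"unknown oversampler {oversampler!r}")
    try:
        train_ds = build_windows(data.train, thresholds=thresholds)
        test_ds = build_windows(data.test, thresholds=thresholds)
        if len(train_ds) == 0 or len(test_ds) == 0:
            raise ValueError("windowing produced an empty train or test set")
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # degenerate-class oversample warnings
            train_ds = apply_oversampler(train_ds, oversampler, seed=seed)
        model = train(spec.with_seed(seed), train_ds.X, train_ds.y)
        # clamp forecasts to the sensor's reporting range, as a deployed
        # display would; keeps relative-error metrics well defined
        predictions = np.clip(model.predict(test_ds.X), GLUCOSE_MIN, GLUCOSE_MAX)
    except Exception as exc:
        raise RuntimeError(
            f"experiment failed (patient={data.patient_id!r}, "
            f"model={spec.name!r}, oversampler={oversampler!r}): {exc}"
        ) from exc
    return (
        mard_by_range(predictions, test_ds.y, thresholds),
        ega_report(predictions, test_ds.y),
    )


def run_grid(
    patients,
    seed: int = 0,
    model_specs: list[ModelSpec] | None = None,
    oversamplers: tuple[str, ...] = OVERSAMPLER_NAMES,
    profile: str = "fast",
    thresholds: GlycemicThresholds = DEFAULT_THRESHOLDS,
) -> pd.DataFrame:
    """Run every (model, oversampler, patient) cell into a tidy table.

    Returns a DataFrame with one row per cell, columns ``model``,
    ``oversampler``, ``patient``, ``combination``, the metric columns of
    :data:`METRIC_COLUMNS`, subrange counts, and an ``error`` column (empty
    string normally; per-cell failures are recorded there and the grid
    continues).
    """
    patients = list(patients)
    if not patients:
        raise ValueError("need at least one patient")
    if model_specs is None:
        model_specs = registry(profile=profile)
    rows = []
    for data in patients:
        for spec in model_specs:
            for osname in oversamplers:
                sub = cell_seed(seed, data.patient_id, spec.name, osname)
                row = {
                    "model": spec.name,
                    "oversampler": osname,
                    "patient": data.patient_id,
                    "combination": combo_name(spec.name, osname),
                    "error": "",
                }
                try:
                    mard_rep, ega_rep = run_experiment(
                        data, spec, osname, seed=sub, thresholds=thresholds
                    )
                except RuntimeError as exc:
                    row["error"] = str(exc)
                    for col in METRIC_COLUMNS:
                        row[col] = np.nan
                else:
                    d = mard_rep.as_dict()
                    for key in ("mard_all", "mard_hypo", "mard_norm", "mard_hyper"):
                        row[key] = np.nan if d[key] is None else d[key]
                    for key in ("n_all", "n_hypo", "n_norm", "n_hyper"):
                        row[key] = d[key]
                    for z in EGA_ZONES:
                        row[f"pct_{z}"] = ega_rep.percentages[z]
                rows.append(row)
    return pd.DataFrame(rows)


def combo_name(model: str, oversampler: str) -> str:
    return model if oversampler == "none" else f"{model}+{oversampler}"


def rank_combinations(
    table: pd.DataFrame, metric: str, top_n: int = 5
) -> pd.DataFrame:
    """Combinations sorted by patient-averaged metric.

    NaN (undefined) cells are excluded from each combination's mean; the
    count of contributing patients is reported. Ties keep a stable
    alphabetical order by combination name.
    """
    _check_metric(metric)
    grouped = table.groupby("combination")[metric]
    means = grouped.mean()
    counts = grouped.count()
    out = pd.DataFrame(
        {"combination": means.index, "mean": means.to_numpy(), "n_patients": counts.to_numpy()}
    )
    out = out[out["n_patients"] > 0]
    ascending = LOWER_IS_BETTER[metric]
    out = out.sort_values(
        ["mean", "combination"], ascending=[ascending, True], kind="stable"
    ).reset_index(drop=True)
    return out.head(top_n) if top_n else out


def rank_matrix(table: pd.DataFrame, metric: str) -> pd.DataFrame:
    """Within-patient ranks of every combination on one metric.

    Rows are combinations, columns patients; rank 1 is best (direction-aware),
    ties get average ranks, NaN metric values stay NaN.
    """
    _check_metric(metric)
    wide = table.pivot_table(
        index="combination", columns="patient", values=metric, aggfunc="first"
    )
    sign = 1.0 if LOWER_IS_BETTER[metric] else -1.0
    ranked = wide.apply(
        lambda col: pd.Series(
            stats.rankdata(sign * col.to_numpy(), method="average", nan_policy="omit"),
            index=col.index,
        ),
        axis=0,
    )
    return ranked


def friedman_test(ranks: pd.DataFrame | np.ndarray) -> tuple[float, float]:
    """Friedman omnibus test from a (combinations × blocks) rank matrix.

    Tie-corrected chi-square statistic with k−1 degrees of freedom. Columns
    containing NaN are dropped (a block must rank every combination).
    Returns ``(statistic, p)``; a fully tied matrix is degenerate and
    reported as (0, 1) with a warning.
    """
    R = np.asarray(ranks, dtype=float)
    if R.ndim != 2:
        raise ValueError("rank matrix must be 2-D")
    R = R[:, ~np.any(np.isnan(R), axis=0)]
    k, n = R.shape
    if k < 2 or n < 2:
        raise ValueError("need >= 2 combinations and >= 2 complete blocks")
    # tie correction per block: sum of (t^3 - t) over tied groups
    ties = 0.0
    for j in range(n):
        _, t = np.unique(R[:, j], return_counts=True)
        ties += float(np.sum(t**3 - t))
    c = 1.0 - ties / (n * (k**3 - k))
    if c <= 0.0:
        warnings.warn(
            "all combinations tied in every block; Friedman statistic undefined",
            UserWarning,
            stacklevel=2,
        )
        return 0.0, 1.0
    row_sums = R.sum(axis=1)
    chisq = (12.0 / (n * k * (k + 1)) * float(np.sum(row_sums**2)) - 3.0 * n * (k + 1)) / c
    chisq = max(chisq, 0.0)
    p = float(stats.chi2.sf(chisq, k - 1))
    return float(chisq), p


def nemenyi_posthoc(ranks: pd.DataFrame | np.ndarray) -> pd.DataFrame:
    """Pairwise Nemenyi p-values from a rank matrix.

    Based on the studentized-range distribution of mean-rank differences:
    q_ij = |R̄_i − R̄_j| / sqrt(k(k+1)/(6n)), p = P(Q_{k,∞} ≥ q·√2).
    Symmetric, diagonal 1.
    """
    labels = None
    if isinstance(ranks, pd.DataFrame):
        labels = list(ranks.index)
    R = np.asarray(ranks, dtype=float)
    R = R[:, ~np.any(np.isnan(R), axis=0)]
    k, n = R.shape
    if k < 2 or n < 2:
        raise ValueError("need >= 2 combinations and >= 2 complete blocks")
    mean_ranks = R.mean(axis=1)
    scale = np.sqrt(k * (k + 1) / (6.0 * n))
    diff = np.abs(mean_ranks[:, None] - mean_ranks[None, :])
    q = diff / scale * np.sqrt(2.0)
    p = stats.studentized_range.sf(q, k, np.inf)
    p = np.clip(np.where(np.isnan(p), 1.0, p), 0.0, 1.0)
    np.fill_diagonal(p, 1.0)
    p = (p + p.T) / 2.0  # enforce exact symmetry
    if labels is None:
        labels = list(range(k))
    return pd.DataFrame(p, index=labels, columns=labels)


def paired_t_test(
    table: pd.DataFrame, combo_a: str, combo_b: str, metric: str
) -> tuple[float, int]:
    """Two-sided paired t-test between two combinations on one metric.

    Pairs patients; drops patients where either value is undefined. Returns
    ``(p, n_pairs)``. Zero-variance differences are degenerate and reported
    as p = 1 with a warning.
    """
    _check_metric(metric)
    wide = table.pivot_table(
        index="patient", columns="combination", values=metric, aggfunc="first"
    )
    for combo in (combo_a, combo_b):
        if combo not in wide.columns:
            raise ValueError(f"combination {combo!r} not in table")
    paired = wide[[combo_a, combo_b]].dropna()
    n = len(paired)
    if n < 2:
        raise ValueError(f"fewer than 2 complete pairs ({n})")
    diffs = paired[combo_a].to_numpy() - paired[combo_b].to_numpy()
    if np.allclose(diffs, diffs[0]):
        warnings.warn(
            "zero-variance paired differences; t-test degenerate, p = 1",
            UserWarning,
            stacklevel=2,
        )
        return 1.0, n
    result = stats.ttest_rel(paired[combo_a], paired[combo_b])
    return float(result.pvalue), n


@dataclass(frozen=True)
class StatReport:
    """Friedman p per metric plus the Nemenyi matrix for one chosen metric."""

    friedman: dict[str, tuple[float, float]]
    nemenyi: pd.DataFrame | None


def stat_report(
    table: pd.DataFrame,
    metrics: tuple[str, ...] = (
        "mard_all",
        "mard_hypo",
        "mard_norm",
        "mard_hyper",
        "pct_A",
        "pct_B",
        "pct_D",
    ),
    nemenyi_metric: str | None = "mard_all",
) -> StatReport:
    """Friedman tests across all combinations for each metric (zones C/E are
    omitted from the default list: unreliable for selection)."""
    friedman = {}
    for metric in metrics:
        ranks = rank_matrix(table, metric)
        try:
            friedman[metric] = friedman_test(ranks)
        except ValueError:
            # metric undefined for too many patients (e.g. no test
            # hypoglycemia anywhere): report as missing, not a crash
            friedman[metric] = (float("nan"), float("nan"))
    nemenyi = (
        nemenyi_posthoc(rank_matrix(table, nemenyi_metric))
        if nemenyi_metric
        else None
    )
    return StatReport(friedman=friedman, nemenyi=nemenyi)


def _check_metric(metric: str) -> None:
    if metric not in LOWER_IS_BETTER:
        raise ValueError(
            f"unknown metric {metric!r}; choose from {sorted(LOWER_IS_BETTER)}"
        )
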