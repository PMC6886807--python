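"""Glycemic-aware predictive-performance metrics.

MARD (mean absolute relative difference) is the field's standard relative
error:  MARD = (100/N) Σ |ŷ − y| / y, with the ground truth y in the
denominator. Because an overall MARD hides how a model behaves in the
rarely-visited but clinically critical ranges, the range-conditioned variant
MARD_C restricts the average to prediction pairs whose ground truth satisfies
a criterion C — here the three glycemic ranges (<70, 70–180, >180 mg/dl).
The weighted decomposition  N·MARD_all = Σ_C N_C·MARD_C  holds exactly.

Clarke Error Grid Analysis (EGA) instead scores each (actual, predicted)
pair by clinical consequence, zones A (benign) through E (dangerous). The
canonical grid inequalities are evaluated in precedence order A, E, C, D,
else B, so every pair lands in exactly one zone.

Empty subranges are reported as undefined (None / NaN), never as 0 — a
constant predictor must not look perfect on a range it never visits.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .windowing import DEFAULT_THRESHOLDS, GlycemicThresholds
from .io import GLUCOSE_MAX, GLUCOSE_MIN

EGA_ZONES = ("A", "B", "C", "D", "E")


class EmptyInputError(ValueError):
    """A metric was requested on zero prediction pairs."""


def _validate_pairs(predicted, actual) -> tuple[np.ndarray, np.ndarray]:
    predicted = np.asarray(predicted, dtype=float).ravel()
    actual = np.asarray(actual, dtype=float).ravel()
    if predicted.shape != actual.shape:
        raise ValueError("predicted and actual must have equal length")
    if predicted.size == 0:
        raise EmptyInputError("no prediction pairs")
    if not np.all(np.isfinite(predicted)) or np.any(predicted <= 0):
        raise ValueError("predictions must be finite and > 0")
    if np.any(actual < GLUCOSE_MIN) or np.any(actual > GLUCOSE_MAX):
        raise ValueError(
            f"actual values must lie in [{GLUCOSE_MIN:g}, {GLUCOSE_MAX:g}]"
        )
    return predicted, actual


def mard(predicted, actual) -> float:
    """Mean absolute relative difference, in percent."""
    predicted, actual = _validate_pairs(predicted, actual)
    return float(100.0 * np.mean(np.abs(predicted - actual) / actual))


@dataclass(frozen=True)
class MardReport:
    """Overall and range-conditioned MARD with subrange counts.

    A subrange with no pairs has MARD ``None`` (undefined), never 0.
    """

    mard_all: float
    mard_hypo: float | None
    mard_norm: float | None
    mard_hyper: float | None
    n_all: int
    n_hypo: int
    n_norm: int
    n_hyper: int

    def as_dict(self) -> dict:
        return {
            "mard_all": self.mard_all,
            "mard_hypo": self.mard_hypo,
            "mard_norm": self.mard_norm,
            "mard_hyper": self.mard_hyper,
            "n_all": self.n_all,
            "n_hypo": self.n_hypo,
            "n_norm": self.n_norm,
            "n_hyper": self.n_hyper,
        }


def mard_by_range(
    predicted, actual, thresholds: GlycemicThresholds = DEFAULT_THRESHOLDS
) -> MardReport:
    """MARD overall and conditioned on the ground truth's glycemic range.

    Ranges partition on the ACTUAL value: hypo strictly below ``hypo``,
    normal inclusive between the thresholds, hyper strictly above ``hyper``.
    """
    predicted, actual = _validate_pairs(predicted, actual)
    rel = 100.0 * np.abs(predicted - actual) / actual
    masks = {
        "hypo": actual < thresholds.hypo,
        "norm": (actual >= thresholds.hypo) & (actual <= thresholds.hyper),
        "hyper": actual > thresholds.hyper,
    }
    sub = {}
    counts = {}
    for name, mask in masks.items():
        counts[name] = int(mask.sum())
        sub[name] = float(rel[mask].mean()) if counts[name] else None
    return MardReport(
        mard_all=float(rel.mean()),
        mard_hypo=sub["hypo"],
        mard_norm=sub["norm"],
        mard_hyper=sub["hyper"],
        n_all=int(rel.size),
        n_hypo=counts["hypo"],
        n_norm=counts["norm"],
        n_hyper=counts["hyper"],
    )


def ega_zone(actual: float, predicted: float) -> str:
    """Clarke zone of one (actual, predicted) pair.

    Canonical grid inequalities, precedence A, E, C, D, else B:

    - A: both below 70, or |pred − actual| ≤ 20% of actual
    - E: actual ≤ 70 & pred ≥ 180, or actual ≥ 180 & pred ≤ 70
    - C: 70 ≤ actual ≤ 290 & pred ≥ actual + 110,
         or 130 ≤ actual ≤ 180 & pred ≤ (7/5)·actual − 182
    - D: actual ≥ 240 & 70 ≤ pred ≤ 180,
         or actual ≤ 175/3 & 70 ≤ pred ≤ 180,
         or 175/3 ≤ actual ≤ 70 & pred ≥ (6/5)·actual
    """
    return str(ega_zones(np.asarray([actual]), np.asarray([predicted]))[0])


def ega_zones(actual, predicted) -> np.ndarray:
    """Vectorized Clarke zone assignment (array of 'A'..'E')."""
    a = np.asarray(actual, dtype=float).ravel()
    p = np.asarray(predicted, dtype=float).ravel()
    if a.shape != p.shape:
        raise ValueError("actual and predicted must have equal length")
    if np.any(a <= 0) or np.any(p <= 0):
        raise ValueError("EGA inputs must be positive")
    zone = np.full(a.shape, "B", dtype="<U1")
    d_mask = (
        ((a >= 240.0) & (p >= 70.0) & (p <= 180.0))
        | ((a <= 175.0 / 3.0) & (p >= 70.0) & (p <= 180.0))
        | ((a >= 175.0 / 3.0) & (a <= 70.0) & (p >= 1.2 * a))
    )
    zone[d_mask] = "D"
    c_mask = ((a >= 70.0) & (a <= 290.0) & (p >= a + 110.0)) | (
        (a >= 130.0) & (a <= 180.0) & (p <= 1.4 * a - 182.0)
    )
    zone[c_mask] = "C"
    e_mask = ((a <= 70.0) & (p >= 180.0)) | ((a >= 180.0) & (p <= 70.0))
    zone[e_mask] = "E"
    a_mask = ((a < 70.0) & (p < 70.0)) | (np.abs(p - a) <= 0.2 * a)
    zone[a_mask] = "A"
    return zone


@dataclass(frozen=True)
class EgaReport:
    """Per-zone counts and percentages over N prediction pairs."""

    counts: dict[str, int]
    percentages: dict[str, float]
    n: int

    def as_dict(self) -> dict:
        out = {f"pct_{z}": self.percentages[z] for z in EGA_ZONES}
        out.update({f"n_{z}": self.counts[z] for z in EGA_ZONES})
        out["n"] = self.n
        return out


def ega_report(predicted, actual) -> EgaReport:
    """Zone frequency table of all prediction pairs."""
    predicted, actual = _validate_pairs(predicted, actual)
    zones = ega_zones(actual, predicted)
    counts = {z: int(np.sum(zones == z)) for z in EGA_ZONES}
    n = int(zones.size)
    percentages = {z: 100.0 * counts[z] / n for z in EGA_ZONES}
    return EgaReport(counts=counts, percentages=percentages, n=n)
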