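"""Seeded synthetic CGM generator.

Emulates the statistical structure the forecasting pipeline assumes about
real sensor data: 5-minute sampling, the 40–400 mg/dl reporting range, trace
gaps of widely varying duration, and heavy normoglycemic imbalance (a few
percent of readings hypoglycemic, roughly a third hyperglycemic).

Glucose follows a discrete mean-reverting process driven by a latent
"drive" curve: a normoglycemic baseline plus gamma-shaped meal excursions at
Poisson event times, minus occasional post-meal overcorrection dips that
push the trace below 70 mg/dl, plus Gaussian noise:

    g_{t+1} = g_t + a · (drive(t) − g_t) · Δt + ε_t,   ε_t ~ N(0, σ²Δt)

clipped to the sensor range. Gaps delete contiguous readings (log-uniform
durations); nothing is imputed. This is deliberately a statistical stand-in,
not a physiological model — no insulin kinetics, no sensor error model.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import (
    GLUCOSE_MAX,
    GLUCOSE_MIN,
    CgmTrace,
    PatientDataset,
    split_chronological,
)
from .windowing import DEFAULT_THRESHOLDS, GlycemicThresholds

_EPOCH = pd.Timestamp("2021-01-04 00:00:00")
_STEPS_PER_DAY = 288  # 5-min cadence


@dataclass(frozen=True)
class SimConfig:
    """Generator parameters; defaults are calibrated once to the benchmark
    imbalance (~3–5% hypo, ~35% hyper) and frozen.

    Units: rates are per minute or per day as named; amplitudes/depths are
    mg/dl; ``noise_sd`` is mg/dl per √min; durations are minutes.
    """

    days: int = 56
    interval_minutes: float = 5.0
    baseline_mean: float = 140.0
    reversion_rate: float = 0.06
    noise_sd: float = 1.3
    meal_rate: float = 4.0
    meal_amplitude: tuple[float, float] = (30.0, 120.0)
    overcorrection_prob: float = 0.40
    overcorrection_depth: tuple[float, float] = (105.0, 135.0)
    gap_rate: float = 1.0
    gap_duration: tuple[float, float] = (15.0, 480.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.days < 1:
            raise ValueError("days must be >= 1")
        for name in ("reversion_rate", "noise_sd", "meal_rate", "gap_rate"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 70.0 < self.baseline_mean < 180.0:
            raise ValueError("baseline_mean must be normoglycemic (70, 180)")
        if not 0.0 <= self.overcorrection_prob <= 1.0:
            raise ValueError("overcorrection_prob must be a probability")


@dataclass(frozen=True)
class SimCohort:
    """Independently simulated patients sharing one configuration."""

    patients: tuple[PatientDataset, ...]
    config: SimConfig


def _gamma_kernel(minutes: np.ndarray, peak_min: float, shape: float) -> np.ndarray:
    """Unit-peak gamma-shaped response: 0 at onset, 1 at ``peak_min``."""
    tau = np.clip(minutes / peak_min, 0.0, None)
    return tau**shape * np.exp(shape * (1.0 - tau))


def _drive_curve(config: SimConfig, n_steps: int, rng: np.random.Generator) -> np.ndarray:
    dt = config.interval_minutes
    t_min = np.arange(n_steps) * dt
    drive = np.full(n_steps, config.baseline_mean)

    n_meals = rng.poisson(config.meal_rate * config.days)
    meal_times = np.sort(rng.uniform(0.0, n_steps * dt, size=n_meals))
    lo, hi = config.meal_amplitude
    amplitudes = rng.uniform(lo, hi, size=n_meals)
    overcorrect = rng.random(n_meals) < config.overcorrection_prob
    d_lo, d_hi = config.overcorrection_depth
    depths = rng.uniform(d_lo, d_hi, size=n_meals)
    delays = rng.uniform(120.0, 240.0, size=n_meals)

    for i in range(n_meals):
        start = meal_times[i]
        # meal excursion: peak after ~75 min, effectively over by ~9 h
        sl = slice(
            int(np.searchsorted(t_min, start)),
            int(np.searchsorted(t_min, start + 540.0)),
        )
        drive[sl] += amplitudes[i] * _gamma_kernel(t_min[sl] - start, 75.0, 1.2)
        if overcorrect[i]:
            # delayed overcorrection dip (insulin overshoot), narrower kernel
            dip_start = start + delays[i]
            sl = slice(
                int(np.searchsorted(t_min, dip_start)),
                int(np.searchsorted(t_min, dip_start + 300.0)),
            )
            drive[sl] -= depths[i] * _gamma_kernel(t_min[sl] - dip_start, 55.0, 2.0)
    return drive


def simulate_trace(
    config: SimConfig = SimConfig(),
    seed: int | None = None,
    patient_id: str = "sim",
) -> CgmTrace:
    """One patient's gap-bearing CGM trace under ``config``."""
    if seed is None:
        seed = config.seed
    rng = np.random.default_rng(seed)
    n_steps = config.days * _STEPS_PER_DAY
    dt = config.interval_minutes
    drive = _drive_curve(config, n_steps, rng)

    g = np.empty(n_steps)
    g[0] = config.baseline_mean
    step_noise = rng.normal(0.0, config.noise_sd * np.sqrt(dt), size=n_steps)
    a = config.reversion_rate
    for t in range(n_steps - 1):
        g[t + 1] = g[t] + a * (drive[t] - g[t]) * dt + step_noise[t]
        if g[t + 1] < GLUCOSE_MIN:
            g[t + 1] = GLUCOSE_MIN
        elif g[t + 1] > GLUCOSE_MAX:
            g[t + 1] = GLUCOSE_MAX
    glucose = np.clip(np.round(g, 1), GLUCOSE_MIN, GLUCOSE_MAX)

    times = _EPOCH + pd.to_timedelta(np.arange(n_steps) * dt, unit="m")
    keep = np.ones(n_steps, dtype=bool)
    n_gaps = rng.poisson(config.gap_rate * config.days)
    if n_gaps:
        lo, hi = config.gap_duration
        starts = rng.uniform(0.0, n_steps * dt, size=n_gaps)
        durations = 10.0 ** rng.uniform(np.log10(lo), np.log10(hi), size=n_gaps)
        t_min = np.arange(n_steps) * dt
        for s, d in zip(starts, durations):
            keep &= ~((t_min >= s) & (t_min < s + d))
    return CgmTrace(
        patient_id=patient_id,
        times=pd.DatetimeIndex(times[keep]),
        glucose=glucose[keep],
    )


def simulate_patient(
    config: SimConfig = SimConfig(),
    seed: int | None = None,
    patient_id: str = "sim",
    test_fraction: float = 0.25,
) -> PatientDataset:
    """Simulate one patient and split 75/25 chronologically."""
    trace = simulate_trace(config, seed=seed, patient_id=patient_id)
    return split_chronological(trace, test_fraction=test_fraction)


def simulate_cohort(
    n: int = 6, config: SimConfig = SimConfig(), seed: int | None = None
) -> SimCohort:
    """``n`` independent patients from per-patient sub-seeds of one master."""
    if n < 1:
        raise ValueError("n must be >= 1")
    if seed is None:
        seed = config.seed
    children = np.random.SeedSequence(seed).spawn(n)
    patients = tuple(
        simulate_patient(
            config,
            seed=int(child.generate_state(1)[0] % 2**31),
            patient_id=f"sim-{i + 1:03d}",
        )
        for i, child in enumerate(children)
    )
    return SimCohort(patients=patients, config=config)


def range_occupancy(
    trace: CgmTrace, thresholds: GlycemicThresholds = DEFAULT_THRESHOLDS
) -> tuple[float, float, float]:
    """Fractions of readings in the (hypo, normal, hyper) ranges; sums to 1."""
    if len(trace) == 0:
        raise ValueError("empty trace")
    g = trace.glucose
    n = len(g)
    hypo = float(np.sum(g < thresholds.hypo)) / n
    hyper = float(np.sum(g > thresholds.hyper)) / n
    return hypo, 1.0 - hypo - hyper, hyper
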