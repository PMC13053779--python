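"""Automated radiation modulator (ARM): dwell-time dose scheduling.

The ARM translates a 384-pillar plate under a fixed, tungsten-shielded
radiation slit.  Dose delivered to a well is (beam rate) x (dwell time in
the slit); different column groups of the plate receive different doses by
resting in the slit for different times.  This module fits the
seconds-per-gray calibration, builds dwell schedules for target dose
ladders, simulates delivery (with optional multiplicative noise and shield
leakage) onto a 16 x 24 dose map, and summarizes delivery quality
(mean rate, CV, linearity).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats as _stats

from .plate import N_COLS, N_ROWS

#: Dose (Gy) -> dwell (s) pairs of the device calibration run.
DEFAULT_CALIBRATION_POINTS: tuple[tuple[float, float], ...] = (
    (1.0, 51.59),
    (2.0, 102.98),
    (4.0, 205.96),
    (8.0, 411.92),
)

#: Fraction of the open-field dose leaking through the tungsten shield,
#: back-derived from the ~6 Gy open vs ~1 Gy shielded measurement.
DEFAULT_SHIELD_TRANSMISSION = 1.0 / 6.0


@dataclass(frozen=True)
class ArmCalibration:
    """Dose/dwell calibration pairs plus the shield leakage fraction."""

    calibration_points: tuple[tuple[float, float], ...] = DEFAULT_CALIBRATION_POINTS
    shield_transmission: float = DEFAULT_SHIELD_TRANSMISSION

    def __post_init__(self) -> None:
        if not 0.0 <= self.shield_transmission <= 1.0:
            raise ValueError("shield_transmission must lie in [0, 1]")
        for dose, dwell in self.calibration_points:
            if dose <= 0 or dwell <= 0:
                raise ValueError("calibration doses and dwells must be positive")


@dataclass(frozen=True)
class DoseSchedule:
    """Dwell time per plate column group.

    ``steps`` maps a half-open column range [start, stop) to the seconds the
    group rests in the exposure slit.  Every column must be covered exactly
    once.
    """

    steps: tuple[tuple[tuple[int, int], float], ...]

    def __post_init__(self) -> None:
        covered = np.zeros(N_COLS, dtype=int)
        for (start, stop), dwell in self.steps:
            if dwell < 0:
                raise ValueError("dwell times must be non-negative")
            covered[start:stop] += 1
        if not np.all(covered == 1):
            raise ValueError("schedule must cover every column exactly once")

    @property
    def total_time_s(self) -> float:
        return float(sum(dwell for _, dwell in self.steps))

    def dwell_per_column(self) -> np.ndarray:
        out = np.zeros(N_COLS)
        for (start, stop), dwell in self.steps:
            out[start:stop] = dwell
        return out


@dataclass(frozen=True)
class DeliveryStats:
    mean_rate_gy_per_min: float
    cv_percent: float
    r_squared: float


def fit_unit_time(calibration: ArmCalibration) -> float:
    """Least-squares seconds-per-Gy, constrained through the origin.

    Zero dwell delivers zero dose, so the dwell-vs-dose line is forced
    through the origin: slope = sum(d*t) / sum(d^2).
    """
    pts = np.asarray(calibration.calibration_points, dtype=float)
    if pts.size == 0:
        raise ValueError("calibration has no points")
    dose, dwell = pts[:, 0], pts[:, 1]
    return float(np.sum(dose * dwell) / np.sum(dose * dose))


def dwell_time_for_dose(dose_gy: float, unit_time_s_per_gy: float) -> float:
    """Seconds the plate must rest in the slit to receive ``dose_gy``."""
    if dose_gy < 0:
        raise ValueError("dose must be non-negative")
    return dose_gy * unit_time_s_per_gy


def dose_rate_from_dwell(dose_gy: float, dwell_s: float) -> float:
    """Delivered-dose rate in Gy/min from one (dose, dwell) observation."""
    if dwell_s <= 0:
        raise ValueError("dwell must be positive")
    return 60.0 * dose_gy / dwell_s


def build_schedule(
    target_doses_gy: "list[float] | np.ndarray",
    unit_time_s_per_gy: float,
    column_groups: "list[tuple[int, int]] | None" = None,
) -> DoseSchedule:
    """Dwell schedule delivering one target dose per column group.

    With ``column_groups`` omitted, the plate's 24 columns are split into
    equal contiguous groups, one per target (e.g. four 6-column groups for
    the 0/2/4/8 Gy ladder).
    """
    targets = np.asarray(target_doses_gy, dtype=float)
    if np.any(targets < 0):
        raise ValueError("target doses must be non-negative")
    if column_groups is None:
        if N_COLS % len(targets) != 0:
            raise ValueError(f"{len(targets)} targets do not evenly split {N_COLS} columns")
        width = N_COLS // len(targets)
        column_groups = [(i * width, (i + 1) * width) for i in range(len(targets))]
    if len(column_groups) != len(targets):
        raise ValueError("one column group per target required")
    steps = tuple(
        (tuple(group), float(dwell_time_for_dose(t, unit_time_s_per_gy)))
        for group, t in zip(column_groups, targets)
    )
    return DoseSchedule(steps=steps)


def simulate_delivery(
    schedule: DoseSchedule,
    rate_gy_per_min: float,
    shield_transmission: float = 1.0,
    shield_mask: "np.ndarray | None" = None,
    noise_sd: float = 0.0,
    seed: "int | None" = None,
) -> np.ndarray:
    """Deliver the schedule onto a 16 x 24 dose map (Gy).

    Open wells receive rate x dwell x (1 + eps) with eps ~ N(0, noise_sd);
    wells under the shield mask receive additionally x shield_transmission.
    """
    if rate_gy_per_min <= 0:
        raise ValueError("rate must be positive")
    dwell = schedule.dwell_per_column()
    dose = np.tile(rate_gy_per_min * dwell / 60.0, (N_ROWS, 1))
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        dose = dose * (1.0 + rng.normal(0.0, noise_sd, size=dose.shape))
    if shield_mask is not None:
        mask = np.asarray(shield_mask, dtype=bool)
        if mask.shape != dose.shape:
            raise ValueError("shield mask must be 16 x 24")
        dose = np.where(mask, dose * shield_transmission, dose)
    return np.clip(dose, 0.0, None)


def delivery_stats(dwells_s, doses_gy) -> DeliveryStats:
    """Quality summary of repeated delivery measurements.

    Per-measurement rates (60 * dose / dwell) give the mean rate and the
    coefficient of variation (sample SD, n-1); R^2 is from the simple linear
    regression of delivered dose on dwell time.
    """
    dwells = np.asarray(dwells_s, dtype=float)
    doses = np.asarray(doses_gy, dtype=float)
    if dwells.shape != doses.shape or dwells.size < 2:
        raise ValueError("need >= 2 paired (dwell, dose) measurements")
    if np.any(dwells <= 0):
        raise ValueError("dwells must be positive")
    rates = 60.0 * doses / dwells
    mean_rate = float(np.mean(rates))
    if mean_rate == 0:
        raise ValueError("CV undefined for all-zero measurements")
    cv = 100.0 * float(np.std(rates, ddof=1)) / mean_rate
    if np.ptp(dwells) == 0:
        # repeated measurements at one dwell carry no linearity information
        r2 = float("nan")
    else:
        fit = _stats.linregress(dwells, doses)
        r2 = float(fit.rvalue**2)
    return DeliveryStats(mean_rate_gy_per_min=mean_rate, cv_percent=cv, r_squared=r2)
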