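"""Synthetic wearable-light cohorts.

Emulates field recordings from body-worn photometric loggers: a regular
wake/sleep schedule with right-skewed (lognormal) indoor daytime light,
darkness during sleep, timed light interventions (e.g. morning blue-light
goggles), 30-180 s storage intervals, and day-to-day schedule jitter.
Cohorts pair each subject's series with observed ΔDLMO values generated
from the model itself plus Gaussian observation noise, so parameter- and
phase-recovery experiments have a known ground truth.

Intervention presets mirror the published field protocols:

``advance``       2 h morning blue light (CS 0.5) + evening orange filter
``delay``         3 h evening blue light (CS 0.5) + morning orange filter
``morning_blue``  1 h of ~225 lux blue light after waking (~CS 0.4)
``goggles``       3 h morning blue-light goggles (CS 0.5) + orange-filtered
                  evenings from 17:00 to bedtime

Orange-filtered light (no short wavelengths) carries essentially no
circadian stimulus and is modeled as CS 0.02.  The default schedule
emulates the delayed-sleep young-adult cohorts common to these protocols:
wake 09:00, sleep 01:00, and dim predominantly-indoor ambient exposure of
CS 0.05 at eye level while awake.  Absolute indoor levels in the field
studies are not published, so the ambient default is a plausible
stand-in, not a measured value; a 5-day baseline under such dim ambient
light leaves the oscillator only partially entrained, preserving the
influence of the initial circadian phase that the field analyses relied
on (a 2-week bright baseline would erase it).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Callable

import numpy as np

from .config import ModelConfig, SolverOptions
from .core import integrate_series
from .errors import ValidationError
from .light import LightSeries, Unit
from .markers import PhaseOffsetConfig, delta_phase, find_cbt_min, initialize_from_cbt_min
from .pipeline import SubjectRecord

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ScheduleSpec:
    """One segment (baseline or intervention) of a daily light schedule.

    Times are clock hours; levels are in ``unit``.  ``interventions`` is a
    list of (window_start, window_end, level) daily pulses that overwrite
    the ambient level inside their windows (overlaps resolve to the max
    level, with a warning).  ``day_sigma`` is the lognormal sigma (log
    units) of multiplicative daytime variability; ``jitter_sd`` jitters
    wake/sleep times per day.
    """

    wake_time: float = 9.0
    sleep_time: float = 1.0
    day_level: float = 0.05
    night_level: float = 0.0
    interventions: tuple[tuple[float, float, float], ...] = ()
    sample_interval: float = 180.0          # seconds
    n_days: int = 5
    jitter_sd: float = 0.25                 # hours
    day_sigma: float = 0.3                  # lognormal sigma, log units
    unit: Unit = Unit.CS
    seed: int = 0
    start_day: int = 0

    def __post_init__(self) -> None:
        if not (30.0 <= self.sample_interval <= 180.0):
            logger.warning(
                "sample_interval %.0f s outside the typical 30-180 s logger range",
                self.sample_interval,
            )
        if self.day_level < 0 or self.night_level < 0:
            raise ValidationError("light levels must be nonnegative")
        if any(level < 0 for _, _, level in self.interventions):
            raise ValidationError("intervention levels must be nonnegative")
        if self.n_days < 1:
            raise ValidationError("n_days must be >= 1")


def _in_window(clock: np.ndarray, start: float, end: float) -> np.ndarray:
    if start < end:
        return (clock >= start) & (clock < end)
    return (clock >= start) | (clock < end)


def generate_series(spec: ScheduleSpec) -> LightSeries:
    """Deterministic (seeded) light series for one schedule segment."""
    rng = np.random.default_rng(spec.seed)
    interval_h = spec.sample_interval / 3600.0
    n_per_day = int(round(86400.0 / spec.sample_interval))
    n = spec.n_days * n_per_day
    t0 = 24.0 * spec.start_day
    times = t0 + interval_h * np.arange(n)
    clock = np.mod(times, 24.0)
    day_idx = ((times - t0) // 24.0).astype(int)

    wake = np.mod(spec.wake_time + rng.normal(0.0, spec.jitter_sd, spec.n_days), 24.0)
    sleep = np.mod(spec.sleep_time + rng.normal(0.0, spec.jitter_sd, spec.n_days), 24.0)
    awake = _in_window_per_day(clock, day_idx, wake, sleep)

    noise = rng.lognormal(mean=-0.5 * spec.day_sigma**2, sigma=spec.day_sigma, size=n)
    values = np.where(awake, spec.day_level * noise, spec.night_level)

    applied = np.zeros(n, dtype=bool)
    for start, end, level in spec.interventions:
        mask = _in_window(clock, start, end)
        overlap = mask & applied
        if overlap.any():
            logger.warning("overlapping intervention windows; resolving by max level")
            values[mask] = np.maximum(values[mask], level)
        else:
            values[mask] = level
        applied |= mask

    if spec.unit is Unit.CS:
        values = np.minimum(values, 0.699)  # stay below the CS asymptote
    return LightSeries(times=times, values=values, unit=spec.unit)


def _in_window_per_day(
    clock: np.ndarray, day_idx: np.ndarray, wake: np.ndarray, sleep: np.ndarray
) -> np.ndarray:
    w = wake[day_idx]
    s = sleep[day_idx]
    normal = w < s
    out = np.where(normal, (clock >= w) & (clock < s), (clock >= w) | (clock < s))
    return out


# ---------------------------------------------------------------------------
# Protocol presets (printed timings/levels from the field protocols)
# ---------------------------------------------------------------------------

_ORANGE_CS = 0.02  # orange-filtered light: essentially no circadian stimulus


def _w(h: float) -> float:
    return float(np.mod(h, 24.0))


def _advance(base: ScheduleSpec) -> ScheduleSpec:
    morning = (_w(base.wake_time), _w(base.wake_time + 2.0), 0.5)
    evening = (_w(base.sleep_time - 3.0), _w(base.sleep_time), _ORANGE_CS)
    return replace(base, interventions=base.interventions + (morning, evening))


def _delay(base: ScheduleSpec) -> ScheduleSpec:
    evening = (_w(base.sleep_time - 3.0), _w(base.sleep_time), 0.5)
    morning = (_w(base.wake_time), _w(base.wake_time + 2.0), _ORANGE_CS)
    return replace(base, interventions=base.interventions + (evening, morning))


def _morning_blue(base: ScheduleSpec) -> ScheduleSpec:
    window = (_w(base.wake_time), _w(base.wake_time + 1.0), 0.4)
    return replace(base, interventions=base.interventions + (window,))


def _goggles(base: ScheduleSpec) -> ScheduleSpec:
    morning = (_w(base.wake_time), _w(base.wake_time + 3.0), 0.5)
    evening = (17.0, _w(base.sleep_time), _ORANGE_CS)
    return replace(base, interventions=base.interventions + (morning, evening))


PRESETS: dict[str, Callable[[ScheduleSpec], ScheduleSpec]] = {
    "advance": _advance,
    "delay": _delay,
    "morning_blue": _morning_blue,
    "goggles": _goggles,
}


def preset_schedule(name: str, base: ScheduleSpec | None = None) -> ScheduleSpec:
    """Apply a named intervention preset to a base schedule."""
    if name not in PRESETS:
        raise ValueError(f"unknown preset {name!r}; choose from {sorted(PRESETS)}")
    return PRESETS[name](base or ScheduleSpec())


# ---------------------------------------------------------------------------
# Cohorts
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CohortSpec:
    """Synthetic cohort: chronotype spread, observation noise, schedules.

    ``true_init_cbt_min`` is the chronotype center (clock time of the
    initial CBT_min); per-subject chronotypes are Gaussian around it with
    SD ``chronotype_sd``.  Observation noise (SD ``obs_noise_sd``) is
    added to the model-truth ΔDLMO, not to the two DLMO times separately,
    because the evaluation operates on ΔDLMO.
    """

    n_subjects: int = 20
    true_init_cbt_min: float = 4.0
    chronotype_sd: float = 0.0
    obs_noise_sd: float = 0.25
    baseline_schedule: ScheduleSpec = field(default_factory=lambda: ScheduleSpec(n_days=5))
    intervention_schedule: ScheduleSpec = field(
        default_factory=lambda: preset_schedule("goggles", ScheduleSpec(n_days=7))
    )
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ValidationError("n_subjects must be >= 1")
        if self.chronotype_sd < 0 or self.obs_noise_sd < 0:
            raise ValidationError("SDs must be nonnegative")


def simulate_true_dlmos(
    baseline: LightSeries,
    intervention: LightSeries,
    cfg: ModelConfig,
    init_cbt_min: float,
    opts: SolverOptions = SolverOptions(),
    offsets: PhaseOffsetConfig = PhaseOffsetConfig(),
) -> tuple[float, float]:
    """Model-truth (baseline DLMO, post DLMO) clock times for one subject,
    integrating continuously from baseline through intervention."""
    from .core import PacemakerState, Trajectory  # avoid cycle at import time

    t0 = float(baseline.times[0])
    state0 = initialize_from_cbt_min(
        init_cbt_min, cfg, initial_light=float(baseline.values[0]),
        t_start=t0, offsets=offsets,
    )
    traj_b = integrate_series(state0, baseline, cfg, opts)
    base_dlmo = find_cbt_min(traj_b, offsets).last_dlmo

    end_state = PacemakerState(float(traj_b.x[-1]), float(traj_b.xc[-1]), float(traj_b.n[-1]))
    tail = float(np.median(np.diff(intervention.times))) if len(intervention) > 1 else 0.0
    traj_i = integrate_series(
        end_state, intervention, cfg, opts,
        t_span=(float(traj_b.t[-1]), float(intervention.times[-1]) + tail),
    )
    ti0 = float(intervention.times[0])
    sel = traj_i.t >= ti0 - 1e-9
    traj_sel = Trajectory(traj_i.t[sel], traj_i.x[sel], traj_i.xc[sel], traj_i.n[sel])
    post_dlmo = find_cbt_min(traj_sel, offsets).last_dlmo
    return base_dlmo, post_dlmo


def generate_cohort(
    spec: CohortSpec,
    cfg: ModelConfig = ModelConfig(),
    opts: SolverOptions = SolverOptions(),
    offsets: PhaseOffsetConfig = PhaseOffsetConfig(),
) -> list[SubjectRecord]:
    """Generate a fully reproducible synthetic cohort.

    Per subject: draw a chronotype, generate seeded baseline and
    intervention series (the intervention segment's timeline continues the
    baseline's), simulate the model to obtain true DLMOs, then add
    Gaussian noise to the true ΔDLMO to form the observations.
    """
    master = np.random.default_rng(spec.seed)
    base0 = spec.baseline_schedule
    inter0 = replace(
        spec.intervention_schedule,
        start_day=base0.start_day + base0.n_days,
    )

    subjects: list[SubjectRecord] = []
    for i in range(spec.n_subjects):
        s_base = int(master.integers(0, 2**31 - 1))
        s_inter = int(master.integers(0, 2**31 - 1))
        chronotype = float(
            np.mod(spec.true_init_cbt_min + master.normal(0.0, spec.chronotype_sd), 24.0)
        )
        noise = float(master.normal(0.0, spec.obs_noise_sd))

        baseline = generate_series(replace(base0, seed=s_base))
        intervention = generate_series(replace(inter0, seed=s_inter))
        true_base, true_post = simulate_true_dlmos(
            baseline, intervention, cfg, chronotype, opts, offsets
        )
        true_delta = delta_phase(true_post, true_base)
        obs_post = float(np.mod(true_base + true_delta + noise, 24.0))
        subjects.append(
            SubjectRecord(
                subject_id=f"S{i:03d}",
                baseline_series=baseline,
                intervention_series=intervention,
                observed_baseline_dlmo=true_base,
                observed_post_dlmo=obs_post,
                chronotype_label="none",
            )
        )
    return subjects


def write_cohort(subjects: list[SubjectRecord], out_dir) -> "Path":
    """Write per-subject light CSVs plus a manifest; returns manifest path."""
    from pathlib import Path

    import pandas as pd

    from .light import write_light_csv

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows = []
    for s in subjects:
        b = f"{s.subject_id}_baseline.csv"
        iv = f"{s.subject_id}_intervention.csv"
        s.baseline_series.subject_id = s.subject_id
        s.intervention_series.subject_id = s.subject_id
        write_light_csv(s.baseline_series, out / b)
        write_light_csv(s.intervention_series, out / iv)
        rows.append(
            {
                "subject_id": s.subject_id,
                "baseline_file": b,
                "intervention_file": iv,
                "obs_baseline_dlmo": round(s.observed_baseline_dlmo, 6),
                "obs_post_dlmo": round(s.observed_post_dlmo, 6),
                "chronotype": s.chronotype_label,
            }
        )
    manifest = out / "cohort.csv"
    pd.DataFrame(rows).to_csv(manifest, index=False)
    return manifest
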