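"""Phase response curve (PRC) simulation.

A standardized light pulse (fixed level and duration, optionally repeated
on consecutive circadian cycles) is delivered with its midpoint at a grid
of circadian phases relative to CBT_min.  After a dark washout, the phase
shift is the wrapped difference between the treatment run's final CBT_min
and that of an unstimulated control run sharing all settings — the control
subtraction removes free-run drift exactly.  Delays are positive.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .config import ModelConfig, SolverOptions
from .core import PacemakerState, integrate_series
from .light import LightSeries, Unit
from .markers import PhaseOffsetConfig, dim_light_cycle, find_cbt_min

#: Sampling interval (hours) of the constructed pulse series.
_SAMPLE_H = 60.0 / 3600.0


@dataclass(frozen=True)
class PulseSpec:
    """Standardized light pulse protocol.

    duration : pulse length in hours.
    level : pulse light level, in ``unit``.
    n_cycles : number of consecutive daily administrations (the classic
        bright-pulse protocol uses three ~6 h pulses on successive cycles).
    background : light level between pulses (usually darkness).
    unit : unit of ``level``/``background``.
    """

    duration: float = 6.0
    level: float = 0.5
    n_cycles: int = 3
    background: float = 0.0
    unit: Unit = Unit.CS

    def __post_init__(self) -> None:
        if self.duration <= 0:
            raise ValueError("duration must be positive")
        if self.level < 0 or self.background < 0:
            raise ValueError("levels must be nonnegative")
        if self.n_cycles < 1:
            raise ValueError("n_cycles must be >= 1")


@dataclass
class PRCCurve:
    """Phase shift vs circadian phase of the pulse midpoint."""

    initial_phases: np.ndarray   # hours relative to CBT_min at pulse midpoint
    shifts: np.ndarray           # signed hours, delays positive
    pulse: PulseSpec

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"phase_h": self.initial_phases, "shift_h": self.shifts})

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)


def _pulse_series(
    pulse: PulseSpec, t_end: float, pulse_windows: list[tuple[float, float]]
) -> LightSeries:
    """Piecewise-constant series over [0, t_end] at 1-min sampling."""
    times = np.arange(0.0, t_end, _SAMPLE_H)
    values = np.full(times.shape, pulse.background)
    for a, b in pulse_windows:
        values[(times >= a) & (times < b)] = pulse.level
    return LightSeries(times=times, values=values, unit=pulse.unit)


def _last_min_near(markers_abs: np.ndarray, t_ref: float) -> float:
    return float(markers_abs[np.argmin(np.abs(markers_abs - t_ref))])


def compute_prc(
    pulse: PulseSpec,
    phase_grid: np.ndarray | list[float] | None = None,
    cfg: ModelConfig = ModelConfig(),
    opts: SolverOptions = SolverOptions(),
    lead_in_cycles: int = 1,
    washout_cycles: int = 3,
    offsets: PhaseOffsetConfig = PhaseOffsetConfig(),
) -> PRCCurve:
    """Simulate the PRC of the pacemaker for a pulse protocol.

    For each phase in ``phase_grid`` (hours of pulse midpoint relative to
    CBT_min; default 24 phases spanning -12..+11 h), the oscillator starts
    on the dark limit cycle at its x-minimum, free-runs for
    ``lead_in_cycles``, receives ``pulse.n_cycles`` pulses centered at the
    stated phase on consecutive free-run cycles, then free-runs for
    ``washout_cycles`` before the final CBT_min is compared against the
    control run (identical, but with the pulse level replaced by the
    background level).
    """
    if washout_cycles < 2:
        raise ValueError("washout must span at least 2 cycles")
    if phase_grid is None:
        phase_grid = np.arange(-12.0, 12.0, 1.0)
    phase_grid = np.asarray(phase_grid, dtype=float)

    period, phi, xs, xcs = dim_light_cycle(cfg)
    # start exactly at the x-minimum (phase 0 of the cached cycle)
    state0 = PacemakerState(float(xs[0]), float(xcs[0]), 0.0)
    total = (lead_in_cycles + pulse.n_cycles + washout_cycles) * period + period
    t_ref_end = total - 0.5 * period  # where to read the final marker

    control_pulse = PulseSpec(
        duration=pulse.duration, level=pulse.background, n_cycles=pulse.n_cycles,
        background=pulse.background, unit=pulse.unit,
    )

    def run(p: PulseSpec, midpoint_phase: float) -> float:
        # phase is circadian-time-of-day relative to CBT_min: wrap to (-12, 12]
        ph = np.mod(midpoint_phase + 12.0, 24.0) - 12.0
        windows = []
        for c in range(p.n_cycles):
            mid = (lead_in_cycles + c) * period + ph
            windows.append((mid - p.duration / 2.0, mid + p.duration / 2.0))
        series = _pulse_series(p, total, windows)
        traj = integrate_series(state0, series, cfg, opts, t_span=(0.0, total),
                                gap_threshold=None)
        markers = find_cbt_min(traj, offsets)
        return _last_min_near(markers.cbt_min_abs, t_ref_end)

    t_ctrl = run(control_pulse, 0.0)  # control is phase-independent

    shifts = np.empty(phase_grid.size)
    for j, ph in enumerate(phase_grid):
        t_treat = run(pulse, float(ph))
        d = np.mod(t_treat - t_ctrl, period)
        if d > period / 2.0:
            d -= period
        shifts[j] = d
    return PRCCurve(initial_phases=phase_grid, shifts=shifts, pulse=pulse)


@dataclass
class PRCSummary:
    max_advance: float           # hours, reported as a positive magnitude
    max_delay: float
    amplitude: float             # peak-to-trough
    zero_crossing_phase: float   # nan for a degenerate (all-zero) curve

    def to_dict(self) -> dict:
        return {
            "max_advance": self.max_advance,
            "max_delay": self.max_delay,
            "amplitude": self.amplitude,
            "zero_crossing_phase": self.zero_crossing_phase,
        }


def prc_summary(curve: PRCCurve) -> PRCSummary:
    """Max advance/delay, peak-to-trough amplitude, and the delay-to-advance
    zero crossing (linear interpolation; nan if the curve never changes
    sign or is identically zero)."""
    s = curve.shifts
    p = curve.initial_phases
    amplitude = float(s.max() - s.min())
    max_delay = float(max(s.max(), 0.0))
    max_advance = float(max(-s.min(), 0.0))

    crossing = float("nan")
    if np.any(s > 0) and np.any(s < 0):
        # first sign change scanning in phase order
        for i in range(s.size - 1):
            if s[i] == 0.0:
                crossing = float(p[i])
                break
            if s[i] * s[i + 1] < 0:
                frac = s[i] / (s[i] - s[i + 1])
                crossing = float(p[i] + frac * (p[i + 1] - p[i]))
                break
    return PRCSummary(
        max_advance=max_advance, max_delay=max_delay,
        amplitude=amplitude, zero_crossing_phase=crossing,
    )
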