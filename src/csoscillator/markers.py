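"""Circadian phase markers: CBT_min and DLMO.

The model's phase reference is the minimum of the oscillator state x,
identified with the core body temperature minimum (CBT_min); an optional
lag parameter absorbs alternative phase-reference conventions.  DLMO is
defined as CBT_min minus a fixed offset (7 h by default).

Clock-time arithmetic is modulo 24 h; signed phase differences are wrapped
to (-12, +12] with delays positive (later = positive).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .config import ModelConfig, SolverOptions
from .core import DriveSeries, PacemakerState, Trajectory, integrate
from .errors import InsufficientSpanError

#: Minima closer than this (hours) are treated as the same circadian cycle
#: and only the deeper one is kept.
_MIN_SEPARATION = 15.0


@dataclass(frozen=True)
class PhaseOffsetConfig:
    """Marker timing conventions.

    dlmo_offset : hours by which DLMO precedes CBT_min (default 7).
    xmin_to_cbtmin_lag : hours added to the x-minimum time to define
        CBT_min (default 0; some pacemaker formulations use ~0.97 h).
    """

    dlmo_offset: float = 7.0
    xmin_to_cbtmin_lag: float = 0.0

    def __post_init__(self) -> None:
        if not (0.0 < self.dlmo_offset < 12.0):
            raise ValueError("dlmo_offset must be in (0, 12) hours")
        if not (0.0 <= self.xmin_to_cbtmin_lag <= 2.0):
            raise ValueError("xmin_to_cbtmin_lag must be in [0, 2] hours")


@dataclass
class MarkerSet:
    """Predicted CBT_min / DLMO times, one per circadian cycle."""

    cycle_index: np.ndarray       # integer day labels
    cbt_min_abs: np.ndarray       # absolute hours since origin
    cbt_min_clock: np.ndarray     # hours mod 24
    dlmo_clock: np.ndarray        # hours mod 24

    def __len__(self) -> int:
        return self.cycle_index.size

    @property
    def last_dlmo(self) -> float:
        return float(self.dlmo_clock[-1])

    @property
    def last_cbt_min_clock(self) -> float:
        return float(self.cbt_min_clock[-1])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "cycle": self.cycle_index,
                "cbt_min_clock": self.cbt_min_clock,
                "dlmo_clock": self.dlmo_clock,
                "abs_time_h": self.cbt_min_abs,
            }
        )

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)


def _refine_minimum(t: np.ndarray, y: np.ndarray, i: int) -> float:
    """Vertex of the parabola through the three points around index i."""
    a, b, _ = np.polyfit(t[i - 1:i + 2], y[i - 1:i + 2], 2)
    if a <= 0:  # degenerate/flat: keep the discrete sample
        return float(t[i])
    return float(-b / (2.0 * a))


def find_cbt_min(traj: Trajectory, cfg: PhaseOffsetConfig = PhaseOffsetConfig()) -> MarkerSet:
    """Locate one CBT_min per circadian cycle of a trajectory.

    Minima of x are found on the discrete grid, refined by quadratic
    interpolation, and minima closer than ~15 h are merged (deeper one
    kept), so successive markers are separated by one circadian cycle.

    Raises :class:`InsufficientSpanError` if the trajectory is shorter
    than one cycle or contains no interior minimum (e.g. constant x).
    """
    if len(traj) < 3 or traj.duration < 18.0:
        raise InsufficientSpanError(
            f"trajectory spans {traj.duration:.1f} h; need at least one circadian cycle"
        )
    t, x = traj.t, traj.x
    interior = np.flatnonzero((x[1:-1] < x[:-2]) & (x[1:-1] <= x[2:])) + 1
    if interior.size == 0:
        raise InsufficientSpanError("no interior minimum of x found (flat trajectory?)")

    # merge minima within the same cycle, keeping the deeper one
    kept: list[int] = []
    for i in interior:
        if kept and t[i] - t[kept[-1]] < _MIN_SEPARATION:
            if x[i] < x[kept[-1]]:
                kept[-1] = int(i)
        else:
            kept.append(int(i))

    times = np.array([_refine_minimum(t, x, i) for i in kept]) + cfg.xmin_to_cbtmin_lag
    cbt_clock = np.mod(times, 24.0)
    dlmo_clock = np.mod(cbt_clock - cfg.dlmo_offset, 24.0)
    return MarkerSet(
        cycle_index=np.arange(len(kept)),
        cbt_min_abs=times,
        cbt_min_clock=cbt_clock,
        dlmo_clock=dlmo_clock,
    )


def dlmo_from_cbt_min(cbt_min: float, cfg: PhaseOffsetConfig = PhaseOffsetConfig()) -> float:
    """DLMO clock time = (CBT_min - offset) mod 24."""
    return float(np.mod(cbt_min - cfg.dlmo_offset, 24.0))


def delta_phase(t1: float, t0: float) -> float:
    """Signed circular difference t1 - t0 in hours, wrapped to (-12, +12].

    Positive values are phase delays (t1 later than t0); the 12-h
    boundary maps to +12.
    """
    d = math.fmod(t1 - t0, 24.0)
    if d < 0:
        d += 24.0
    return d - 24.0 if d > 12.0 else d


# ---------------------------------------------------------------------------
# Limit-cycle initialization
# ---------------------------------------------------------------------------

_cycle_cache: dict[tuple, tuple[float, np.ndarray, np.ndarray, np.ndarray]] = {}


def dim_light_cycle(cfg: ModelConfig) -> tuple[float, np.ndarray, np.ndarray, np.ndarray]:
    """Dark (free-running) limit cycle of Process P.

    Returns ``(period, phi, x, xc)`` where ``phi`` runs from 0 (at the
    x-minimum) to the free-run period at ~1 min resolution.  Computed once
    per parameter set (100-cycle burn-in) and cached; in darkness the
    drive is zero, so only mu, tau_x and the period correction matter.
    """
    pp = cfg.pp
    key = (round(pp.mu, 12), round(pp.tau_x, 12), round(pp.period_correction, 12))
    if key in _cycle_cache:
        return _cycle_cache[key]

    dark = DriveSeries.dark()
    tau = pp.tau_x
    coarse = SolverOptions(rel_tol=1e-8, abs_tol=1e-10, max_step=0.5)
    fine = SolverOptions(rel_tol=1e-9, abs_tol=1e-11, max_step=1.0 / 60.0)

    burn = integrate(PacemakerState(-1.0, 0.0, 0.0), dark, (0.0, 97.0 * tau), cfg, coarse)
    s = PacemakerState(float(burn.x[-1]), float(burn.xc[-1]), 0.0)
    traj = integrate(s, dark, (0.0, 3.0 * tau), cfg, fine)

    markers = find_cbt_min(traj)
    if len(markers) < 2:
        raise InsufficientSpanError("could not resolve two successive free-run minima")
    t_min0, t_min1 = float(markers.cbt_min_abs[0]), float(markers.cbt_min_abs[1])
    period = t_min1 - t_min0

    sel = (traj.t >= t_min0) & (traj.t <= t_min1)
    phi = traj.t[sel] - t_min0
    result = (period, phi, traj.x[sel], traj.xc[sel])
    _cycle_cache[key] = result
    return result


def initialize_from_cbt_min(
    clock_time: float,
    cfg: ModelConfig = ModelConfig(),
    initial_light: float = 0.0,
    t_start: float = 0.0,
    offsets: PhaseOffsetConfig = PhaseOffsetConfig(),
) -> PacemakerState:
    """State on the dim-light limit cycle whose next x-minimum (plus lag)
    falls at ``clock_time``.

    ``t_start`` is the absolute hour at which the simulation begins (its
    clock time is ``t_start % 24``).  The Process L pool starts at its
    fixed point for ``initial_light`` (in drive units), so darkness gives
    n = 0.
    """
    if not (0.0 <= clock_time < 24.0):
        raise ValueError("clock_time must be in [0, 24)")
    period, phi, xs, xcs = dim_light_cycle(cfg)
    target = clock_time - offsets.xmin_to_cbtmin_lag
    delta = math.fmod(target - t_start, 24.0)
    if delta < 0:
        delta += 24.0
    if delta < 1e-9:
        delta = 24.0  # place the requested minimum one full day ahead
    phi0 = math.fmod(period - delta, period)
    if phi0 < 0:
        phi0 += period
    x0 = float(np.interp(phi0, phi, xs))
    xc0 = float(np.interp(phi0, phi, xcs))
    if initial_light < 0:
        raise ValueError("initial_light must be nonnegative")
    if initial_light == 0:
        n0 = 0.0
    else:
        a = cfg.lp.alpha0 * (initial_light / cfg.drive_I0) ** cfg.lp.p
        n0 = a / (a + cfg.lp.beta)
    return PacemakerState(x0, xc0, n0)
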