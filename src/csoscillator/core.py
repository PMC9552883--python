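"""Pacemaker dynamics and numerical integration.

Process L converts light I (in drive units, saturation constant I0) into a
neural drive via an activation rate

    alpha(I) = alpha0 * (I / I0)^p            [per minute]

and a used/ready element pool n with

    dn/dt = 60 * [alpha(I) * (1 - n) - beta * n]   [per hour]

The raw drive is B_hat = G * alpha(I) * (1 - n); with Process L bypassed
the adaptation term (1 - n) is frozen at 1.  The sensitivity modulator
multiplies by (1 - 0.4 x)(1 - 0.4 x_c), making photic effectiveness depend
on current circadian phase.  Process P is the van der Pol-type oscillator

    dx/dt   = (pi/12) * [x_c + B + mu * (x/3 + 4 x^3/3 - 256 x^7/105)]
    dx_c/dt = (pi/12) * [q B x_c - x * ((24 / (0.99669 tau_x))^2 + k B)]

Light between samples is held constant (zero-order hold); the adaptive
Dormand-Prince 4(5) integrator restarts at every sample boundary so no
sample is stepped over.  A fixed-step Euler integrator is provided as an
independent numerical cross-check.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np

from .config import ModelConfig, ProcessLParams, ProcessPParams, SolverOptions
from .errors import IntegrationError
from .light import LightSeries
from .phototransduction import prepare_drive_series

logger = logging.getLogger(__name__)

#: Gaps longer than this (hours) are filled with darkness after holding the
#: last value; shorter gaps are held at the last value throughout.
GAP_HOLD_HOURS = 0.25

#: Divergence guard: the limit cycle has amplitude O(1).
STATE_BOUND = 5.0

_PI12 = math.pi / 12.0


@dataclass
class PacemakerState:
    """Oscillator state (x, x_c) plus Process L pool fraction n."""

    x: float
    xc: float
    n: float

    def __post_init__(self) -> None:
        if not (math.isfinite(self.x) and math.isfinite(self.xc) and math.isfinite(self.n)):
            raise ValueError("state must be finite")
        if not (0.0 <= self.n <= 1.0):
            raise ValueError("n must lie in [0, 1]")
        if max(abs(self.x), abs(self.xc)) >= STATE_BOUND:
            raise ValueError(f"|x|, |x_c| must be < {STATE_BOUND}")


@dataclass
class Trajectory:
    """Dense time course of the pacemaker state."""

    t: np.ndarray
    x: np.ndarray
    xc: np.ndarray
    n: np.ndarray

    def __len__(self) -> int:
        return self.t.size

    @property
    def duration(self) -> float:
        return float(self.t[-1] - self.t[0]) if len(self) else 0.0

    def state_at(self, time: float) -> PacemakerState:
        """Linearly interpolated state at an absolute time within the span."""
        return PacemakerState(
            x=float(np.interp(time, self.t, self.x)),
            xc=float(np.interp(time, self.t, self.xc)),
            n=float(np.clip(np.interp(time, self.t, self.n), 0.0, 1.0)),
        )


# ---------------------------------------------------------------------------
# Right-hand sides (public, per-operation surface)
# ---------------------------------------------------------------------------

def alpha_of_I(I: float, lp: ProcessLParams, I0: float | None = None) -> float:
    """Light activation rate alpha(I) = alpha0 * (I/I0)^p, per minute."""
    if I < 0:
        raise ValueError("light must be nonnegative")
    i0 = lp.I0 if I0 is None else I0
    if i0 is None:
        raise ValueError("I0 not set; pass I0 or use a config-resolved value")
    if I == 0.0:
        return 0.0
    return lp.alpha0 * (I / i0) ** lp.p


def process_l_rhs(n: float, I: float, lp: ProcessLParams, I0: float | None = None) -> float:
    """dn/dt in hours^-1; zero exactly at the fixed point alpha/(alpha+beta)."""
    if not (0.0 <= n <= 1.0):
        raise ValueError("n must lie in [0, 1]")
    a = alpha_of_I(I, lp, I0)
    return 60.0 * (a * (1.0 - n) - lp.beta * n)


def photic_drive(
    state: PacemakerState,
    I: float,
    lp: ProcessLParams,
    pp: ProcessPParams,
    modulator_on: bool = True,
    bypass_l: bool = False,
    I0: float | None = None,
) -> float:
    """Photic drive B entering Process P.

    ``bypass_l`` freezes the adaptation term (1 - n) at 1 (light feeds
    Process P directly); ``modulator_on`` applies the phase-dependent
    (1 - c x)(1 - c x_c) factor.  B is zero whenever I is zero.
    """
    a = alpha_of_I(I, lp, I0)
    pool = 1.0 if bypass_l else (1.0 - state.n)
    b = lp.G * a * pool
    if modulator_on:
        c = pp.modulator_coeff
        b *= (1.0 - c * state.x) * (1.0 - c * state.xc)
    return b


def process_p_rhs(state: PacemakerState, B: float, pp: ProcessPParams) -> tuple[float, float]:
    """(dx/dt, dx_c/dt) in hours^-1 for the driven limit-cycle oscillator."""
    x, xc = state.x, state.xc
    if not (math.isfinite(x) and math.isfinite(xc) and math.isfinite(B)):
        raise IntegrationError("non-finite state or drive")
    omega2 = (24.0 / (pp.period_correction * pp.tau_x)) ** 2
    xdot = _PI12 * (xc + B + pp.mu * (x / 3.0 + 4.0 * x**3 / 3.0 - 256.0 * x**7 / 105.0))
    xcdot = _PI12 * (pp.q * B * xc - x * (omega2 + pp.k * B))
    return xdot, xcdot


# ---------------------------------------------------------------------------
# Drive preparation: zero-order hold segments with gap policy
# ---------------------------------------------------------------------------

@dataclass
class DriveSeries:
    """Piecewise-constant drive: value ``values[i]`` holds on
    [``bounds[i]``, ``bounds[i+1]``).  Before ``bounds[0]`` and after
    ``bounds[-1]`` the drive is dark (0)."""

    bounds: np.ndarray   # length m+1 segment edges, hours
    values: np.ndarray   # length m
    I0: float

    @classmethod
    def dark(cls, I0: float = 1.0) -> "DriveSeries":
        return cls(bounds=np.array([0.0]), values=np.array([]), I0=I0)

    def value_at(self, t: float) -> float:
        i = int(np.searchsorted(self.bounds, t, side="right")) - 1
        if i < 0 or i >= self.values.size:
            return 0.0
        return float(self.values[i])


def make_drive(
    series: LightSeries,
    cfg: ModelConfig,
    gap_threshold: float | None = GAP_HOLD_HOURS,
) -> DriveSeries:
    """Build the zero-order-hold drive in ``cfg.input_unit`` from a series.

    Each sample value holds until the next sample.  Gaps longer than
    ``gap_threshold`` hours hold the last value for ``gap_threshold`` and
    are then filled with darkness (logged); ``gap_threshold=None`` disables
    the policy (hold throughout), for exactly-piecewise-constant synthetic
    inputs.  Consecutive equal values are merged into one segment.
    """
    drive, i0 = prepare_drive_series(series, cfg.input_unit, cfg.cs)
    t = drive.times
    v = drive.values
    if t.size == 0:
        return DriveSeries.dark(i0)

    dt = np.diff(t)
    med = float(np.median(dt)) if dt.size else GAP_HOLD_HOURS
    tail = med if dt.size else GAP_HOLD_HOURS

    bounds = [float(t[0])]
    values: list[float] = []

    def emit(t_end: float, val: float) -> None:
        if values and values[-1] == val:
            bounds[-1] = t_end
        else:
            values.append(val)
            bounds.append(t_end)

    n_gaps = 0
    for i in range(t.size):
        t_next = float(t[i + 1]) if i + 1 < t.size else float(t[i]) + tail
        span = t_next - float(t[i])
        if gap_threshold is not None and span > gap_threshold:
            emit(float(t[i]) + gap_threshold, float(v[i]))
            emit(t_next, 0.0)
            n_gaps += 1
        elif span > 0:
            emit(t_next, float(v[i]))
    if n_gaps:
        logger.warning("filled %d gap(s) > %.2f h with darkness", n_gaps, gap_threshold)
    return DriveSeries(bounds=np.asarray(bounds), values=np.asarray(values), I0=i0)


# ---------------------------------------------------------------------------
# Integrators
# ---------------------------------------------------------------------------

# Dormand-Prince 4(5) tableau (FSAL pair, as used by classic RK45 codes).
_A21 = 1 / 5
_A31, _A32 = 3 / 40, 9 / 40
_A41, _A42, _A43 = 44 / 45, -56 / 15, 32 / 9
_A51, _A52, _A53, _A54 = 19372 / 6561, -25360 / 2187, 64448 / 6561, -212 / 729
_A61, _A62, _A63, _A64, _A65 = 9017 / 3168, -355 / 33, 46732 / 5247, 49 / 176, -5103 / 18656
_B1, _B3, _B4, _B5, _B6 = 35 / 384, 500 / 1113, 125 / 192, -2187 / 6784, 11 / 84
# error = y5 - y4 coefficients (includes the k7 = f(y5) stage)
_E1, _E3, _E4, _E5, _E6, _E7 = (
    71 / 57600, -71 / 16695, 71 / 1920, -17253 / 339200, 22 / 525, -1 / 40,
)


def _make_rhs(cfg: ModelConfig, I0: float):
    """Closure evaluating the full RHS with plain floats (hot path)."""
    lp, pp = cfg.lp, cfg.pp
    alpha0, beta, G, p = lp.alpha0, lp.beta, lp.G, lp.p
    mu, q, k = pp.mu, pp.q, pp.k
    c = pp.modulator_coeff
    omega2 = (24.0 / (pp.period_correction * pp.tau_x)) ** 2
    inv_i0 = 1.0 / I0
    bypass = not cfg.process_l
    modulate = cfg.modulator

    def rhs(x: float, xc: float, n: float, I: float):
        a = alpha0 * (I * inv_i0) ** p if I > 0.0 else 0.0
        ndot = 60.0 * (a * (1.0 - n) - beta * n)
        b = G * a * (1.0 if bypass else (1.0 - n))
        if modulate:
            b *= (1.0 - c * x) * (1.0 - c * xc)
        xdot = _PI12 * (xc + b + mu * (x / 3.0 + 4.0 * x * x * x / 3.0
                                       - 256.0 * x**7 / 105.0))
        xcdot = _PI12 * (q * b * xc - x * (omega2 + k * b))
        return xdot, xcdot, ndot

    return rhs


def _segments(drive: DriveSeries, t0: float, t1: float):
    """Yield (a, b, I) constant-light pieces covering [t0, t1]."""
    if t1 <= t0:
        return
    edges = drive.bounds
    t = t0
    while t < t1 - 1e-12:
        i = int(np.searchsorted(edges, t, side="right")) - 1
        if i < 0:
            b = min(float(edges[0]), t1) if edges.size else t1
            yield t, b, 0.0
        elif i >= drive.values.size:
            yield t, t1, 0.0
            b = t1
        else:
            b = min(float(edges[i + 1]), t1)
            yield t, b, float(drive.values[i])
        t = b


def integrate(
    state0: PacemakerState,
    drive: DriveSeries,
    t_span: tuple[float, float],
    cfg: ModelConfig = ModelConfig(),
    opts: SolverOptions = SolverOptions(),
) -> Trajectory:
    """Propagate the pacemaker through a light series.

    Adaptive Dormand-Prince 4(5) with the step capped at ``opts.max_step``
    (and implicitly at each light-sample boundary, where integration
    restarts).  The trajectory is recorded at every accepted step, giving
    <= 6 min output resolution at the default ``max_step``.

    Raises :class:`IntegrationError` on divergence (|x| or |x_c| > 5).
    """
    t0, t1 = float(t_span[0]), float(t_span[1])
    if t1 < t0:
        raise ValueError("t_span must be increasing")

    rhs = _make_rhs(cfg, drive.I0)
    rtol, atol, hmax = opts.rel_tol, opts.abs_tol, opts.max_step

    ts = [t0]
    xs = [state0.x]
    xcs = [state0.xc]
    ns = [state0.n]
    x, xc, n = state0.x, state0.xc, state0.n
    h = hmax

    for a, b, I in _segments(drive, t0, t1):
        t = a
        f1 = rhs(x, xc, n, I)
        while t < b - 1e-12:
            h = min(h, hmax, b - t)
            # stages (overflow in a trial stage = wildly too large a step)
            try:
                k1x, k1c, k1n = f1
                y2 = (x + h * _A21 * k1x, xc + h * _A21 * k1c, n + h * _A21 * k1n)
                k2x, k2c, k2n = rhs(*y2, I)
                y3 = (x + h * (_A31 * k1x + _A32 * k2x),
                      xc + h * (_A31 * k1c + _A32 * k2c),
                      n + h * (_A31 * k1n + _A32 * k2n))
                k3x, k3c, k3n = rhs(*y3, I)
                y4 = (x + h * (_A41 * k1x + _A42 * k2x + _A43 * k3x),
                      xc + h * (_A41 * k1c + _A42 * k2c + _A43 * k3c),
                      n + h * (_A41 * k1n + _A42 * k2n + _A43 * k3n))
                k4x, k4c, k4n = rhs(*y4, I)
                y5 = (x + h * (_A51 * k1x + _A52 * k2x + _A53 * k3x + _A54 * k4x),
                      xc + h * (_A51 * k1c + _A52 * k2c + _A53 * k3c + _A54 * k4c),
                      n + h * (_A51 * k1n + _A52 * k2n + _A53 * k3n + _A54 * k4n))
                k5x, k5c, k5n = rhs(*y5, I)
                y6 = (x + h * (_A61 * k1x + _A62 * k2x + _A63 * k3x + _A64 * k4x + _A65 * k5x),
                      xc + h * (_A61 * k1c + _A62 * k2c + _A63 * k3c + _A64 * k4c + _A65 * k5c),
                      n + h * (_A61 * k1n + _A62 * k2n + _A63 * k3n + _A64 * k4n + _A65 * k5n))
                k6x, k6c, k6n = rhs(*y6, I)
                xn = x + h * (_B1 * k1x + _B3 * k3x + _B4 * k4x + _B5 * k5x + _B6 * k6x)
                xcn = xc + h * (_B1 * k1c + _B3 * k3c + _B4 * k4c + _B5 * k5c + _B6 * k6c)
                nn = n + h * (_B1 * k1n + _B3 * k3n + _B4 * k4n + _B5 * k5n + _B6 * k6n)
                f7 = rhs(xn, xcn, nn, I)
                k7x, k7c, k7n = f7
            except OverflowError:
                if h <= 2e-9:
                    raise IntegrationError(
                        f"state overflow near t={t:.3f} h at minimal step"
                    )
                h = max(h * 0.2, 1e-9)
                continue
            ex = h * (_E1 * k1x + _E3 * k3x + _E4 * k4x + _E5 * k5x + _E6 * k6x + _E7 * k7x)
            ec = h * (_E1 * k1c + _E3 * k3c + _E4 * k4c + _E5 * k5c + _E6 * k6c + _E7 * k7c)
            en = h * (_E1 * k1n + _E3 * k3n + _E4 * k4n + _E5 * k5n + _E6 * k6n + _E7 * k7n)
            err = max(
                abs(ex) / (atol + rtol * max(abs(x), abs(xn))),
                abs(ec) / (atol + rtol * max(abs(xc), abs(xcn))),
                abs(en) / (atol + rtol * max(abs(n), abs(nn))),
            )
            if err <= 1.0 or h <= 1e-9:
                t += h
                x, xc, n = xn, xcn, nn
                if n < 0.0:
                    n = 0.0
                elif n > 1.0:
                    n = 1.0
                f1 = f7  # FSAL
                if not (math.isfinite(x) and math.isfinite(xc)):
                    raise IntegrationError(f"non-finite state at t={t:.3f} h")
                if max(abs(x), abs(xc)) > STATE_BOUND:
                    raise IntegrationError(
                        f"divergence at t={t:.3f} h: |state| > {STATE_BOUND}"
                    )
                ts.append(t)
                xs.append(x)
                xcs.append(xc)
                ns.append(n)
            # step-size update (both accept and reject)
            factor = 0.9 * err ** -0.2 if err > 0 else 5.0
            h *= min(5.0, max(0.2, factor))

    return Trajectory(
        t=np.asarray(ts), x=np.asarray(xs), xc=np.asarray(xcs), n=np.asarray(ns)
    )


def integrate_euler(
    state0: PacemakerState,
    drive: DriveSeries,
    t_span: tuple[float, float],
    cfg: ModelConfig = ModelConfig(),
    dt: float = 0.5 / 3600.0,
    record_every: int = 60,
) -> Trajectory:
    """Brute-force fixed-step forward-Euler integrator (numerical oracle).

    Deliberately independent of the adaptive path: one explicit Euler step
    per ``dt`` hours, with the zero-order-hold light looked up per step.
    Records every ``record_every``-th step (plus the endpoint).
    """
    t0, t1 = float(t_span[0]), float(t_span[1])
    n_steps = max(int(round((t1 - t0) / dt)), 0)
    rhs = _make_rhs(cfg, drive.I0)

    # precompute per-step light via vectorized segment lookup
    step_t = t0 + dt * np.arange(n_steps)
    idx = np.searchsorted(drive.bounds, step_t, side="right") - 1
    vals = np.zeros(n_steps)
    ok = (idx >= 0) & (idx < drive.values.size)
    if drive.values.size:
        vals[ok] = drive.values[idx[ok]]
    light = vals.tolist()

    x, xc, n = state0.x, state0.xc, state0.n
    ts = [t0]
    xs = [x]
    xcs = [xc]
    ns = [n]
    for i in range(n_steps):
        xd, xcd, nd = rhs(x, xc, n, light[i])
        x += dt * xd
        xc += dt * xcd
        n += dt * nd
        if n < 0.0:
            n = 0.0
        elif n > 1.0:
            n = 1.0
        if (i + 1) % record_every == 0 or i == n_steps - 1:
            ts.append(t0 + dt * (i + 1))
            xs.append(x)
            xcs.append(xc)
            ns.append(n)
    return Trajectory(
        t=np.asarray(ts), x=np.asarray(xs), xc=np.asarray(xcs), n=np.asarray(ns)
    )


def integrate_series(
    state0: PacemakerState,
    series: LightSeries,
    cfg: ModelConfig = ModelConfig(),
    opts: SolverOptions = SolverOptions(),
    t_span: tuple[float, float] | None = None,
    gap_threshold: float | None = GAP_HOLD_HOURS,
) -> Trajectory:
    """Convenience wrapper: prepare the drive from a series and integrate
    over its span (or an explicit ``t_span``)."""
    drive = make_drive(series, cfg, gap_threshold=gap_threshold)
    if t_span is None:
        tail = float(np.median(np.diff(series.times))) if len(series) > 1 else 0.0
        t_span = (float(series.times[0]), float(series.times[-1]) + tail)
    return integrate(state0, drive, t_span, cfg, opts)
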