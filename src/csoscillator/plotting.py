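"""Plotting hooks (matplotlib)."""

from __future__ import annotations

from .core import Trajectory
from .prc import PRCCurve


def plot_prc(curve: PRCCurve, ax=None):
    """Phase response curve panel: shift vs circadian phase of the pulse
    midpoint (delays positive, advances negative)."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(5.5, 3.5))
    ax.axhline(0.0, color="0.6", lw=0.8)
    ax.plot(curve.initial_phases, curve.shifts, "o-", ms=4)
    ax.set_xlabel("pulse midpoint, hours from CBT$_{min}$")
    ax.set_ylabel("phase shift (h)\ndelay > 0")
    return ax


def plot_trajectory(traj: Trajectory, ax=None):
    """Oscillator state x and Process L pool n over time."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(7, 3))
    ax.plot(traj.t / 24.0, traj.x, lw=0.9, label="x")
    ax.plot(traj.t / 24.0, traj.n, lw=0.9, label="n")
    ax.set_xlabel("days")
    ax.legend(frameon=False)
    return ax
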