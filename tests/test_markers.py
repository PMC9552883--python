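"""Phase markers: CBT_min extraction, DLMO offset, initialization."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from csoscillator import (
    PacemakerState,
    PhaseOffsetConfig,
    delta_phase,
    dlmo_from_cbt_min,
    find_cbt_min,
    initialize_from_cbt_min,
    integrate,
)
from csoscillator.core import DriveSeries, Trajectory
from csoscillator.errors import InsufficientSpanError
from csoscillator.markers import dim_light_cycle


def _cosine_traj(days=2, minimum_at=4.0, step=0.1):
    t = np.arange(0.0, days * 24.0, step)
    x = -np.cos(2 * np.pi * (t - minimum_at) / 24.0)
    return Trajectory(t=t, x=x, xc=np.zeros_like(t), n=np.zeros_like(t))


class TestFindCBTMin:
    def test_cosine_minimum_located(self):
        markers = find_cbt_min(_cosine_traj(minimum_at=4.0))
        assert len(markers) == 2
        np.testing.assert_allclose(markers.cbt_min_clock, [4.0, 4.0], atol=1 / 60)

    def test_flat_trajectory_rejected(self):
        t = np.arange(0.0, 48.0, 0.1)
        traj = Trajectory(t=t, x=np.ones_like(t), xc=np.zeros_like(t), n=np.zeros_like(t))
        with pytest.raises(InsufficientSpanError):
            find_cbt_min(traj)

    def test_short_trajectory_rejected(self):
        with pytest.raises(InsufficientSpanError):
            find_cbt_min(_cosine_traj(days=0.5))

    def test_lag_shifts_marker(self):
        cfg = PhaseOffsetConfig(xmin_to_cbtmin_lag=0.97)
        markers = find_cbt_min(_cosine_traj(minimum_at=4.0), cfg)
        np.testing.assert_allclose(markers.cbt_min_clock, [4.97, 4.97], atol=1 / 60)

    def test_offset_preserved_every_cycle(self):
        """dlmo = cbt_min - 7 (mod 24), exactly, for each cycle."""
        markers = find_cbt_min(_cosine_traj(days=5))
        diff = np.mod(markers.cbt_min_clock - markers.dlmo_clock, 24.0)
        np.testing.assert_allclose(diff, 7.0, atol=1e-9)


class TestDLMO:
    @pytest.mark.parametrize("cbt, dlmo", [(4.0, 21.0), (5.0, 22.0), (3.0, 20.0)])
    def test_seven_hour_offset(self, cbt, dlmo):
        assert dlmo_from_cbt_min(cbt) == pytest.approx(dlmo)

    def test_configurable_offset(self):
        assert dlmo_from_cbt_min(4.0, PhaseOffsetConfig(dlmo_offset=6.0)) == pytest.approx(22.0)


class TestDeltaPhase:
    @pytest.mark.parametrize(
        "t1, t0, expected",
        [
            (1.0, 23.0, 2.0),     # wrap across midnight, delay
            (23.0, 1.0, -2.0),    # advance
            (5.0, 5.0, 0.0),
            (11.0, 23.0, 12.0),   # boundary maps to +12
        ],
    )
    def test_wrapped_difference(self, t1, t0, expected):
        assert delta_phase(t1, t0) == pytest.approx(expected)

    @settings(deadline=None, derandomize=True, max_examples=100)
    @given(
        st.floats(min_value=0.0, max_value=24.0, exclude_max=True),
        st.floats(min_value=0.0, max_value=24.0, exclude_max=True),
    )
    def test_antisymmetric(self, a, b):
        d = delta_phase(a, b)
        assert -12.0 < d <= 12.0
        if abs(d) != 12.0:  # boundary is the documented exception
            assert delta_phase(b, a) == pytest.approx(-d, abs=1e-9)


class TestInitialization:
    def test_dark_integration_reproduces_requested_time(self, cfg):
        """Self-consistency on a 1-h grid of requested clock times."""
        dark = DriveSeries.dark(cfg.drive_I0)
        for clock in range(0, 24, 3):
            s = initialize_from_cbt_min(float(clock), cfg)
            traj = integrate(s, dark, (0.0, 30.0), cfg)
            markers = find_cbt_min(traj)
            err = delta_phase(markers.cbt_min_clock[0], float(clock))
            assert abs(err) < 0.1, f"clock {clock}: err {err}"

    def test_phase_rotation_between_requests(self, cfg):
        """04:00 vs 09:00 initial states differ by a 5-h rotation."""
        period, phi, xs, xcs = dim_light_cycle(cfg)
        s4 = initialize_from_cbt_min(4.0, cfg)
        s9 = initialize_from_cbt_min(9.0, cfg)
        # find phases of both states on the cached cycle
        p4 = phi[np.argmin((xs - s4.x) ** 2 + (xcs - s4.xc) ** 2)]
        p9 = phi[np.argmin((xs - s9.x) ** 2 + (xcs - s9.xc) ** 2)]
        rot = (p4 - p9) % period
        assert rot == pytest.approx(5.0, abs=0.05)

    def test_dark_pool_starts_empty(self, cfg):
        assert initialize_from_cbt_min(4.0, cfg, initial_light=0.0).n == 0.0

    def test_lit_pool_starts_at_fixed_point(self, cfg):
        s = initialize_from_cbt_min(4.0, cfg, initial_light=0.35)
        a = cfg.lp.alpha0 * (0.35 / cfg.drive_I0) ** cfg.lp.p
        assert s.n == pytest.approx(a / (a + cfg.lp.beta))

    def test_invalid_clock_rejected(self, cfg):
        with pytest.raises(ValueError):
            initialize_from_cbt_min(24.5, cfg)


def test_pacemaker_state_invariants():
    with pytest.raises(ValueError):
        PacemakerState(0.0, 0.0, 1.5)
    with pytest.raises(ValueError):
        PacemakerState(6.0, 0.0, 0.0)
    with pytest.raises(ValueError):
        PacemakerState(float("nan"), 0.0, 0.0)
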