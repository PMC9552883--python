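"""Process L / Process P dynamics and the integrator."""

import math

import numpy as np
import pytest

from csoscillator import (
    ModelConfig,
    PacemakerState,
    SolverOptions,
    alpha_of_I,
    integrate,
    integrate_euler,
    photic_drive,
    process_l_rhs,
    process_p_rhs,
)
from csoscillator.config import ProcessLParams, ProcessPParams
from csoscillator.core import DriveSeries, make_drive
from csoscillator.errors import IntegrationError
from csoscillator.light import LightSeries, Unit
from csoscillator.markers import find_cbt_min
from csoscillator.synth import ScheduleSpec, generate_series

LP = ProcessLParams(I0=9500.0)
PP = ProcessPParams()


class TestAlpha:
    @pytest.mark.parametrize(
        "I, expected",
        [
            (0.0, 0.0),
            (9500.0, 0.05),                       # alpha(I0) = alpha0
            (2 * 9500.0, 0.05 * 2 ** 0.6),        # direct arithmetic
        ],
    )
    def test_values(self, I, expected):
        assert alpha_of_I(I, LP) == pytest.approx(expected, rel=1e-12)

    def test_negative_light_rejected(self):
        with pytest.raises(ValueError):
            alpha_of_I(-1.0, LP)


class TestProcessL:
    def test_fixed_point_is_zero(self):
        a = alpha_of_I(500.0, LP)
        n_inf = a / (a + LP.beta)
        assert process_l_rhs(n_inf, 500.0, LP) == pytest.approx(0.0, abs=1e-15)

    def test_dark_decay_rate(self):
        # dn/dt = -60 * beta * n in darkness
        assert process_l_rhs(0.5, 0.0, LP) == pytest.approx(-60.0 * 0.0075 * 0.5)

    def test_fresh_pool_at_saturating_light(self):
        assert process_l_rhs(0.0, 9500.0, LP) == pytest.approx(60.0 * 0.05)

    def test_pool_domain_enforced(self):
        with pytest.raises(ValueError):
            process_l_rhs(1.2, 0.0, LP)


class TestDrive:
    def test_origin_state_full_pool(self):
        s = PacemakerState(0.0, 0.0, 0.0)
        assert photic_drive(s, 9500.0, LP, PP) == pytest.approx(33.75 * 0.05)

    def test_depleted_pool_kills_drive(self):
        s = PacemakerState(0.0, 0.0, 1.0)
        assert photic_drive(s, 9500.0, LP, PP) == 0.0

    def test_modulator_identity_at_origin(self):
        s = PacemakerState(0.0, 0.0, 0.3)
        on = photic_drive(s, 500.0, LP, PP, modulator_on=True)
        off = photic_drive(s, 500.0, LP, PP, modulator_on=False)
        assert on == pytest.approx(off)

    def test_bypass_freezes_adaptation(self):
        s = PacemakerState(0.0, 0.0, 0.9)
        b = photic_drive(s, 9500.0, LP, PP, bypass_l=True)
        assert b == pytest.approx(33.75 * 0.05)

    def test_monotone_in_light(self):
        s = PacemakerState(0.4, -0.6, 0.2)
        levels = [0.0, 10.0, 100.0, 1000.0, 9500.0]
        drives = [photic_drive(s, I, LP, PP) for I in levels]
        assert all(b1 <= b2 for b1, b2 in zip(drives, drives[1:]))


class TestProcessP:
    def test_quiescent_x_axis(self):
        xd, xcd = process_p_rhs(PacemakerState(0.0, 1.0, 0.0), 0.0, PP)
        assert xd == pytest.approx(math.pi / 12)
        assert xcd == pytest.approx(0.0)

    def test_unit_x_state(self):
        xd, xcd = process_p_rhs(PacemakerState(1.0, 0.0, 0.0), 0.0, PP)
        assert xd == pytest.approx((math.pi / 12) * 0.13 * (1 / 3 + 4 / 3 - 256 / 105))
        assert xcd == pytest.approx(-(math.pi / 12) * (24.0 / (0.99669 * 24.2)) ** 2)

    def test_against_symbolic_evaluation(self):
        """Full RHS vs an independently coded symbolic expression."""
        import sympy as sp

        x, xc, B = sp.symbols("x x_c B")
        mu, q, k, taux, pc = sp.Rational(13, 100), sp.Rational(33, 100), sp.Rational(55, 100), sp.Rational(121, 5), sp.Float("0.99669")
        xdot = sp.pi / 12 * (xc + B + mu * (x / 3 + sp.Rational(4, 3) * x**3 - sp.Rational(256, 105) * x**7))
        xcdot = sp.pi / 12 * (q * B * xc - x * ((24 / (pc * taux)) ** 2 + k * B))
        f = sp.lambdify((x, xc, B), (xdot, xcdot), "math")

        rng = np.random.default_rng(1)
        for _ in range(10):
            xs, xcs = rng.uniform(-1.2, 1.2, 2)
            b = rng.uniform(0.0, 2.0)
            got = process_p_rhs(PacemakerState(float(xs), float(xcs), 0.0), float(b), PP)
            want = f(xs, xcs, b)
            assert got[0] == pytest.approx(want[0], abs=1e-12)
            assert got[1] == pytest.approx(want[1], abs=1e-12)


def _constant_drive(level: float, i0: float, t_end: float) -> DriveSeries:
    return DriveSeries(bounds=np.array([0.0, t_end]), values=np.array([level]), I0=i0)


class TestIntegrate:
    def test_zero_length_span(self, cfg):
        s = PacemakerState(0.5, -0.5, 0.2)
        traj = integrate(s, DriveSeries.dark(0.7), (0.0, 0.0), cfg)
        assert len(traj) == 1
        assert traj.x[0] == 0.5

    def test_pool_fixed_point_convergence(self, cfg):
        """n(t) -> alpha/(alpha+beta) under constant light, within 1e-6."""
        level = 0.3
        a = alpha_of_I(level, cfg.lp, 0.7)
        n_inf = a / (a + cfg.lp.beta)
        tau_n = 1.0 / (60.0 * (a + cfg.lp.beta))
        drive = _constant_drive(level, 0.7, 20.0 * tau_n)
        opts = SolverOptions(rel_tol=1e-10, abs_tol=1e-12, max_step=0.05)
        traj = integrate(PacemakerState(0.0, 0.0, 0.0), drive, (0.0, 16.0 * tau_n), cfg, opts)
        assert abs(traj.n[-1] - n_inf) < 1e-6
        assert np.all(traj.n >= -1e-9) and np.all(traj.n <= 1.0 + 1e-9)

    def test_free_run_period(self, cfg):
        """Dark free run: period within tau_x +/- 0.05 h."""
        dark = DriveSeries.dark(0.7)
        coarse = SolverOptions(rel_tol=1e-8, abs_tol=1e-10, max_step=0.5)
        burn = integrate(PacemakerState(-1.0, 0.0, 0.0), dark, (0.0, 50 * 24.2), cfg, coarse)
        s = PacemakerState(float(burn.x[-1]), float(burn.xc[-1]), 0.0)
        traj = integrate(s, dark, (0.0, 10 * 24.2 + 12.0), cfg)
        minima = find_cbt_min(traj).cbt_min_abs
        periods = np.diff(minima)
        assert abs(np.mean(periods) - cfg.pp.tau_x) < 0.05

    def test_free_run_period_modulator_independent(self, cfg):
        """In darkness the modulator has no effect (B = 0)."""
        dark = DriveSeries.dark(0.7)
        s = PacemakerState(-1.0, 0.0, 0.0)
        t1 = integrate(s, dark, (0.0, 48.0), cfg.replace(modulator=True))
        t2 = integrate(s, dark, (0.0, 48.0), cfg.replace(modulator=False))
        assert np.allclose(t1.x[-1], t2.x[-1], atol=1e-12)

    def test_entrainment_to_24h_schedule(self, cfg):
        """16 h at CS 0.4 / 8 h dark entrains; CBT_min drift < 0.05 h/day."""
        days = 36
        bounds, values = [0.0], []
        for d in range(days):
            values += [0.4, 0.0]
            bounds += [d * 24.0 + 16.0, (d + 1) * 24.0]
        drive = DriveSeries(bounds=np.array(bounds), values=np.array(values), I0=0.7)
        s = PacemakerState(-1.0, 0.0, 0.0)
        traj = integrate(s, drive, (0.0, days * 24.0), cfg)
        minima = find_cbt_min(traj).cbt_min_abs
        late = minima[minima > 30 * 24.0]
        drifts = np.abs(np.diff(late) - 24.0)
        assert len(late) >= 4
        assert np.all(drifts < 0.05)

    def test_divergence_guard(self, cfg):
        hot = cfg.replace(G=1e7)
        drive = _constant_drive(0.699, 0.7, 24.0)
        with pytest.raises(IntegrationError):
            integrate(PacemakerState(0.0, 0.0, 0.0), drive, (0.0, 24.0), hot)

    def test_adaptive_matches_euler_oracle(self, cfg):
        """Adaptive RK45 vs brute-force 0.5 s Euler over 2 days of light."""
        series = generate_series(ScheduleSpec(n_days=2, seed=3))
        drive = make_drive(series, cfg)
        s = PacemakerState(-1.0, 0.0, 0.0)
        span = (0.0, 48.0)
        adaptive = integrate(s, drive, span, cfg)
        euler = integrate_euler(s, drive, span, cfg, dt=0.5 / 3600.0, record_every=120)
        x_adapt = np.interp(euler.t, adaptive.t, adaptive.x)
        assert np.max(np.abs(x_adapt - euler.x)) < 1e-3

    def test_against_scipy_reference(self, cfg):
        """Constant-light segment vs scipy's own RK45."""
        from scipy.integrate import solve_ivp

        level, i0 = 0.35, 0.7
        lp, pp = cfg.lp, cfg.pp
        a = alpha_of_I(level, lp, i0)
        om2 = (24.0 / (pp.period_correction * pp.tau_x)) ** 2

        def rhs(t, y):
            x, xc, n = y
            b = lp.G * a * (1 - n) * (1 - 0.4 * x) * (1 - 0.4 * xc)
            return [
                (math.pi / 12) * (xc + b + pp.mu * (x / 3 + 4 * x**3 / 3 - 256 * x**7 / 105)),
                (math.pi / 12) * (pp.q * b * xc - x * (om2 + pp.k * b)),
                60.0 * (a * (1 - n) - lp.beta * n),
            ]

        ref = solve_ivp(rhs, (0, 48), [-0.8, 0.2, 0.1], rtol=1e-10, atol=1e-12, dense_output=True)
        drive = _constant_drive(level, i0, 48.0)
        traj = integrate(PacemakerState(-0.8, 0.2, 0.1), drive, (0.0, 48.0), cfg)
        x_ref = ref.sol(traj.t)[0]
        assert np.max(np.abs(traj.x - x_ref)) < 1e-5


class TestDrivePreparation:
    def test_gap_policy(self, cfg):
        # 1-h gap: hold last value 15 min, then darkness
        series = LightSeries(
            times=np.array([0.0, 0.05, 1.05, 1.10]),
            values=np.array([0.2, 0.2, 0.3, 0.3]),
            unit=Unit.CS,
        )
        drive = make_drive(series, cfg)
        assert drive.value_at(0.06) == pytest.approx(0.2)   # held into gap
        assert drive.value_at(0.29) == pytest.approx(0.2)   # still within hold
        assert drive.value_at(0.5) == 0.0                   # gap filled dark
        assert drive.value_at(1.07) == pytest.approx(0.3)

    def test_gap_policy_disabled(self, cfg):
        series = LightSeries(
            times=np.array([0.0, 2.0]), values=np.array([0.2, 0.0]), unit=Unit.CS
        )
        drive = make_drive(series, cfg, gap_threshold=None)
        assert drive.value_at(1.5) == pytest.approx(0.2)
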