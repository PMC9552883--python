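"""Phase response curve machinery."""

import numpy as np
import pytest

from csoscillator import ModelConfig, PulseSpec, Unit, compute_prc, cs_from_cla, prc_summary
from csoscillator.prc import PRCCurve


@pytest.fixture(scope="module")
def cs_cfg():
    return ModelConfig(input_unit=Unit.CS)


class TestComputePRC:
    def test_zero_pulse_no_shift(self, cs_cfg):
        pulse = PulseSpec(duration=6.0, level=0.0, n_cycles=1)
        curve = compute_prc(pulse, phase_grid=[-6.0, 0.0, 6.0], cfg=cs_cfg)
        np.testing.assert_allclose(curve.shifts, 0.0, atol=1e-6)

    def test_delay_and_advance_regions(self, cs_cfg):
        """Light before CBT_min delays, after CBT_min advances (type 1)."""
        pulse = PulseSpec(duration=6.0, level=0.5, n_cycles=1)
        curve = compute_prc(pulse, phase_grid=[-5.0, 5.0], cfg=cs_cfg)
        before, after = curve.shifts
        assert before * after < 0, f"expected opposite signs, got {curve.shifts}"
        assert before > 0  # delay region (pulse in subjective evening/night)
        assert after < 0   # advance region (pulse after CBT_min)

    def test_unit_invariance(self, cs_cfg):
        """The same CL_A pulse fed as CL_A (converted in-pipeline) or
        pre-converted to CS gives identical curves."""
        cla_level = 800.0
        grid = [-6.0, -3.0, 0.0, 3.0, 6.0]
        pulse_cla = PulseSpec(duration=5.0, level=cla_level, n_cycles=1, unit=Unit.CLA)
        pulse_cs = PulseSpec(
            duration=5.0, level=cs_from_cla(cla_level), n_cycles=1, unit=Unit.CS
        )
        c1 = compute_prc(pulse_cla, phase_grid=grid, cfg=cs_cfg)
        c2 = compute_prc(pulse_cs, phase_grid=grid, cfg=cs_cfg)
        np.testing.assert_allclose(c1.shifts, c2.shifts, atol=1e-6)

    def test_type1_shape_preserved_in_cla_mode(self):
        """Re-characterizing the input (CL_A drive, I0 = 9500) preserves the
        type-1 shape: delay region before CBT_min, advance region after."""
        cla_cfg = ModelConfig(input_unit=Unit.CLA)
        pulse = PulseSpec(duration=6.0, level=5000.0, n_cycles=1, unit=Unit.CLA)
        curve = compute_prc(pulse, phase_grid=[-5.0, 5.0], cfg=cla_cfg)
        before, after = curve.shifts
        assert before > 0 and after < 0

    def test_periodicity(self, cs_cfg):
        pulse = PulseSpec(duration=4.0, level=0.4, n_cycles=1)
        a = compute_prc(pulse, phase_grid=[-4.0, 2.0], cfg=cs_cfg)
        b = compute_prc(pulse, phase_grid=[20.0, 26.0], cfg=cs_cfg)
        np.testing.assert_allclose(a.shifts, b.shifts, atol=1e-9)

    def test_stronger_pulse_not_weaker_response(self, cs_cfg):
        """At a fixed responsive phase, |shift| is nondecreasing in level."""
        shifts = []
        for level in (0.1, 0.3, 0.5):
            pulse = PulseSpec(duration=6.0, level=level, n_cycles=1)
            curve = compute_prc(pulse, phase_grid=[-5.0], cfg=cs_cfg)
            shifts.append(abs(curve.shifts[0]))
        assert shifts[0] <= shifts[1] + 1e-6 <= shifts[2] + 2e-6

    def test_short_washout_rejected(self, cs_cfg):
        with pytest.raises(ValueError, match="washout"):
            compute_prc(PulseSpec(), phase_grid=[0.0], cfg=cs_cfg, washout_cycles=1)


class TestSummary:
    def test_amplitude_arithmetic(self):
        curve = PRCCurve(
            initial_phases=np.array([-6.0, 6.0]),
            shifts=np.array([2.0, -3.0]),
            pulse=PulseSpec(),
        )
        s = prc_summary(curve)
        assert s.amplitude == pytest.approx(5.0)
        assert s.max_delay == pytest.approx(2.0)
        assert s.max_advance == pytest.approx(3.0)
        assert s.zero_crossing_phase == pytest.approx(-6.0 + 12.0 * 2.0 / 5.0)

    def test_all_zero_curve(self):
        curve = PRCCurve(
            initial_phases=np.array([-6.0, 0.0, 6.0]),
            shifts=np.zeros(3),
            pulse=PulseSpec(),
        )
        s = prc_summary(curve)
        assert s.amplitude == 0.0
        assert np.isnan(s.zero_crossing_phase)
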