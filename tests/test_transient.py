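"""Mittag-Leffler numerics, closed-form responses and the inverse-Laplace oracle."""

import numpy as np
import pytest
from scipy.special import erfcx, gamma

from cochlear_eis import (
    BiphasicPulse,
    BlockVariant,
    MLArgs,
    Provenance,
    TransimpedanceModel,
    VoltageWaveform,
    arbitrary_response,
    default_grid,
    mittag_leffler,
    numeric_ilt,
    pulse_response,
    pulse_response_numeric,
    rms_error,
    step_response,
    transimpedance_laplace,
)
from cochlear_eis.transient import ILTConvergenceError

from conftest import draw_random_model


class TestMittagLeffler:
    def test_alpha_one_is_exponential(self):
        z = -np.logspace(-6, 6, 25)
        assert np.allclose(mittag_leffler(1.0, 1.0, z), np.exp(z), atol=1e-12)

    def test_alpha_one_beta_two(self):
        z = -np.logspace(-6, 6, 25)
        assert np.allclose(mittag_leffler(1.0, 2.0, z), np.expm1(z) / z, atol=1e-12)

    def test_half_order_is_scaled_erfc(self):
        # E_{1/2,1}(-x) = exp(x^2)*erfc(x) evaluated stably as erfcx(x)
        x = np.logspace(-3, 6, 40)
        assert np.allclose(mittag_leffler(0.5, 1.0, -x), erfcx(x), atol=1e-10)

    def test_at_zero_equals_reciprocal_gamma(self):
        for a, b in [(0.5, 1.0), (0.7, 1.7), (1.0, 2.0)]:
            assert mittag_leffler(a, b, 0.0) == pytest.approx(1.0 / gamma(b), abs=1e-14)

    @pytest.mark.parametrize("alpha", [0.3, 0.55, 0.7, 0.85, 0.95])
    def test_beta_shift_identity_across_routes(self, alpha):
        # E_{a,a+1}(z) = (E_{a,1}(z) - 1)/z ties the series, asymptotic and
        # integral evaluation regions together
        for x in [0.5, 2.0, 5.0, 8.0, 20.0, 60.0, 300.0, 1e5]:
            lhs = mittag_leffler(alpha, alpha + 1.0, -x)
            rhs = (mittag_leffler(alpha, 1.0, -x) - 1.0) / (-x)
            assert lhs == pytest.approx(rhs, abs=2e-11)

    def test_complete_monotonicity_sign(self):
        # E_{a,1}(-x) is completely monotone, hence positive and decreasing
        for a in (0.4, 0.8, 0.99):
            vals = mittag_leffler(a, 1.0, -np.logspace(-2, 4, 30))
            assert np.all(vals > 0.0)
            assert np.all(np.diff(vals) < 0.0)

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            mittag_leffler(1.5, 1.0, -1.0)
        with pytest.raises(ValueError):
            mittag_leffler(0.5, -1.0, -1.0)
        with pytest.raises(ValueError):
            mittag_leffler(0.5, 1.0, 1.0)
        with pytest.raises(ValueError):
            MLArgs(alpha=0.0, beta=1.0, z=-1.0)


class TestStepResponse:
    def test_bare_cpe_capacitor_ramp(self):
        # p1 = 1: block 1 is an ideal capacitor, f(t) = t/Y1 (Gamma(2) = 1)
        model = TransimpedanceModel.from_values(
            Y1=1e-6, p1=1.0, R2=100.0, Y2=1e-5, p2=1.0, variant=BlockVariant.BARE_CPE1
        )
        t = np.array([1e-4, 1e-3])
        block2 = 100.0 * (1.0 - np.exp(-t / (100.0 * 1e-5)))
        assert np.allclose(step_response(model, t), t / 1e-6 + block2, rtol=1e-10)

    def test_rc_block_at_one_time_constant(self):
        model = TransimpedanceModel.from_values(
            Y1=1e6, p1=0.5, R2=100.0, Y2=1e-5, p2=1.0, variant=BlockVariant.BARE_CPE1
        )
        # block 1 admittance is huge, so f(1 ms) ~= R2*(1-1/e) ~= 63.212 ohm
        assert step_response(model, 1e-3) == pytest.approx(
            100.0 * (1.0 - np.exp(-1.0)), rel=1e-6
        )

    def test_block2_asymptote_and_causality(self, adjacent_model):
        m = adjacent_model
        t_inf = 1e3
        bare1 = TransimpedanceModel.from_values(
            Y1=m.Y1, p1=m.p1, R2=m.R2, Y2=m.Y2, p2=m.p2, variant=BlockVariant.BARE_CPE1
        )
        ramp = t_inf**m.p1 / (m.Y1 * gamma(m.p1 + 1.0))
        assert step_response(bare1, t_inf) - ramp == pytest.approx(m.R2, rel=1e-4)
        assert step_response(bare1, -1.0) == 0.0
        assert step_response(bare1, 0.0) == 0.0

    def test_matches_numeric_inverse_laplace(self):
        rng = np.random.default_rng(21)
        for _ in range(5):
            m = draw_random_model(rng)
            tau = (m.R2 * m.Y2) ** (1.0 / m.p2)
            t = np.logspace(np.log10(tau) - 2, np.log10(tau) + 1, 40)
            Z = transimpedance_laplace(m)
            num = numeric_ilt(lambda s: Z(s) / s, t)
            ana = step_response(m, t)
            assert np.max(np.abs(num - ana) / np.abs(ana)) < 1e-6


class TestPulseResponse:
    def test_all_p_one_ramp_cancels_after_pulse(self):
        model = TransimpedanceModel.from_values(
            Y1=1e-6, p1=1.0, R2=200.0, Y2=1e-7, p2=1.0, variant=BlockVariant.BARE_CPE1
        )
        pulse = BiphasicPulse(amplitude=1e-3, phase_duration=32e-6)
        wf = pulse_response(model, pulse)
        t0, tau2 = pulse.phase_duration, 200.0 * 1e-7
        post = wf.times > 2 * t0

        def rc(t):
            f = 200.0 * (1.0 - np.exp(-np.clip(t, 0, None) / tau2)) * (t > 0)
            return f

        # the capacitor-ramp contribution t - 2(t-T0) + (t-2T0) vanishes
        # identically, leaving only the exponential block-2 combination
        expected = -1e-3 * (
            rc(wf.times) - 2 * rc(wf.times - t0) + rc(wf.times - 2 * t0)
        )
        assert np.allclose(wf.voltages[post], expected[post], atol=1e-10 * 0.2)

    def test_cathodic_first_phase_negative(self, adjacent_model):
        pulse = BiphasicPulse(amplitude=800e-6, phase_duration=32e-6)
        wf = pulse_response(adjacent_model, pulse)
        first = wf.voltages[(wf.times > 0) & (wf.times < pulse.phase_duration)]
        assert np.all(first < 0.0)
        assert wf.voltages[0] == 0.0

    def test_superposition_equals_pulse_response(self, adjacent_model):
        pulse = BiphasicPulse(amplitude=800e-6, phase_duration=32e-6)
        grid = default_grid(pulse)
        direct = pulse_response(adjacent_model, pulse, grid)
        via_steps = arbitrary_response(adjacent_model, pulse.to_piecewise(), grid)
        assert np.allclose(direct.voltages, via_steps.voltages, atol=1e-15)

    def test_amplitude_scaling_linearity(self, adjacent_model):
        t0 = 32e-6
        w1 = pulse_response(adjacent_model, BiphasicPulse(400e-6, t0))
        w2 = pulse_response(adjacent_model, BiphasicPulse(800e-6, t0))
        assert np.allclose(w2.voltages, 2.0 * w1.voltages, rtol=1e-12)

    def test_monophasic_step_is_scaled_step_response(self, adjacent_model):
        from cochlear_eis import PiecewiseConstantStimulus

        stim = PiecewiseConstantStimulus(breakpoints=(0.0, 1e-3), levels=(2e-3,))
        grid = np.linspace(0.0, 1e-3, 129)
        wf = arbitrary_response(adjacent_model, stim, grid)
        expected = 2e-3 * np.asarray(step_response(adjacent_model, grid))
        assert np.allclose(wf.voltages, expected, rtol=1e-10, atol=1e-15)

    def test_grid_must_cover_pulse(self, adjacent_model):
        pulse = BiphasicPulse(amplitude=800e-6, phase_duration=32e-6)
        with pytest.raises(ValueError):
            pulse_response(adjacent_model, pulse, np.linspace(0, 50e-6, 64))

    def test_triphasic_stimulus_matches_numeric_oracle(self):
        from cochlear_eis import PiecewiseConstantStimulus

        rng = np.random.default_rng(3)
        m = draw_random_model(rng)
        t0 = 20e-6
        stim = PiecewiseConstantStimulus(
            breakpoints=(0.0, t0, 3 * t0, 4 * t0),
            levels=(-1e-3, 1e-3, -1e-3),
        )
        grid = np.linspace(0.0, 6 * t0, 241)
        wf = arbitrary_response(m, stim, grid)
        Z = transimpedance_laplace(m)
        num = np.zeros_like(grid)
        from cochlear_eis import stimulus_to_step_superposition

        for d, a in stimulus_to_step_superposition(stim):
            tau = grid - d
            sel = tau > 0
            num[sel] += a * numeric_ilt(lambda s: Z(s) / s, tau[sel])
        peak = np.max(np.abs(wf.voltages))
        assert np.max(np.abs(wf.voltages - num)) < 1e-6 * peak


class TestRMSError:
    def test_identical_and_offset(self, adjacent_model):
        pulse = BiphasicPulse(amplitude=800e-6, phase_duration=32e-6)
        wf = pulse_response(adjacent_model, pulse)
        assert rms_error(wf, wf) == (0.0, 0.0)
        shifted = VoltageWaveform(wf.times, wf.voltages + 1e-3, wf.provenance)
        rms, rel = rms_error(shifted, wf)
        assert rms == pytest.approx(1e-3, rel=1e-12)
        assert rel == pytest.approx(1e-3 / np.max(np.abs(wf.voltages)), rel=1e-12)

    def test_grid_mismatch_raises(self, adjacent_model):
        pulse = BiphasicPulse(amplitude=800e-6, phase_duration=32e-6)
        a = pulse_response(adjacent_model, pulse, np.linspace(0, 96e-6, 193))
        b = pulse_response(adjacent_model, pulse, np.linspace(0, 96e-6, 129))
        with pytest.raises(ValueError):
            rms_error(a, b)


class TestNumericILT:
    def test_reference_transforms(self):
        t = np.linspace(0.05, 5.0, 40)
        assert np.max(np.abs(numeric_ilt(lambda s: 1 / (s + 1), t) - np.exp(-t))) < 1e-8
        assert np.max(np.abs(numeric_ilt(lambda s: 1 / s**2, t) - t) / t) < 1e-8
        tal = numeric_ilt(lambda s: 1 / (s + 1), t, method="talbot")
        assert np.max(np.abs(tal - np.exp(-t))) < 1e-8

    def test_cpe_step_kernel_power_law(self):
        Y, p = 1e-5, 0.7
        t = np.logspace(-5, 0, 30)
        num = numeric_ilt(lambda s: 1.0 / (Y * s ** (p + 1.0)), t)
        ana = t**p / (Y * gamma(p + 1.0))
        assert np.max(np.abs(num - ana) / ana) < 1e-8

    def test_nonfinite_result_is_flagged(self):
        with pytest.raises(ILTConvergenceError):
            numeric_ilt(lambda s: np.full(np.shape(s), np.nan, dtype=complex),
                        np.array([1.0]))

    def test_requires_positive_times(self):
        with pytest.raises(ValueError):
            numeric_ilt(lambda s: 1 / s, np.array([0.0, 1.0]))


class TestWaveformContainer:
    def test_uniform_grid_enforced(self):
        with pytest.raises(ValueError):
            VoltageWaveform(times=np.array([0.0, 1.0, 3.0]), voltages=np.zeros(3))

    def test_provenance_tagging(self, adjacent_model):
        pulse = BiphasicPulse(amplitude=800e-6, phase_duration=32e-6)
        grid = default_grid(pulse)
        assert pulse_response(adjacent_model, pulse).provenance is Provenance.SIMULATED_CLOSED_FORM
        wf = pulse_response_numeric(adjacent_model, pulse, grid)
        assert wf.provenance is Provenance.SIMULATED_NUMERIC_ILT
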