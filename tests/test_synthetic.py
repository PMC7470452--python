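"""Ground-truth corpus generation, noisy spectra, pseudo-measured waveforms."""

import numpy as np
import pytest
from scipy import signal

from cochlear_eis import (
    ArrayGeometry,
    BiphasicPulse,
    CorpusSpec,
    ElectrodePairKey,
    Provenance,
    VoltageWaveform,
    butterworth_condition,
    default_sweep,
    generate_parameter_matrix,
    pulse_response,
    rms_error,
    simulate_corpus_spectra,
    simulate_measured_waveform,
    simulate_spectrum,
    transimpedance,
)


class TestParameterMatrix:
    def test_block1_and_theta2_location_independent(self, corpus_models):
        ref = next(iter(corpus_models.values()))
        for m in corpus_models.values():
            assert (m.R1, m.Y1, m.p1, m.p2) == (ref.R1, ref.Y1, ref.p1, ref.p2)

    def test_hill_r2_and_valley_y2_by_construction(self, corpus_models, geometry):
        for stim in geometry.electrodes:
            recs = [e for e in geometry.electrodes if e != stim]
            d = np.array([geometry.distance(stim, r) for r in recs])
            r2 = np.array([corpus_models[ElectrodePairKey(stim, r)].R2 for r in recs])
            y2 = np.array([corpus_models[ElectrodePairKey(stim, r)].Y2 for r in recs])
            order = np.argsort(d)
            ds, r2s, y2s = d[order], r2[order], y2[order]
            inc = np.diff(ds) > 0
            assert np.all(np.diff(r2s)[inc] < 0.0)  # hill: decreasing with distance
            assert np.all(np.diff(y2s)[inc] > 0.0)  # valley: increasing with distance
            assert np.all(np.abs(np.diff(r2s)[~inc]) < 1e-12)  # symmetric ties

    def test_deterministic(self, geometry, corpus_spec):
        a = generate_parameter_matrix(geometry, corpus_spec)
        b = generate_parameter_matrix(geometry, corpus_spec)
        assert a == b

    def test_spec_validation(self):
        with pytest.raises(ValueError):
            CorpusSpec(noise_sigma=0.5)
        with pytest.raises(ValueError):
            CorpusSpec(r1=-1.0)
        with pytest.raises(ValueError):
            ArrayGeometry(electrodes=(3,))


class TestSpectrumSimulation:
    def test_sigma_zero_is_exact_model(self, adjacent_model):
        sp = simulate_spectrum(adjacent_model, sigma=0.0)
        exact = transimpedance(adjacent_model, 2 * np.pi * sp.frequencies)
        assert np.array_equal(sp.impedances, exact)

    def test_default_sweep_has_41_log_spaced_points(self):
        f = default_sweep()
        assert f.size == 41
        assert f[0] == pytest.approx(10.0) and f[-1] == pytest.approx(1e5)
        assert np.allclose(np.diff(np.log10(f)), 0.1)

    def test_noise_is_proportional_and_seeded(self, adjacent_model):
        a = simulate_spectrum(adjacent_model, sigma=0.01, rng=5)
        b = simulate_spectrum(adjacent_model, sigma=0.01, rng=5)
        c = simulate_spectrum(adjacent_model, sigma=0.01, rng=6)
        assert np.array_equal(a.impedances, b.impedances)
        assert not np.array_equal(a.impedances, c.impedances)
        exact = transimpedance(adjacent_model, 2 * np.pi * a.frequencies)
        rel = np.abs(a.impedances / exact - 1.0)
        assert np.all(rel < 0.1) and np.median(rel) > 1e-4

    def test_corpus_spectra_pure_function_of_seed(self, geometry):
        spec = CorpusSpec(noise_sigma=0.01, seed=3)
        a = simulate_corpus_spectra(geometry, spec)
        b = simulate_corpus_spectra(geometry, spec)
        key = ElectrodePairKey(3, 5)
        assert np.array_equal(a[key].impedances, b[key].impedances)


class TestMeasuredWaveform:
    def test_noiseless_equals_closed_form(self, adjacent_model):
        pulse = BiphasicPulse(amplitude=800e-6, phase_duration=32e-6)
        wf = simulate_measured_waveform(adjacent_model, pulse, sigma_v=0.0)
        clean = pulse_response(adjacent_model, pulse)
        assert np.array_equal(wf.voltages, clean.voltages)
        assert wf.provenance is Provenance.MEASURED

    def test_default_stimulus_is_clinical_pulse(self, adjacent_model):
        wf = simulate_measured_waveform(adjacent_model)
        # grid spans [0, 3*T0] with T0 = 32 us
        assert wf.times[-1] == pytest.approx(96e-6)

    def test_noise_calibration(self, adjacent_model):
        pulse = BiphasicPulse(amplitude=800e-6, phase_duration=32e-6)
        clean = pulse_response(adjacent_model, pulse)
        rmss = []
        for r in range(10):
            noisy = simulate_measured_waveform(
                adjacent_model, pulse, sigma_v=0.01, rng=r
            )
            rmss.append(rms_error(noisy, clean)[0])
        expected = 0.01 * np.max(np.abs(clean.voltages))
        assert np.mean(rmss) == pytest.approx(expected, rel=0.25)


class TestButterworth:
    def _waveform(self, fs, n, values):
        return VoltageWaveform(times=np.arange(n) / fs, voltages=values)

    def test_constant_unchanged(self):
        wf = self._waveform(1e9, 4096, np.full(4096, 0.25))
        out = butterworth_condition(wf, cutoff_hz=6.25e6, order=4)
        assert np.allclose(out.voltages, 0.25, atol=1e-9)

    def test_single_pass_minus_3db_at_cutoff(self):
        fs, fc = 1e9, 6.25e6
        sos = signal.butter(4, fc, btype="low", fs=fs, output="sos")
        w, h = signal.sosfreqz(sos, worN=[fc], fs=fs)
        assert 20 * np.log10(np.abs(h[0])) == pytest.approx(-3.01, abs=0.05)

    def test_high_frequency_power_reduced(self):
        rng = np.random.default_rng(0)
        fs, n = 1e9, 8192
        t = np.arange(n) / fs
        base = np.sin(2 * np.pi * 1e6 * t)
        noisy = base + 0.5 * rng.standard_normal(n)
        out = butterworth_condition(self._waveform(fs, n, noisy), 6.25e6, order=4)
        spec_in = np.abs(np.fft.rfft(noisy)) ** 2
        spec_out = np.abs(np.fft.rfft(out.voltages)) ** 2
        f = np.fft.rfftfreq(n, 1 / fs)
        hi = f > 5e7
        lo = (f > 5e5) & (f < 2e6)
        assert spec_out[hi].sum() < 1e-3 * spec_in[hi].sum()
        assert spec_out[lo].sum() == pytest.approx(spec_in[lo].sum(), rel=0.05)

    def test_sampling_rate_precondition(self, adjacent_model):
        wf = simulate_measured_waveform(adjacent_model)  # fs ~ 2 MHz
        with pytest.raises(ValueError, match="sampling rate"):
            butterworth_condition(wf, cutoff_hz=6.25e6)
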