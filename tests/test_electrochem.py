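"""CV peak extraction, Nicholson ratio, cycle statistics, circuit impedance
model and fit, spectrum summaries."""

import numpy as np
import pytest

from brspike.electrochem import (CircuitParams, ImpedanceSpectrum, Voltammogram,
                                 circuit_impedance, extract_cv_peaks,
                                 fit_circuit, nicholson_ratio,
                                 summarize_cycles, summarize_spectrum,
                                 synthesize_voltammogram)
from brspike.exceptions import (InputError, InsufficientEventsError,
                                ParameterError)

TRUE_PARAMS = CircuitParams(R1=100.0, R2=5000.0, Q2=1e-6, n2=0.9,
                            R3=20_000.0, Q3=5e-5, n3=0.8, sigma_w=500.0)


def _spectrum_from(params: CircuitParams, noise=0.0, seed=0,
                   n=40) -> ImpedanceSpectrum:
    f = np.logspace(-1, 5, n)
    z = circuit_impedance(params, f)
    if noise > 0:
        rng = np.random.default_rng(seed)
        z = z * (1 + noise * rng.normal(size=z.size)) \
            + 1j * np.abs(z) * noise * rng.normal(size=z.size) * 0  # multiplicative only
    return ImpedanceSpectrum(frequency=f, z_real=z.real, z_imag=z.imag)


class TestCvPeaks:
    def test_symmetric_couple_ratio_near_one(self):
        vg = synthesize_voltammogram()
        peaks = extract_cv_peaks(vg)
        assert peaks.i_pa / abs(peaks.i_pc) == pytest.approx(1.0, abs=0.05)
        assert peaks.i_pa > 0 and peaks.i_pc < 0

    def test_capacitive_box_raises(self):
        n = 200
        up = np.linspace(-5, 5, n // 2)
        p = np.concatenate([up, up[::-1][1:]])
        i = np.where(np.arange(p.size) < n // 2, 20.0, -20.0)
        with pytest.raises(InputError, match="faradaic"):
            extract_cv_peaks(Voltammogram(potential=p, current=i))

    def test_current_scaling_linearity(self):
        vg = synthesize_voltammogram()
        scaled = Voltammogram(potential=vg.potential, current=3.0 * vg.current)
        a, b = extract_cv_peaks(vg), extract_cv_peaks(scaled)
        for field in ("i_pa", "i_pc", "i_sp", "i_pc0", "i_sp0"):
            assert getattr(b, field) == pytest.approx(3.0 * getattr(a, field),
                                                      rel=1e-9)

    def test_monotone_sweep_rejected(self):
        p = np.linspace(-5, 5, 100)
        with pytest.raises(InputError):
            extract_cv_peaks(Voltammogram(potential=p, current=np.sin(p)))


class TestNicholson:
    def test_intercept(self):
        assert nicholson_ratio(0, 0) == pytest.approx(0.086)

    def test_hand_arithmetic(self):
        assert nicholson_ratio(0.5, 0.25) == pytest.approx(0.70725)

    def test_affine_coefficients(self):
        base = nicholson_ratio(0.3, 0.4)
        assert nicholson_ratio(0.3 + 1, 0.4) - base == pytest.approx(1.0)
        assert nicholson_ratio(0.3, 0.4 + 2) - base == pytest.approx(0.485 * 2)

    def test_nonfinite_rejected(self):
        with pytest.raises(ParameterError):
            nicholson_ratio(np.inf, 0)


class TestCycleStats:
    def test_constant_cycles_zero_sd(self):
        peaks = [extract_cv_peaks(synthesize_voltammogram()) for _ in range(3)]
        stats = summarize_cycles(peaks)
        assert stats.i_pa_sd == 0.0 and stats.ratio_sd == 0.0

    def test_mean_within_3_sem_of_complex_peak_current(self):
        """100 cycles with anodic peaks ~ Normal(285.00, 6.42)."""
        rng = np.random.default_rng(42)
        heights = rng.normal(285.00, 6.42, 100)
        peaks = [extract_cv_peaks(synthesize_voltammogram(i_pa=h, capacitive=0.0))
                 for h in heights]
        stats = summarize_cycles(peaks)
        sem = stats.i_pa_sd / np.sqrt(100)
        assert stats.i_pa_mean == pytest.approx(285.00, abs=3 * sem)

    def test_hand_arithmetic_two_values(self):
        vals = np.array([1.0, 3.0])
        assert vals.mean() == 2.0
        assert np.std(vals, ddof=1) == pytest.approx(np.sqrt(2))

    def test_single_cycle_insufficient(self):
        with pytest.raises(InsufficientEventsError):
            summarize_cycles([extract_cv_peaks(synthesize_voltammogram())])


class TestCircuitImpedance:
    def test_ideal_capacitor_limit(self):
        omega = 2 * np.pi * np.logspace(0, 4, 20)
        from brspike.electrochem import cpe_impedance
        C = 1e-6
        assert np.allclose(cpe_impedance(C, 1.0, omega), 1 / (1j * omega * C),
                           rtol=1e-12)

    def test_resistor_limit_n_zero(self):
        from brspike.electrochem import cpe_impedance
        z = cpe_impedance(0.01, 0.0, 2 * np.pi * np.logspace(0, 4, 10))
        assert np.allclose(z, 100.0) and np.allclose(z.imag, 0.0)

    def test_warburg_phase_minus_45(self):
        from brspike.electrochem import warburg_impedance
        z = warburg_impedance(500.0, 2 * np.pi * np.logspace(-2, 4, 20))
        assert np.allclose(np.degrees(np.angle(z)), -45.0, atol=1e-9)

    def test_real_part_at_least_series_resistance(self):
        f = np.logspace(-2, 5, 60)
        z = circuit_impedance(TRUE_PARAMS, f)
        assert np.all(z.real >= TRUE_PARAMS.R1)

    def test_magnitude_monotone_nonincreasing(self):
        f = np.logspace(-2, 5, 200)
        mag = np.abs(circuit_impedance(TRUE_PARAMS, f))
        assert np.all(np.diff(mag) <= 1e-9 * mag[:-1])

    def test_nonpositive_frequency_rejected(self):
        with pytest.raises(ParameterError):
            circuit_impedance(TRUE_PARAMS, 0.0)


class TestCircuitFit:
    def test_noiseless_recovery_within_01_percent(self):
        spectrum = _spectrum_from(TRUE_PARAMS)
        init = CircuitParams(R1=150, R2=3000, Q2=2e-6, n2=0.85,
                             R3=30_000, Q3=2e-5, n3=0.7, sigma_w=300)
        fit = fit_circuit(spectrum, init)
        for name in ("R1", "R2", "Q2", "n2", "R3", "Q3", "n3", "sigma_w"):
            assert getattr(fit.params, name) == pytest.approx(
                getattr(TRUE_PARAMS, name), rel=1e-3), name

    def test_noisy_recovery_within_5_percent(self):
        spectrum = _spectrum_from(TRUE_PARAMS, noise=0.01, seed=11)
        init = CircuitParams(R1=150, R2=3000, Q2=2e-6, n2=0.85,
                             R3=30_000, Q3=2e-5, n3=0.7, sigma_w=300)
        fit = fit_circuit(spectrum, init)
        for name in ("R1", "R2", "n2", "R3", "n3"):
            assert getattr(fit.params, name) == pytest.approx(
                getattr(TRUE_PARAMS, name), rel=0.05), name

    def test_pure_resistor_pins_elements_at_bounds(self):
        f = np.logspace(0, 3, 20)
        z = np.full(f.size, 1000.0, dtype=complex)
        spectrum = ImpedanceSpectrum(frequency=f, z_real=z.real, z_imag=z.imag)
        init = CircuitParams(R1=800, R2=100, Q2=1e-5, n2=0.9,
                             R3=100, Q3=1e-5, n3=0.8, sigma_w=10)
        with pytest.warns(UserWarning, match="bounds"):
            fit = fit_circuit(spectrum, init)
        total_r = fit.params.R1 + fit.params.R2 + fit.params.R3
        assert total_r == pytest.approx(1000.0, rel=0.02)
        assert fit.at_bounds

    def test_determinism_given_init(self):
        spectrum = _spectrum_from(TRUE_PARAMS, noise=0.01, seed=3)
        init = CircuitParams(R1=150, R2=3000, Q2=2e-6, n2=0.85,
                             R3=30_000, Q3=2e-5, n3=0.7, sigma_w=300)
        a, b = fit_circuit(spectrum, init), fit_circuit(spectrum, init)
        assert a.params == b.params

    def test_too_few_frequencies_rejected(self):
        f = np.logspace(0, 3, 5)
        z = circuit_impedance(TRUE_PARAMS, f)
        with pytest.raises(InputError):
            fit_circuit(ImpedanceSpectrum(f, z.real, z.imag), TRUE_PARAMS)


class TestSpectrumSummary:
    def test_published_percent_difference(self):
        """Mean |Z| 9,900.02 (reference) vs 13,875.70 -> 40.16%."""
        f = np.array([1.0, 10.0])
        a = ImpedanceSpectrum(f, np.full(2, 9_900.02), np.zeros(2))
        b = ImpedanceSpectrum(f, np.full(2, 13_875.70), np.zeros(2))
        cmpn = summarize_spectrum({"proteinoid": a, "complex": b})
        assert cmpn.percent_difference == pytest.approx(40.16, abs=0.005)

    def test_identical_spectra_zero_percent(self):
        f = np.logspace(0, 3, 12)
        z = circuit_impedance(TRUE_PARAMS, f)
        a = ImpedanceSpectrum(f, z.real, z.imag)
        b = ImpedanceSpectrum(f, z.real.copy(), z.imag.copy())
        assert summarize_spectrum({"x": a, "y": b}).percent_difference == \
            pytest.approx(0.0, abs=1e-12)

    def test_single_point_magnitude_and_phase(self):
        sp = ImpedanceSpectrum(np.array([1.0]), np.array([3.0]), np.array([4.0]))
        stats = summarize_spectrum({"s": sp}).per_label["s"]
        assert stats.mean_magnitude == pytest.approx(5.0)
        assert stats.mean_phase_deg == pytest.approx(53.13, abs=0.005)

    def test_empty_rejected(self):
        with pytest.raises(InputError):
            summarize_spectrum({})
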