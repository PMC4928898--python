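"""Cole equation evaluation, fitting, and frequency-band partitioning."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import bisqc as b
from bisqc.cole import Band, ColeFitError, ColeModel, cole_impedance


class TestEvaluate:
    def test_zero_frequency_limit_is_r0(self):
        p = b.ColeParameters(100, 20, 1.0, 1.0)
        assert cole_impedance(p, 0.0) == pytest.approx(100 + 0j)

    def test_characteristic_frequency_value(self):
        # at w = wc with alpha = 1: Z = 20 + 80/(1+j) = 60 - 40j
        p = b.ColeParameters(100, 20, 1.0, 1.0)
        assert cole_impedance(p, 1.0) == pytest.approx(60 - 40j)

    def test_polar_form_oracle(self):
        # independent complex arithmetic via explicit polar evaluation
        p = b.ColeParameters(100, 20, 0.7, 1e-5)
        w = 3e5
        mag = (w * p.tau) ** p.alpha
        phase = p.alpha * np.pi / 2
        denom = 1 + mag * np.cos(phase) + 1j * mag * np.sin(phase)
        expected = 20 + 80 / denom
        assert cole_impedance(p, w) == pytest.approx(expected, rel=1e-12)

    def test_high_frequency_limit_tends_to_rinf(self, cole_params):
        z = cole_impedance(cole_params, 1e9 * cole_params.omega_c)
        assert abs(z - cole_params.rinf) < 1e-3 * (cole_params.r0 - cole_params.rinf)

    def test_reactance_nonpositive_for_valid_alpha(self, log_grid):
        for alpha in (0.3, 0.65, 1.0):
            p = b.ColeParameters(500, 200, alpha, 1e-6)
            assert np.all(b.evaluate_cole(p, log_grid).z.imag <= 0)

    @pytest.mark.parametrize("kwargs", [
        dict(r0=10, rinf=20, alpha=0.7, tau=1e-5),   # R0 < Rinf
        dict(r0=100, rinf=20, alpha=0.0, tau=1e-5),  # alpha out of range
        dict(r0=100, rinf=20, alpha=1.2, tau=1e-5),
        dict(r0=100, rinf=20, alpha=0.7, tau=-1e-5),
        dict(r0=100, rinf=-5, alpha=0.7, tau=1e-5),
    ])
    def test_invalid_parameters_rejected(self, kwargs):
        with pytest.raises(ValueError):
            b.ColeParameters(**kwargs)


class TestBands:
    WC = 2 * np.pi * 40e3

    @pytest.mark.parametrize("ratio, band", [
        (0.199, Band.VLF),
        (0.2, Band.LF),      # left edge of LF inclusive
        (0.49, Band.LF),
        (0.5, Band.MF),
        (1.99, Band.MF),
        (2.0, Band.HF),
        (5.0, Band.HF),      # HF upper edge inclusive
        (5.0001, Band.VHF),
    ])
    def test_band_edges(self, ratio, band):
        assert b.band_of(ratio * self.WC, self.WC) is band

    @given(ratio=st.floats(min_value=1e-6, max_value=1e6),
           wc=st.floats(min_value=1e2, max_value=1e7))
    @settings(max_examples=200, deadline=None)
    def test_bands_partition_positive_frequencies(self, ratio, wc):
        # every positive frequency falls in exactly one band
        from bisqc.cole import band_masks
        omega = np.array([ratio * wc, ratio * wc * 1.0001])
        masks = band_masks(omega, wc)
        counts = sum(m.astype(int) for m in masks.values())
        assert np.all(counts == 1)
        assert b.band_of(ratio * wc, wc) in list(Band)

    def test_band_of_rejects_nonpositive(self):
        with pytest.raises(ValueError):
            b.band_of(0.0, self.WC)
        with pytest.raises(ValueError):
            b.band_of(self.WC, -1.0)


class TestFit:
    def test_exact_recovery_on_noiseless_data(self, cole_params, log_grid):
        res = ColeModel(b.evaluate_cole(cole_params, log_grid)).fit()
        for name in ("r0", "rinf", "alpha", "tau"):
            got, true = getattr(res.params, name), getattr(cole_params, name)
            assert abs(got - true) / true < 1e-3
        assert res.residual < 1e-6

    def test_recovery_under_mild_noise(self, cole_params, log_grid, rng):
        clean = b.evaluate_cole(cole_params, log_grid)
        r = clean.z.real * (1 + 0.001 * rng.standard_normal(50))
        x = clean.z.imag * (1 + 0.001 * rng.standard_normal(50))
        res = ColeModel(b.ComplexSpectrum(log_grid, r + 1j * x)).fit()
        for name in ("r0", "rinf", "alpha", "tau"):
            got, true = getattr(res.params, name), getattr(cole_params, name)
            assert abs(got - true) / true < 0.02

    def test_round_trip_random_parameters(self, log_grid, rng):
        for _ in range(10):
            r0 = rng.uniform(100, 900)
            p = b.ColeParameters(r0, r0 * rng.uniform(0.4, 0.8),
                                 rng.uniform(0.6, 0.95),
                                 1 / (2 * np.pi * rng.uniform(15e3, 90e3)))
            params, _ = b.fit_cole(b.evaluate_cole(p, log_grid))
            assert params.r0 == pytest.approx(p.r0, rel=1e-3)
            assert params.alpha == pytest.approx(p.alpha, rel=1e-3)
            assert params.tau == pytest.approx(p.tau, rel=1e-3)

    def test_scale_equivariance(self, cole_params, log_grid):
        spec = b.evaluate_cole(cole_params, log_grid)
        k = 3.7
        p1, _ = b.fit_cole(spec)
        p2, _ = b.fit_cole(spec.scaled(k))
        assert p2.r0 == pytest.approx(k * p1.r0, rel=1e-6)
        assert p2.rinf == pytest.approx(k * p1.rinf, rel=1e-6)
        assert p2.alpha == pytest.approx(p1.alpha, rel=1e-6)
        assert p2.tau == pytest.approx(p1.tau, rel=1e-6)

    def test_constant_spectrum_raises_fit_error(self, log_grid):
        spec = b.ComplexSpectrum(log_grid, np.full(50, 100 + 0j))
        with pytest.raises(ColeFitError):
            ColeModel(spec).fit()

    def test_too_few_points_rejected(self):
        spec = b.ComplexSpectrum(np.array([1.0, 2.0, 3.0]),
                                 np.array([5 - 1j, 4 - 2j, 3 - 1j]))
        with pytest.raises(ValueError):
            ColeModel(spec)

    def test_results_predict_and_summary(self, cole_params, log_grid):
        res = ColeModel(b.evaluate_cole(cole_params, log_grid)).fit()
        assert np.allclose(res.predict().z,
                           b.evaluate_cole(res.params, log_grid).z)
        assert "R0" in res.summary() and "fc" in res.summary()


class TestSpectrumValidation:
    def test_rejects_decreasing_omega(self):
        with pytest.raises(ValueError):
            b.ComplexSpectrum(np.array([2.0, 1.0]), np.array([1 + 0j, 1 + 0j]))

    def test_rejects_length_mismatch(self):
        with pytest.raises(ValueError):
            b.ComplexSpectrum(np.array([1.0, 2.0]), np.array([1 + 0j]))
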