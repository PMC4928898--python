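"""Synthetic spectrum generator: parameter sampling, artifact templates."""

import numpy as np
import pytest

import bisqc as b
from bisqc.classes import ErrorClass
from bisqc.cole import ColeModel
from bisqc.synth import (DEFAULT_PROFILES, GeneratorConfig, _uniform,
                         default_frequency_grid, generate_dataset,
                         inject_error, sample_cole_params)


class TestParameterSampling:
    def test_draws_respect_invariants(self, rng):
        prof = DEFAULT_PROFILES["body_composition"]
        for _ in range(1000):
            p = sample_cole_params(prof, rng)
            assert p.r0 > p.rinf > 0
            assert 0 < p.alpha <= 1 and p.tau > 0
            assert prof.r0[0] <= p.r0 <= prof.r0[1]

    def test_fixed_seed_reproducibility(self):
        prof = DEFAULT_PROFILES["cerebral"]
        a = sample_cole_params(prof, np.random.default_rng(5))
        c = sample_cole_params(prof, np.random.default_rng(5))
        assert a == c


class TestInjectors:
    @pytest.fixture()
    def setup(self):
        cfg = GeneratorConfig(rng_seed=7)
        rng = np.random.default_rng(7)
        return cfg, rng, cfg.omega

    def _draw(self, cfg, rng, error_type):
        prof = cfg.profiles[sorted(cfg.profiles)[rng.integers(3)]]
        p = sample_cole_params(prof, rng)
        clean = b.evaluate_cole(p, cfg.omega)
        s = _uniform(rng, cfg.severity_ranges[error_type])
        return p, clean, inject_error(clean, error_type, s, p), s

    def test_clean_is_identity(self, setup, cole_params):
        cfg, rng, omega = setup
        clean = b.evaluate_cole(cole_params, omega)
        assert inject_error(clean, ErrorClass.CLEAN, 0.0, cole_params) is clean

    def test_unknown_severity_sign_rejected(self, setup, cole_params):
        cfg, rng, omega = setup
        clean = b.evaluate_cole(cole_params, omega)
        with pytest.raises(ValueError):
            inject_error(clean, ErrorClass.TYPE_A, -0.1, cole_params)

    @pytest.mark.parametrize("error_type", [
        ErrorClass.TYPE_A, ErrorClass.TYPE_B, ErrorClass.TYPE_C,
        ErrorClass.TYPE_D, ErrorClass.TYPE_E, ErrorClass.TYPE_F,
    ])
    def test_signature_predicates(self, setup, error_type):
        cfg, rng, omega = setup
        noise = cfg.noise_sd
        hits = 0
        n = 100
        for _ in range(n):
            p, clean, m, s = self._draw(cfg, rng, error_type)
            x, r = m.z.imag, m.z.real
            xc = clean.z.imag
            if error_type is ErrorClass.TYPE_A:
                # hook: reactance decrement already present at 2 wc
                w2 = 2 * p.omega_c
                xm2 = np.interp(w2, omega, x)
                xc2 = np.interp(w2, omega, xc)
                good = xm2 < xc2 - 3 * noise * abs(xc2) and x[-1] < 0
            elif error_type is ErrorClass.TYPE_B:
                below = omega < 6 * p.omega_c
                good = (np.allclose(m.z[below], clean.z[below])
                        and abs(m.z[-1] - clean.z[-1])
                        > 3 * noise * abs(clean.z[-1]))
            elif error_type is ErrorClass.TYPE_C:
                hf = (omega >= 2 * p.omega_c) & (omega <= 5 * p.omega_c)
                good = hf.any() and np.all(
                    np.abs(m.z[hf] - clean.z[hf])
                    > 3 * noise * np.abs(clean.z[hf]))
            elif error_type is ErrorClass.TYPE_D:
                good = (np.all(x <= 1e-9) and np.any(np.diff(r) > 0)
                        and r[-1] > r[:-1].min())
            elif error_type is ErrorClass.TYPE_E:
                good = x[-1] > 0 and np.all(np.diff(r) < 0)
            else:  # TYPE_F
                good = x[-1] > 0 and np.any(np.diff(r) > 0)
            hits += bool(good)
        assert hits >= 0.99 * n


class TestGenerateDataset:
    def test_default_counts_and_labels(self, benchmark):
        coll, _ = benchmark
        assert len(coll) == 700
        labels = coll.labels
        for c in ErrorClass:
            assert np.sum(labels == int(c)) == 100

    def test_same_seed_identical_dataset(self):
        cfg = GeneratorConfig(rng_seed=12,
                              class_counts={c: 3 for c in ErrorClass})
        a, c = generate_dataset(cfg), generate_dataset(cfg)
        for sa, sc in zip(a.samples, c.samples):
            assert np.array_equal(sa.spectrum.z, sc.spectrum.z)
            assert sa.label == sc.label and sa.severity == sc.severity

    def test_samples_carry_ground_truth(self, mini):
        coll, _ = mini
        for s in coll.samples:
            assert s.params is not None and s.profile in DEFAULT_PROFILES
            if s.label is ErrorClass.CLEAN:
                assert s.severity == 0.0

    def test_clean_fit_residual_below_noise_bound(self, mini):
        coll, _ = mini
        cfg = GeneratorConfig()
        res = [ColeModel(s.spectrum).fit().rms_relative_residual
               for s in coll.samples if s.label is ErrorClass.CLEAN]
        assert np.median(res) < 3 * cfg.noise_sd

    def test_artifacts_exceed_clean_residual_distribution(self, mini):
        coll, _ = mini
        cfg = GeneratorConfig()
        by_class = {c: [] for c in ErrorClass}
        sev = {c: [] for c in ErrorClass}
        for s in coll.samples:
            by_class[s.label].append(
                ColeModel(s.spectrum).fit().rms_relative_residual)
            sev[s.label].append(s.severity)
        clean95 = np.percentile(by_class[ErrorClass.CLEAN], 95)
        for c in ErrorClass:
            if c is ErrorClass.CLEAN:
                continue
            lo, hi = cfg.severity_ranges[c]
            upper = [r for r, s in zip(by_class[c], sev[c])
                     if s >= (lo + hi) / 2]
            assert upper and np.mean(np.array(upper) > clean95) >= 0.95


class TestConfigValidation:
    def test_grid_is_log_spaced_default(self):
        grid = default_frequency_grid()
        assert len(grid) == 50
        assert grid[0] == pytest.approx(5e3) and grid[-1] == pytest.approx(1e6)
        assert np.allclose(np.diff(np.log(grid)), np.diff(np.log(grid))[0])

    def test_invalid_settings_rejected(self):
        with pytest.raises(ValueError):
            GeneratorConfig(noise_sd=-0.1)
        with pytest.raises(ValueError):
            GeneratorConfig(freq_hz=np.array([2.0, 1.0]))
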