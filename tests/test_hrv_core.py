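"""Tests for the HRV index chain: resampling, detrending, Burg AR, PSD,
band powers, and the algebraic identities tying them together."""

import numpy as np
import pytest
from scipy import signal as sps

from hrvdbs import hrv_core
from hrvdbs import synthetic_data as sd
from hrvdbs.ecg_rr import RRISeries
from hrvdbs.hrv_core import ARModel, BandDefinition, UniformSeries


class TestTimeDomain:
    def test_constant_series(self, constant_rr):
        mrri, sdnn = hrv_core.time_domain_indices(constant_rr)
        assert mrri == 1000.0
        assert sdnn == 0.0

    def test_hand_computed(self):
        rr = RRISeries(np.array([0.0, 0.8, 1.8, 3.0]), np.array([800.0, 1000.0, 1200.0]))
        mrri, sdnn = hrv_core.time_domain_indices(rr)
        assert mrri == pytest.approx(1000.0)
        assert sdnn == pytest.approx(200.0)  # n-1 denominator

    def test_ipfm_mean_recovered(self):
        params = sd.IPFMParams(base_interval_T0=0.9, seed=3)
        rr = sd.simulate_rr_ipfm(params, 300.0)
        mrri, _ = hrv_core.time_domain_indices(rr)
        assert mrri == pytest.approx(900.0, rel=0.02)

    def test_too_few_intervals(self):
        rr = RRISeries(np.array([0.0, 1.0]), np.array([1000.0]))
        with pytest.raises(ValueError):
            hrv_core.time_domain_indices(rr)


class TestResample:
    def test_constant_reproduced(self, constant_rr):
        u = hrv_core.resample_cubic_spline(constant_rr)
        np.testing.assert_allclose(u.values, 1000.0)
        assert u.sampling_rate == 4.0

    def test_linear_trend_reproduced(self):
        beats = np.cumsum(np.linspace(0.9, 1.1, 60))
        times = np.concatenate([[0.0], beats])
        values = 900.0 + 3.0 * times[1:]  # linear in anchor time
        rr = RRISeries(times, values)
        u = hrv_core.resample_cubic_spline(rr)
        # cubic spline reproduces degree-1 polynomials exactly
        np.testing.assert_allclose(u.values, 900.0 + 3.0 * u.times, atol=1e-8)

    def test_sinusoid_frequency_preserved(self):
        t = np.arange(0.0, 120.0)
        rr = RRISeries(
            np.concatenate([[-1.0], t]), 1000.0 + 100.0 * np.sin(2 * np.pi * 0.1 * t)
        )
        u = hrv_core.resample_cubic_spline(rr)
        f, p = sps.periodogram(u.values - u.values.mean(), fs=4.0)
        assert f[np.argmax(p)] == pytest.approx(0.1, abs=f[1] - f[0])

    def test_window_length_contract(self, modulated_rr):
        u = hrv_core.resample_cubic_spline(
            modulated_rr, start=modulated_rr.beat_times[1],
            end=modulated_rr.beat_times[1] + 180.0,
        )
        assert len(u) == 720  # 180 s at 4 Hz

    def test_too_few_beats(self):
        rr = RRISeries.from_beat_times(np.array([0.0, 1.0, 2.0]))
        with pytest.raises(ValueError):
            hrv_core.resample_cubic_spline(rr)


class TestDetrend:
    def test_zero_input(self):
        u = UniformSeries(np.zeros(100))
        out = hrv_core.detrend_smoothness_priors(u)
        np.testing.assert_array_equal(out.values, 0.0)

    def test_lambda_zero_identity_smoother(self):
        u = UniformSeries(np.sin(np.arange(100)))
        out = hrv_core.detrend_smoothness_priors(u, lam=0.0)
        np.testing.assert_array_equal(out.values, 0.0)

    def test_negative_lambda(self):
        with pytest.raises(ValueError):
            hrv_core.detrend_smoothness_priors(UniformSeries(np.zeros(10)), lam=-1.0)

    @pytest.mark.parametrize(
        "freq,check",
        [(0.01, lambda r: r <= 0.10), (0.10, lambda r: r >= 0.90)],
    )
    def test_frequency_response(self, freq, check):
        """Oracle: apply the operator to pure tones, measure amplitude ratio."""
        n = 2400  # 600 s at 4 Hz
        t = np.arange(n) / 4.0
        tone = np.sin(2 * np.pi * freq * t)
        out = hrv_core.detrend_smoothness_priors(UniformSeries(tone), lam=500.0)
        mid = slice(n // 4, 3 * n // 4)
        ratio = np.sqrt(np.mean(out.values[mid] ** 2) / np.mean(tone[mid] ** 2))
        assert check(ratio)

    def test_transfer_monotone_below_passband(self):
        n = 2400
        t = np.arange(n) / 4.0
        mid = slice(n // 4, 3 * n // 4)
        ratios = []
        for freq in (0.005, 0.01, 0.02, 0.04):
            tone = np.sin(2 * np.pi * freq * t)
            out = hrv_core.detrend_smoothness_priors(UniformSeries(tone), lam=500.0)
            ratios.append(np.sqrt(np.mean(out.values[mid] ** 2)))
        assert all(a < b for a, b in zip(ratios, ratios[1:]))


class TestBurg:
    def test_ar2_recovery(self, rng):
        """Oracle: the known simulation coefficients at large n."""
        n = 2000
        x = np.zeros(n + 200)
        e = rng.standard_normal(n + 200)
        for t in range(2, n + 200):
            x[t] = 1.0 * x[t - 1] - 0.5 * x[t - 2] + e[t]
        model = hrv_core.burg_fit(x[200:], order=2)
        assert model.coefficients[0] == pytest.approx(-1.0, abs=0.05)
        assert model.coefficients[1] == pytest.approx(0.5, abs=0.05)

    def test_white_noise_small_reflections(self, rng):
        exceed = 0
        total = 0
        for _ in range(100):
            x = rng.standard_normal(720)
            model = hrv_core.burg_fit(x, order=19)
            exceed += int(np.count_nonzero(np.abs(model.reflection_coefficients) >= 0.2))
            total += 19
        assert exceed / total <= 0.05

    def test_sinusoid_peak_location(self, rng):
        t = np.arange(720) / 4.0
        x = np.sin(2 * np.pi * 0.25 * t) + 0.01 * rng.standard_normal(720)
        model = hrv_core.burg_fit(x - x.mean(), order=19)
        psd = hrv_core.ar_psd(model, fs=4.0)
        peak = psd.frequencies[np.argmax(psd.density)]
        assert peak == pytest.approx(0.25, abs=2 * (psd.frequencies[1] - psd.frequencies[0]))

    def test_constant_input_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            hrv_core.burg_fit(np.ones(100), order=4)

    def test_order_precondition(self):
        with pytest.raises(ValueError):
            hrv_core.burg_fit(np.random.default_rng(0).standard_normal(30), order=19)


class TestARPSD:
    def test_order_zero_flat(self):
        model = ARModel(coefficients=np.empty(0), innovation_variance=3.0)
        psd = hrv_core.ar_psd(model, fs=4.0)
        np.testing.assert_allclose(psd.density, 2.0 * 3.0 / 4.0)

    def test_variance_identity_vs_simulation(self, rng):
        """Oracle: variance of a long simulated realization of the model."""
        coeffs = np.array([-0.6, 0.2])
        model = ARModel(coefficients=coeffs, innovation_variance=1.0)
        n = 200_000
        e = rng.standard_normal(n)
        x = sps.lfilter([1.0], np.concatenate([[1.0], coeffs]), e)
        psd = hrv_core.ar_psd(model, fs=4.0)
        integral = np.trapezoid(psd.density, psd.frequencies)
        assert integral == pytest.approx(np.var(x[1000:]), rel=0.05)

    def test_ar1_lowpass_monotone(self):
        model = ARModel(coefficients=np.array([-0.9]), innovation_variance=1.0)
        psd = hrv_core.ar_psd(model, fs=4.0)
        assert np.all(np.diff(psd.density) < 0)


class TestBandPower:
    def _flat_psd(self, c=5.0):
        f = np.linspace(0, 2.0, 4097)[1:]
        return hrv_core.PSDEstimate(f, np.full(f.size, c))

    def test_flat_rectangle(self):
        psd = self._flat_psd(5.0)
        assert hrv_core.band_power(psd, (0.04, 0.4)) == pytest.approx(0.36 * 5.0)

    def test_band_additivity_exact(self, rng):
        f = np.linspace(0, 2.0, 4097)[1:]
        psd = hrv_core.PSDEstimate(f, rng.uniform(0.5, 2.0, f.size))
        lf = hrv_core.band_power(psd, (0.04, 0.15))
        hf = hrv_core.band_power(psd, (0.15, 0.4))
        tp = hrv_core.band_power(psd, (0.04, 0.4))
        assert lf + hf == pytest.approx(tp, abs=1e-12)

    def test_narrowband_tone_in_hf(self, rng):
        t = np.arange(720) / 4.0
        x = 50.0 * np.sin(2 * np.pi * 0.275 * t) + rng.standard_normal(720)
        model = hrv_core.burg_fit(x - x.mean(), order=19)
        psd = hrv_core.ar_psd(model, fs=4.0)
        hf = hrv_core.band_power(psd, (0.15, 0.4))
        tp = hrv_core.band_power(psd, (0.04, 0.4))
        assert hf / tp >= 0.80

    def test_inverted_band_rejected(self):
        with pytest.raises(ValueError):
            hrv_core.band_power(self._flat_psd(), (0.4, 0.15))


class TestFrequencyDomainIndices:
    def test_normalization_identity_exact(self, modulated_rr):
        fd = hrv_core.frequency_domain_indices(modulated_rr)
        assert fd["nLF"] + fd["nHF"] == 100.0

    def test_hf_only_modulation(self):
        vals = []
        for seed in range(10):
            params = sd.IPFMParams(a_LF=0.0, a_HF=0.08, noise_sd=0.005, seed=seed)
            rr = sd.simulate_rr_ipfm(params, 200.0)
            fd = hrv_core.frequency_domain_indices(rr)
            vals.append(fd["nHF"])
        assert np.mean(vals) > 80.0

    def test_band_definition_validation(self):
        with pytest.raises(ValueError):
            BandDefinition(lf=(0.04, 0.12), hf=(0.15, 0.4))

    def test_scale_equivariance(self, modulated_rr):
        """x -> c*x scales mRRI/SDNN by c, powers by c^2, ratios unchanged."""
        c = 1.7
        scaled = RRISeries(
            modulated_rr.beat_times, modulated_rr.intervals * c, modulated_rr.flags
        )
        a = hrv_core.compute_indices(modulated_rr)
        b = hrv_core.compute_indices(scaled)
        assert b.mRRI == pytest.approx(c * a.mRRI, rel=1e-9)
        assert b.SDNN == pytest.approx(c * a.SDNN, rel=1e-9)
        for name in ("TP", "LF", "HF"):
            assert getattr(b, name) == pytest.approx(c**2 * getattr(a, name), rel=1e-6)
        assert b.nLF == pytest.approx(a.nLF, rel=1e-6)
        assert b.LF_HF == pytest.approx(a.LF_HF, rel=1e-6)

    def test_tp_equals_lf_plus_hf(self, modulated_rr):
        fd = hrv_core.frequency_domain_indices(modulated_rr)
        assert fd["TP"] == pytest.approx(fd["LF"] + fd["HF"], abs=1e-9)

    def test_lfhf_ratio_recovered(self):
        """Oracle target 2.0 via calibrated amplitudes; 3-min estimates."""
        a_lf, a_hf = sd.amplitudes_for_band_ratio(2.0)
        vals = []
        for seed in range(10):
            params = sd.IPFMParams(a_LF=a_lf, a_HF=a_hf, noise_sd=0.005, seed=seed)
            rr = sd.simulate_rr_ipfm(params, 200.0)
            s = rr.beat_times[1]
            fd = hrv_core.frequency_domain_indices(rr, start=s, end=s + 180.0)
            vals.append(fd["LF_HF"])
        assert 1.6 <= np.mean(vals) <= 2.4
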