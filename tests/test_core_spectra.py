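"""Core spectral estimators: periodograms, smoothing, normalization, filters."""

import numpy as np
import pytest

from ecotimescale.core_spectra import (
    TimeSeries,
    bandstop_filter,
    batch_spectral_exponents,
    cross_periodogram,
    daniell_smooth,
    fourier_frequencies,
    harmonic_fit,
    normalize_cospectrum,
    normalize_spectrum,
    partition_correlation,
    periodogram,
    smooth_spectrum,
    spectral_exponent,
)


class TestPeriodogram:
    def test_pure_cosine_concentrates_at_signal_frequency(self):
        n = 64
        x = np.cos(2 * np.pi * np.arange(n) / 4.0)
        s = periodogram(TimeSeries(x))
        k = np.argmin(np.abs(s.freqs - 0.25))
        assert s.power[k] == pytest.approx(s.power.sum(), rel=1e-10)
        off = np.delete(s.power, k)
        assert np.all(off < 1e-10)

    def test_constant_series_raises(self):
        with pytest.raises(ValueError, match="degenerate"):
            periodogram(TimeSeries(np.full(32, 3.0)))

    def test_too_short_raises(self):
        with pytest.raises(ValueError, match="at least"):
            periodogram(TimeSeries(np.arange(5.0)))

    @pytest.mark.parametrize("seed,n", [(0, 64), (1, 101), (2, 140)])
    def test_parseval_sum_equals_centered_sum_of_squares(self, seed, n):
        x = np.random.default_rng(seed).standard_normal(n)
        s = periodogram(TimeSeries(x))
        assert s.power.sum() == pytest.approx(((x - x.mean()) ** 2).sum(),
                                              rel=1e-10)

    def test_ar1_low_high_frequency_ratio_matches_theory(self):
        # AR(1) spectrum: sigma^2 / (1 - 2 phi cos 2 pi f + phi^2)
        phi, n = 0.8, 4096
        rng = np.random.default_rng(3)
        e = rng.standard_normal(n + 500)
        x = np.empty_like(e)
        x[0] = e[0]
        for t in range(1, e.size):
            x[t] = phi * x[t - 1] + e[t]
        x = x[500:]
        s = periodogram(TimeSeries(x))
        m = s.freqs.size
        dec = m // 10
        theory = 1.0 / (1 - 2 * phi * np.cos(2 * np.pi * s.freqs) + phi ** 2)
        ratio_obs = s.power[:dec].mean() / s.power[-dec:].mean()
        ratio_th = theory[:dec].mean() / theory[-dec:].mean()
        assert ratio_obs == pytest.approx(ratio_th, rel=0.10)


class TestCrossPeriodogram:
    def test_self_cross_spectrum_is_periodogram(self):
        x = np.random.default_rng(0).standard_normal(100)
        ts = TimeSeries(x)
        cs = cross_periodogram(ts, ts)
        np.testing.assert_allclose(cs.cospectrum, periodogram(ts).power,
                                   rtol=1e-10)
        np.testing.assert_allclose(cs.quadrature, 0.0, atol=1e-9)

    def test_negated_series_flips_cospectrum(self):
        x = np.random.default_rng(1).standard_normal(100)
        cs = cross_periodogram(TimeSeries(x), TimeSeries(-x))
        np.testing.assert_allclose(cs.cospectrum,
                                   -periodogram(TimeSeries(x)).power,
                                   rtol=1e-10)

    def test_quarter_period_shift_moves_covariance_to_quadrature(self):
        n = 64
        t = np.arange(n)
        x = np.cos(2 * np.pi * t / 8.0)
        y = np.cos(2 * np.pi * (t - 2) / 8.0)      # quarter of an 8-sample period
        cs = cross_periodogram(TimeSeries(x), TimeSeries(y))
        k = np.argmin(np.abs(cs.freqs - 1 / 8))
        assert abs(cs.cospectrum[k]) < 1e-9
        assert abs(cs.quadrature[k]) > 1.0

    def test_length_mismatch_raises(self):
        with pytest.raises(ValueError, match="mismatch"):
            cross_periodogram(TimeSeries(np.arange(10.) % 3),
                              TimeSeries(np.arange(12.) % 3))


class TestDaniellSmooth:
    def test_constant_preserved(self):
        np.testing.assert_allclose(daniell_smooth(np.full(40, 2.5)), 2.5)

    def test_impulse_matches_brute_force_double_convolution(self):
        # interior kernel = convolution of the 5- and 7-point boxcars
        x = np.zeros(31)
        x[15] = 1.0
        got = daniell_smooth(x, spans=(5, 7))
        oracle = np.convolve(np.convolve(x, np.ones(5) / 5, mode="same"),
                             np.ones(7) / 7, mode="same")
        np.testing.assert_allclose(got[5:-5], oracle[5:-5], rtol=1e-12)
        assert got.sum() == pytest.approx(1.0, abs=1e-9)  # impulse far from edges

    def test_linear_ramp_interior_unchanged(self):
        x = np.arange(30, dtype=float)
        got = daniell_smooth(x, spans=(5, 7))
        np.testing.assert_allclose(got[5:-5], x[5:-5], rtol=1e-12)

    def test_even_span_rejected(self):
        with pytest.raises(ValueError, match="odd"):
            daniell_smooth(np.ones(20), spans=(4,))


class TestNormalization:
    def test_normalized_spectrum_sums_to_one(self):
        x = np.random.default_rng(0).standard_normal(140)
        s = normalize_spectrum(smooth_spectrum(periodogram(TimeSeries(x))))
        assert s.power.sum() == pytest.approx(1.0, abs=1e-9)

    def test_flat_spectrum_normalizes_to_uniform(self):
        from ecotimescale.core_spectra import SpectrumEstimate
        m = 25
        s = SpectrumEstimate(freqs=fourier_frequencies(50), power=np.full(m, 7.0))
        np.testing.assert_allclose(normalize_spectrum(s).power, 1.0 / m)

    @pytest.mark.parametrize("seed", range(5))
    def test_normalized_cospectrum_sums_to_pearson_r(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.standard_normal(140)
        y = 0.5 * x + rng.standard_normal(140)
        r = np.corrcoef(x, y)[0, 1]
        cs = normalize_cospectrum(cross_periodogram(TimeSeries(x),
                                                    TimeSeries(y)), r)
        assert cs.cospectrum.sum() == pytest.approx(r, abs=1e-6)

    def test_independent_white_noise_total_near_zero(self):
        rng = np.random.default_rng(7)
        x, y = rng.standard_normal((2, 10_000))
        r = np.corrcoef(x, y)[0, 1]
        cs = normalize_cospectrum(cross_periodogram(TimeSeries(x),
                                                    TimeSeries(y)), r)
        assert abs(cs.cospectrum.sum()) < 0.05     # 2/sqrt(n) sampling bound


class TestPartition:
    def _normalized_cross(self, x, y):
        r = np.corrcoef(x, y)[0, 1]
        return normalize_cospectrum(cross_periodogram(TimeSeries(x),
                                                      TimeSeries(y)), r), r

    def test_single_band_recovers_total(self):
        rng = np.random.default_rng(0)
        x = rng.standard_normal(140)
        y = x + rng.standard_normal(140)
        cs, r = self._normalized_cross(x, y)
        part = partition_correlation(cs, timescale_edges=(2.5,))
        assert part.band_correlations.sum() == pytest.approx(part.total,
                                                             abs=1e-12)
        assert part.total == pytest.approx(r, abs=1e-6)

    def test_bands_tile_grid_and_sum_exactly(self):
        rng = np.random.default_rng(1)
        x = rng.standard_normal(140)
        y = 0.7 * x + rng.standard_normal(140)
        cs, _ = self._normalized_cross(x, y)
        part = partition_correlation(cs, timescale_edges=(12.0, 4.0))
        assert part.band_correlations.sum() == pytest.approx(part.total,
                                                             abs=1e-12)
        assert len(part.band_correlations) == 3

    def test_band_limited_correlation_lands_in_low_band(self):
        # shared signal strictly below f = 1/12; independent noise above
        rng = np.random.default_rng(2)
        n = 480
        m = n // 2

        def bandpass(mask_lo, mask_hi):
            X = np.zeros(m + 1, dtype=complex)
            k = np.arange(m + 1)
            sel = (k / n >= mask_lo) & (k / n < mask_hi) & (k > 0)
            X[sel] = rng.standard_normal(sel.sum()) + \
                1j * rng.standard_normal(sel.sum())
            return np.fft.irfft(X, n)

        shared = bandpass(0.0, 1 / 12)
        x = shared + 0.3 * bandpass(1 / 12, 0.5)
        y = shared + 0.3 * bandpass(1 / 12, 0.5)
        cs, _ = self._normalized_cross(x, y)
        part = partition_correlation(cs, timescale_edges=(12.0, 4.0))
        assert part.band_correlations[0] >= 0.9 * part.total


class TestSpectralExponent:
    @pytest.mark.parametrize("p,c", [(1.0, 2.0), (0.0, 3.5), (-1.0, 1.0)])
    def test_power_law_recovered_exactly(self, p, c):
        from ecotimescale.core_spectra import SpectrumEstimate
        f = fourier_frequencies(100)
        s = SpectrumEstimate(freqs=f, power=c * f ** p)
        assert spectral_exponent(s).slope == pytest.approx(p, abs=1e-12)

    def test_mostly_zero_power_raises(self):
        from ecotimescale.core_spectra import SpectrumEstimate
        f = fourier_frequencies(40)
        power = np.zeros_like(f)
        power[:3] = 1.0
        with pytest.raises(ValueError, match="zero spectral power"):
            spectral_exponent(SpectrumEstimate(freqs=f, power=power))

    def test_few_zero_powers_excluded_with_warning(self):
        from ecotimescale.core_spectra import SpectrumEstimate
        f = fourier_frequencies(100)
        power = 2.0 * f
        power[-1] = 0.0
        with pytest.warns(RuntimeWarning, match="excluding"):
            e = spectral_exponent(SpectrumEstimate(freqs=f, power=power))
        assert e.slope == pytest.approx(1.0, abs=1e-12)
        assert e.n_freqs == f.size - 1

    def test_batch_matches_scalar_path(self):
        rng = np.random.default_rng(0)
        X = rng.standard_normal((4, 100))
        batch = batch_spectral_exponents(X)
        for i, row in enumerate(X):
            s = normalize_spectrum(periodogram(TimeSeries(row)))
            assert batch[i] == pytest.approx(spectral_exponent(s).slope,
                                             abs=1e-10)


class TestBandstopFilter:
    t = np.arange(480, dtype=float)

    def _amplitude(self, y):
        return np.sqrt(2) * y[120:360].std()

    def test_annual_cycle_attenuated_20db(self):
        y = bandstop_filter(TimeSeries(np.sin(2 * np.pi * self.t / 12)),
                            (9, 15)).values
        assert self._amplitude(y) <= 0.1

    @pytest.mark.parametrize("period", [6.0, 36.0])
    def test_pass_band_amplitude_preserved(self, period):
        y = bandstop_filter(TimeSeries(np.sin(2 * np.pi * self.t / period)),
                            (9, 15)).values
        assert self._amplitude(y) >= 0.95

    def test_zero_series_maps_to_zero(self):
        y = bandstop_filter(TimeSeries(np.zeros(480)), (9, 15)).values
        np.testing.assert_allclose(y, 0.0, atol=1e-12)

    def test_unrepresentable_stop_band_raises(self):
        with pytest.raises(ValueError, match="representable"):
            bandstop_filter(TimeSeries(np.random.default_rng(0)
                                       .standard_normal(480)), (1.2, 1.9))


class TestHarmonicFit:
    def test_recovers_annual_and_semiannual_amplitudes(self):
        rng = np.random.default_rng(0)
        t = np.arange(140, dtype=float)
        y = 10 + 8 * np.cos(2 * np.pi * t / 12) + 2 * np.cos(2 * np.pi * t / 6) \
            + 0.1 * rng.standard_normal(140)
        fit = harmonic_fit(TimeSeries(y))
        assert fit.amplitudes[0] == pytest.approx(8.0, rel=0.05)
        assert fit.amplitudes[1] == pytest.approx(2.0, rel=0.05)
        assert fit.rss_full <= fit.rss_reduced

    def test_pure_annual_signal_gives_nonsignificant_semiannual(self):
        rng = np.random.default_rng(1)
        t = np.arange(140, dtype=float)
        y = 5 + 3 * np.cos(2 * np.pi * t / 12) + 0.1 * rng.standard_normal(140)
        fit = harmonic_fit(TimeSeries(y))
        assert fit.amplitudes[1] < 0.1
        assert fit.p_value > 0.05

    def test_noiseless_two_harmonic_signal_has_zero_residual(self):
        t = np.arange(140, dtype=float)
        y = 1 + np.cos(2 * np.pi * t / 12) + 0.5 * np.sin(2 * np.pi * t / 6)
        fit = harmonic_fit(TimeSeries(y))
        assert fit.rss_full == pytest.approx(0.0, abs=1e-18)
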