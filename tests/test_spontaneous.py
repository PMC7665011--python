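"""Spontaneous-activity estimators: segment selection, two-Gaussian histogram
amplitude, spectral frequency, and their invariances."""

import dataclasses

import numpy as np
import pytest

import myotrace as mt
from myotrace import spontaneous as sp
from myotrace.errors import (DegenerateHistogramError, DomainError,
                             NoDominantRhythmError, NonStationaryError,
                             NormalizationError, ResolutionError, StageError)
from myotrace.trace_model import EventLog, TensionTrace


class TestStationarySegment:
    def test_drift_free_trace_gives_full_eligible_extent(self,
                                                         noiseless_control_bundle):
        b = noiseless_control_bundle
        seg = mt.select_stationary_segment(b.trace, b.events,
                                           slope_tol_mN_per_min=0.1)
        # eligible region starts after the KCl washout margin
        assert seg[0] == pytest.approx(330.0, abs=1.0)
        assert seg[1] == pytest.approx(1800.0, abs=1.0)

    def test_global_drift_rejected(self, noiseless_control_params):
        p = dataclasses.replace(noiseless_control_params, drift_mN_per_min=0.5)
        b = mt.simulate_strip(p, 1800.0, 10.0)
        with pytest.raises(NonStationaryError):
            mt.select_stationary_segment(b.trace, b.events,
                                         slope_tol_mN_per_min=0.1)

    def test_drift_then_flat_found_in_flat_half(self):
        """Piecewise trace: the selected run must live in the flat half.

        Oracle: brute-force check that every window inside the returned
        segment has lower-envelope slope below tolerance.
        """
        rate = 10.0
        t = np.arange(0, 2400, 1 / rate)
        x = 5.0 + np.where(t < 1200, 0.5 / 60.0 * (t - 1200), 0.0)
        trace = TensionTrace(samples=x, sampling_rate=rate)
        seg = mt.select_stationary_segment(trace, None, slope_tol_mN_per_min=0.1)
        assert seg[0] >= 1140.0  # at most one window straddles the knee
        assert seg[1] == pytest.approx(2400.0, abs=1.0)
        # brute force over 60 s windows every 10 s inside the segment
        for start in np.arange(seg[0], seg[1] - 60.0, 10.0):
            w0 = trace.slice(start, start + 60.0)
            w1 = trace.slice(start + 10.0, start + 70.0)
            slope = (np.percentile(w1, 10) - np.percentile(w0, 10)) / 10.0
            assert abs(slope) < 0.1 / 60.0 + 1e-12

    def test_too_short_trace_rejected(self):
        trace = TensionTrace(samples=np.full(1000, 5.0), sampling_rate=10.0)
        with pytest.raises(NonStationaryError):
            mt.select_stationary_segment(trace, None, min_len_s=300.0)


class TestAmplitudeHistogram:
    def test_counts_sum_to_sample_count(self):
        x = np.random.default_rng(1).normal(size=5000)
        h = mt.amplitude_histogram(x)
        assert h.counts.sum() == 5000
        assert sp.MIN_BINS <= h.centers.size <= sp.MAX_BINS

    def test_constant_segment_degenerate(self):
        with pytest.raises(DegenerateHistogramError):
            mt.amplitude_histogram(np.full(1000, 3.3))

    def test_too_few_samples_degenerate(self):
        with pytest.raises(DegenerateHistogramError):
            mt.amplitude_histogram(np.arange(50.0))

    def test_two_valued_input_occupies_two_bins(self):
        x = np.tile([1.0, 2.0], 500)
        h = mt.amplitude_histogram(x, n_bins=40)
        nz = h.counts[h.counts > 0]
        assert nz.size == 2
        assert set(nz) == {500.0}


class TestTwoGaussianFit:
    def test_labeled_mixture_distance_recovered(self):
        """Sample-mean oracle: the fitted mean separation matches the
        separation of the labeled component sample means within 0.02."""
        rng = np.random.default_rng(42)
        a = rng.normal(0.0, 0.1, 50_000)
        b = rng.normal(1.0, 0.1, 50_000)
        oracle = b.mean() - a.mean()
        h = mt.amplitude_histogram(np.concatenate([a, b]))
        fit = mt.fit_two_gaussians(h)
        assert not fit.unimodal
        assert fit.mu2 - fit.mu1 == pytest.approx(oracle, abs=0.02)
        assert fit.sd1 == pytest.approx(0.1, rel=0.1)

    def test_single_gaussian_flagged_unimodal(self):
        x = np.random.default_rng(3).normal(2.0, 0.5, 20_000)
        fit = mt.fit_two_gaussians(mt.amplitude_histogram(x))
        assert fit.unimodal

    def test_bin_order_invariance(self):
        rng = np.random.default_rng(4)
        h = mt.amplitude_histogram(np.concatenate(
            [rng.normal(0, 0.1, 5000), rng.normal(1, 0.1, 5000)]))
        fit = mt.fit_two_gaussians(h)
        perm = np.random.default_rng(5).permutation(h.centers.size)
        h2 = sp.Histogram(centers=h.centers[perm], counts=h.counts[perm],
                          bin_width=h.bin_width)
        fit2 = mt.fit_two_gaussians(h2)
        assert fit2.mu1 == pytest.approx(fit.mu1, abs=1e-6)
        assert fit2.mu2 == pytest.approx(fit.mu2, abs=1e-6)


class TestEstimateAsc:
    def test_definition(self):
        fit = sp.GaussFit(mu1=5.0, mu2=5.0 + 0.046 * 10.0, sd1=0.01, sd2=0.01,
                          w1=1, w2=1, fit_residual=0.0)
        assert mt.estimate_asc(fit, kcl_amp=10.0) == pytest.approx(4.6)

    def test_gain_invariance(self):
        for g in (0.5, 3.0):
            fit = sp.GaussFit(mu1=5.0 * g, mu2=(5.0 + 0.46) * g, sd1=0.01,
                              sd2=0.01, w1=1, w2=1, fit_residual=0.0)
            assert mt.estimate_asc(fit, kcl_amp=10.0 * g) == pytest.approx(4.6)

    def test_unimodal_reports_zero_with_warning(self):
        fit = sp.GaussFit(mu1=5.0, mu2=5.01, sd1=0.1, sd2=0.1, w1=1, w2=1,
                          fit_residual=0.0, unimodal=True)
        with pytest.warns(UserWarning):
            assert mt.estimate_asc(fit, kcl_amp=10.0) == 0.0

    def test_nonpositive_kcl_rejected(self):
        fit = sp.GaussFit(mu1=0, mu2=1, sd1=0.1, sd2=0.1, w1=1, w2=1,
                          fit_residual=0.0)
        with pytest.raises(DomainError):
            mt.estimate_asc(fit, kcl_amp=0.0)


class TestPowerSpectrum:
    def test_pure_sinusoid_single_dominant_peak(self):
        t = np.arange(0, 2000, 0.5)
        x = np.sin(2 * np.pi * 0.05 * t)
        f, peak = mt.estimate_fsc(mt.power_spectrum(x, 2.0))
        assert f == pytest.approx(0.05, abs=0.001)

    def test_two_sinusoids_strongest_wins(self):
        """Brute-force argmax over the periodogram is the oracle."""
        t = np.arange(0, 2000, 0.5)
        x = (np.sin(2 * np.pi * 0.03 * t)
             + 0.5 * np.sin(2 * np.pi * 0.10 * t))
        spec = mt.power_spectrum(x, 2.0)
        m = (spec.freqs >= 0.005) & (spec.freqs <= 0.5)
        brute = spec.freqs[m][np.argmax(spec.power[m])]
        f, _ = mt.estimate_fsc(spec)
        assert brute == pytest.approx(0.03, abs=spec.df)
        assert f == pytest.approx(0.03, abs=spec.df)

    def test_phase_shift_invariance(self):
        t = np.arange(0, 2000, 0.5)
        fa, _ = mt.estimate_fsc(mt.power_spectrum(
            np.sin(2 * np.pi * 0.047 * t), 2.0))
        fb, _ = mt.estimate_fsc(mt.power_spectrum(
            np.sin(2 * np.pi * 0.047 * t + 1.8), 2.0))
        assert fa == pytest.approx(fb, abs=1e-3)

    def test_white_noise_rarely_flags_a_rhythm(self):
        """Monte-Carlo null: false-detection rate at most 5% over 100 seeds."""
        fp = 0
        for seed in range(100):
            x = np.random.default_rng(seed).normal(size=8000)
            spec = mt.power_spectrum(x, 2.0, band_low=0.02, nperseg_s=250.0)
            try:
                mt.estimate_fsc(spec, band=(0.02, 0.3))
                fp += 1
            except NoDominantRhythmError:
                pass
        assert fp <= 5

    def test_parseval_band_integral_matches_variance(self):
        x = np.random.default_rng(11).normal(0, 2.0, 4000)
        spec = mt.power_spectrum(x, 2.0, window="boxcar", nperseg_s=2000.0,
                                 detrend="constant")
        assert np.sum(spec.power) * spec.df == pytest.approx(np.var(x), rel=0.01)

    def test_flat_spectrum_has_no_dominant_rhythm(self):
        spec = sp.Spectrum(freqs=np.linspace(0, 1, 1001),
                           power=np.ones(1001), df=0.001, n_segments=1)
        with pytest.raises(NoDominantRhythmError):
            mt.estimate_fsc(spec)

    def test_short_segment_resolution_error(self):
        with pytest.raises(ResolutionError):
            mt.power_spectrum(np.random.default_rng(0).normal(size=500),
                              2.0, band_low=0.005)


class TestQuantifySpontaneous:
    def test_noiseless_oracle_equivalence(self, noiseless_control_bundle):
        """On noiseless jitter-free data the estimators recover the generator
        parameters: A_SC to <1% relative, f_SC within one interpolated bin."""
        st = mt.quantify_spontaneous(noiseless_control_bundle)
        assert st.A_SC == pytest.approx(4.6, rel=0.01)
        assert st.f_SC == pytest.approx(0.047, abs=0.001)
        assert st.T_SC * st.f_SC == pytest.approx(1.0)

    def test_gain_rescaling_leaves_estimates_unchanged(self,
                                                       noiseless_control_bundle):
        b = noiseless_control_bundle
        st = mt.quantify_spontaneous(b)
        scaled = mt.TraceBundle(
            trace=TensionTrace(samples=3.0 * b.trace.samples,
                               sampling_rate=b.trace.sampling_rate,
                               strip_meta=b.trace.strip_meta),
            events=b.events)
        st2 = mt.quantify_spontaneous(scaled)
        assert st2.A_SC == pytest.approx(st.A_SC, rel=1e-6)
        assert st2.f_SC == pytest.approx(st.f_SC, abs=1e-9)

    def test_missing_kcl_window_is_normalization_error(self, control_params):
        b = mt.simulate_strip(control_params, 1800.0, 10.0, protocol=EventLog())
        with pytest.raises(NormalizationError):
            mt.quantify_spontaneous(b)

    def test_stage_errors_carry_stage_label(self, control_params):
        p = dataclasses.replace(control_params, drift_mN_per_min=1.0)
        b = mt.simulate_strip(p, 1800.0, 10.0)
        with pytest.raises(StageError) as err:
            mt.quantify_spontaneous(b)
        assert err.value.stage == "segment_selection"

    def test_ensemble_bias_small_at_default_noise(self, spont_tables):
        """Cohort-mean recovery of both parameters within a few percent."""
        tab = spont_tables["control"]
        assert tab.A_SC_pct.mean() == pytest.approx(4.6, rel=0.10)
        assert tab.f_SC_Hz.mean() == pytest.approx(0.047, rel=0.10)
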