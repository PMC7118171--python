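"""Coherence estimators: bounds, thresholds, phase, delay regression."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import cmcpipe as cp
from cmcpipe.mvar import spectral_transform
from cmcpipe.synth import draw_timings


FS = 250.0


class TestSignificanceThreshold:
    def test_printed_reference_value(self):
        assert round(cp.significance_threshold(0.005, 128), 4) == 0.0409

    def test_limit_alpha_to_one_gives_zero(self):
        assert cp.significance_threshold(1 - 1e-12, 128) == pytest.approx(0.0, abs=1e-9)

    def test_two_segments_exponent_one(self):
        assert cp.significance_threshold(0.05, 2) == pytest.approx(0.95)

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            cp.significance_threshold(0.005, 1)
        with pytest.raises(ValueError):
            cp.significance_threshold(0.0, 10)


class TestGaborTransform:
    def test_matched_frequency_row_maximal(self):
        t = np.arange(375) / FS
        tf = cp.gabor_transform(np.sin(2 * np.pi * 20 * t)[None], FS,
                                np.arange(2.0, 101.0))
        mid = np.abs(tf.coeffs[0][:, 187])
        assert tf.freqs[np.argmax(mid)] == 20.0

    def test_time_shift_rotates_phase(self):
        rng = np.random.default_rng(0)
        x = rng.standard_normal(600)
        shift = 5
        freqs = np.array([10.0, 20.0, 40.0])
        a = cp.gabor_transform(x[None, :500], FS, freqs)
        b = cp.gabor_transform(x[None, shift:500 + shift], FS, freqs)
        mid = 250
        dphi = np.angle(a.coeffs[0][:, mid + shift] * np.conj(b.coeffs[0][:, mid]))
        expected = np.zeros_like(freqs)  # same sample of the signal -> equal phase
        np.testing.assert_allclose(dphi, expected, atol=1e-6)

    def test_white_noise_power_flat(self):
        rng = np.random.default_rng(1)
        x = rng.standard_normal((200, 375))
        tf = cp.gabor_transform(x, FS, np.arange(10.0, 91.0, 10.0))
        power = np.mean(np.abs(tf.coeffs) ** 2, axis=(0, 2))
        assert np.ptp(power) / np.mean(power) < 0.2

    def test_frequency_above_nyquist_rejected(self):
        with pytest.raises(ValueError):
            cp.gabor_transform(np.zeros((1, 375)), FS, np.array([130.0]))


class TestWaveletCoherence:
    def _maps(self, x, y):
        freqs = np.arange(5.0, 96.0, 5.0)
        return (cp.gabor_transform(x, FS, freqs),
                cp.gabor_transform(y, FS, freqs))

    def test_identical_signals_coherence_one(self):
        rng = np.random.default_rng(0)
        x = rng.standard_normal((8, 375))
        cm = cp.wavelet_coherence(*self._maps(x, x.copy()))
        np.testing.assert_allclose(cm.coh, 1.0, atol=1e-9)

    def test_independent_signals_small_sample_bias(self):
        rng = np.random.default_rng(1)
        n = 20
        cm = cp.wavelet_coherence(*self._maps(rng.standard_normal((n, 375)),
                                              rng.standard_normal((n, 375))))
        # expected bias of magnitude-squared coherence ~ 1/N
        assert np.mean(cm.coh) == pytest.approx(1.0 / n, rel=0.35)

    def test_bounded_zero_one(self):
        rng = np.random.default_rng(2)
        x = rng.standard_normal((5, 375))
        y = 0.5 * x + rng.standard_normal((5, 375))
        cm = cp.wavelet_coherence(*self._maps(x, y))
        assert np.all(cm.coh >= 0) and np.all(cm.coh <= 1 + 1e-12)

    def test_single_trial_rejected(self):
        rng = np.random.default_rng(3)
        x = rng.standard_normal((1, 375))
        with pytest.raises(ValueError):
            cp.wavelet_coherence(*self._maps(x, x))


class TestSegmentCoherence:
    def test_frequency_resolution(self):
        rng = np.random.default_rng(0)
        spec = cp.segment_coherence(rng.standard_normal((4, 128)),
                                    rng.standard_normal((4, 128)), fs=FS)
        assert spec.delta_f == pytest.approx(1.953125)
        assert round(spec.delta_f, 2) == 1.95

    def test_identical_signals_coherence_one(self):
        rng = np.random.default_rng(1)
        x = rng.standard_normal((6, 128))
        spec = cp.segment_coherence(x, x.copy(), fs=FS)
        np.testing.assert_allclose(spec.coh, 1.0, atol=1e-9)

    def test_mains_band_deleted(self):
        rng = np.random.default_rng(2)
        spec = cp.segment_coherence(rng.standard_normal((4, 128)),
                                    rng.standard_normal((4, 128)),
                                    fs=FS, mains=50.0)
        assert not np.any((spec.freqs > 45.0) & (spec.freqs < 55.0))

    def test_matches_closed_form_ar_coherence(self):
        # coupled VAR fixture vs the analytic coherence of its spectral matrix
        # moderate pole modulus: a resonance broad relative to the 1.95 Hz
        # bins, so rectangular-window leakage is negligible next to the
        # Monte-Carlo error this tolerance budgets for
        spec_true = cp.CouplingSpec(regime="beta_loop", active_phase="both",
                                    pole_modulus=0.85)
        A, V = spec_true.var_coefficients(FS)
        y = cp.simulate_var(A, V, 128 * 3000, np.random.default_rng(3))
        segs = y.reshape(3000, 128, 2)
        est = cp.segment_coherence(segs[:, :, 0], segs[:, :, 1], fs=FS)
        tr = spectral_transform(A, V, est.freqs, FS)
        S = tr["S"]
        coh_true = np.abs(S[:, 0, 1]) ** 2 / (S[:, 0, 0].real * S[:, 1, 1].real)
        assert np.mean(np.abs(est.coh - coh_true)) < 0.02

    def test_wrong_segment_shape_rejected(self):
        with pytest.raises(ValueError):
            cp.segment_coherence(np.zeros((4, 128)), np.zeros((4, 64)))


class TestPhaseAndConfidence:
    def test_one_sample_delay_linear_phase(self):
        rng = np.random.default_rng(0)
        x = rng.standard_normal((64, 129))
        spec = cp.segment_coherence(x[:, :-1], x[:, 1:], fs=FS, demean=False)
        # y leads x by one sample: theta(f) = +2 pi f T on the principal branch
        T = 1.0 / FS
        expected = np.angle(np.exp(2j * np.pi * spec.freqs * T))
        low = spec.freqs < 100
        np.testing.assert_allclose(spec.phase[low], expected[low], atol=0.15)

    def test_perfect_coherence_zero_confidence_width(self):
        assert float(cp.phase_confidence_interval(1.0, 128)) == 0.0

    def test_reference_value_half_coherence(self):
        assert float(cp.phase_confidence_interval(0.5, 128)) == pytest.approx(0.1225, abs=5e-5)


class TestDelayFromPhase:
    def test_unit_slope_conversion(self):
        freqs = np.arange(15.0, 31.0)
        phase = -2 * np.pi / 1000.0 * freqs
        est = cp.delay_from_phase(freqs, phase, np.ones_like(freqs, bool))
        assert est.tau_ms == pytest.approx(1.0, abs=1e-9)
        assert est.significant

    def test_zero_slope_not_significant(self):
        freqs = np.arange(15.0, 31.0)
        est = cp.delay_from_phase(freqs, np.full(16, 0.5), np.ones(16, bool))
        assert est.tau_ms == pytest.approx(0.0, abs=1e-12)
        assert not est.significant

    def test_too_few_bins_returns_none(self):
        freqs = np.arange(4.0)
        mask = np.array([True, True, False, True])
        assert cp.delay_from_phase(freqs, np.zeros(4), mask, min_bins=3) is None

    def test_sample_shift_changes_delay_by_sampling_interval(self):
        spec = cp.CouplingSpec(regime="broadband_efferent", efferent_gain=1.0)
        timings = draw_timings(64, np.random.default_rng(2))
        lfp, emg = cp.simulate_pair(spec, timings, fs=FS, seed=4)
        ev = np.array([t.grip_onset for t in timings])

        def tau(extra_shift):
            ex, _ = cp.extract_epochs(lfp, ev, (0.0, 0.512), FS)
            ey, _ = cp.extract_epochs(
                [np.roll(tr, extra_shift) for tr in emg], ev, (0.0, 0.512), FS)
            s = cp.segment_coherence(ex, ey, fs=FS)
            return cp.delay_from_phase(s.freqs, s.phase, s.significant).tau_ms

        shift_effect = tau(2) - tau(0)
        assert shift_effect == pytest.approx(2 * 4.0, abs=1.0)


@settings(deadline=None, max_examples=25, derandomize=True)
@given(st.integers(min_value=0, max_value=10_000))
def test_coherence_always_in_unit_interval(seed):
    """Both estimators stay inside [0, 1] for arbitrary random inputs."""
    rng = np.random.default_rng(seed)
    x = rng.standard_normal((3, 128))
    y = 0.8 * x + 0.3 * rng.standard_normal((3, 128))
    spec = cp.segment_coherence(x, y, fs=FS)
    assert np.all((spec.coh >= 0) & (spec.coh <= 1 + 1e-12))
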