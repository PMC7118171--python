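"""MVAR estimation and spectral causality measures."""

import numpy as np
import pytest

import cmcpipe as cp
from cmcpipe.mvar import (
    MVARCausality,
    directed_coherence,
    partial_directed_coherence,
    spectral_transform,
)

FS = 250.0
FREQS = np.fft.rfftfreq(128, d=1.0 / FS)[1:]


def _random_stable_var(rng, m=2, p=3, scale=0.3, max_radius=0.95):
    while True:
        A = scale * rng.standard_normal((p, m, m))
        if cp.companion_spectral_radius(A) < max_radius:
            return A


class TestFit:
    def test_white_noise_coefficients_vanish(self):
        rng = np.random.default_rng(0)
        segs = rng.standard_normal((800, 128, 2))  # ~10^5 samples
        model = MVARCausality(order=15, fs=FS).fit(segs)
        assert np.max(np.abs(model.coef_)) < 0.05
        assert model.stable_

    def test_known_var2_recovered(self):
        rng = np.random.default_rng(1)
        A = np.zeros((2, 2, 2))
        A[0] = [[0.5, 0.1], [0.2, 0.4]]
        A[1] = [[-0.3, 0.0], [0.05, -0.2]]
        V = np.diag([1.0, 0.5])
        y = cp.simulate_var(A, V, 128 * 800, rng)
        model = MVARCausality(order=2, fs=FS).fit(y.reshape(800, 128, 2))
        np.testing.assert_allclose(model.coef_, A, atol=0.02)
        np.testing.assert_allclose(model.resid_cov_, V, atol=0.02)

    def test_order_must_fit_segment(self):
        with pytest.raises(ValueError):
            MVARCausality(order=200, fs=FS).fit(np.zeros((4, 128, 2)))

    def test_agrees_with_statsmodels_var(self):
        # independent oracle on one long segment
        from statsmodels.tsa.api import VAR

        rng = np.random.default_rng(2)
        A = _random_stable_var(rng, p=2)
        y = cp.simulate_var(A, np.eye(2), 20000, rng)
        ours = MVARCausality(order=2, fs=FS).fit(y[None, :, :])
        ref = VAR(y - y.mean(axis=0)).fit(maxlags=2, trend="n")
        np.testing.assert_allclose(
            ours.coef_, ref.coefs, atol=5e-3
        )


class TestSpectralTransform:
    def test_all_zero_coefficients_white_case(self):
        V = np.array([[1.5, 0.2], [0.2, 0.8]])
        tr = spectral_transform(np.zeros((1, 2, 2)), V, FREQS, FS)
        np.testing.assert_allclose(tr["H"], np.broadcast_to(np.eye(2), tr["H"].shape), atol=1e-14)
        np.testing.assert_allclose(tr["S"], np.broadcast_to(V, tr["S"].shape), atol=1e-12)

    def test_ar1_spectrum_closed_form(self):
        a, s2 = 0.5, 1.3
        A = np.zeros((1, 2, 2))
        A[0, 0, 0] = a
        V = np.diag([s2, 1.0])
        tr = spectral_transform(A, V, FREQS, FS)
        T = 1.0 / FS
        expected = s2 / np.abs(1 - a * np.exp(-2j * np.pi * FREQS * T)) ** 2
        np.testing.assert_allclose(tr["S"][:, 0, 0].real, expected, rtol=1e-10)

    def test_abar_times_h_is_identity(self):
        rng = np.random.default_rng(3)
        A = _random_stable_var(rng)
        tr = spectral_transform(A, np.eye(2), FREQS, FS)
        prod = tr["Abar"] @ tr["H"]
        np.testing.assert_allclose(prod, np.broadcast_to(np.eye(2), prod.shape), atol=1e-10)


class TestNormalization:
    def test_dc_rows_and_pdc_columns_sum_to_one(self):
        rng = np.random.default_rng(4)
        for _ in range(20):
            A = _random_stable_var(rng)
            V = np.diag(rng.uniform(0.5, 2.0, 2))
            tr = spectral_transform(A, V, FREQS, FS)
            dc = directed_coherence(tr, V)
            pdc, _ = partial_directed_coherence(tr, V)
            np.testing.assert_allclose(dc.sum(axis=2), 1.0, atol=1e-10)
            np.testing.assert_allclose(pdc.sum(axis=1), 1.0, atol=1e-10)

    def test_pdc_zero_without_direct_coupling(self):
        A = np.zeros((2, 2, 2))
        A[0] = np.diag([0.5, 0.3])
        pdc, _ = partial_directed_coherence(
            spectral_transform(A, np.eye(2), FREQS, FS), np.eye(2))
        np.testing.assert_allclose(pdc[:, 0, 1], 0.0, atol=1e-14)
        np.testing.assert_allclose(pdc[:, 1, 0], 0.0, atol=1e-14)


class TestDirectVsIndirect:
    def test_chain_pdc_distinguishes_direct_path(self):
        # x -> y -> z: directed coherence sees z <- x, PDC does not
        A = np.zeros((2, 3, 3))
        A[0] = np.diag([0.5, 0.5, 0.5])
        A[1, 1, 0] = 0.8  # y <- x
        A[1, 2, 1] = 0.8  # z <- y
        V = np.eye(3)
        tr = spectral_transform(A, V, FREQS, FS)
        dc = directed_coherence(tr, V)
        pdc, _ = partial_directed_coherence(tr, V)
        assert dc[:, 2, 0].max() > 0.1
        np.testing.assert_allclose(pdc[:, 2, 0], 0.0, atol=1e-12)


class TestPhaseDelay:
    def test_pure_delayed_coupling_recovers_lag(self):
        rng = np.random.default_rng(5)
        k = 5  # samples -> 20 ms at 250 Hz
        A = np.zeros((k, 2, 2))
        A[k - 1, 1, 0] = 0.9
        y = cp.simulate_var(A, np.eye(2), 128 * 400, rng)
        model = MVARCausality(order=8, fs=FS).fit(y.reshape(400, 128, 2))
        est = model.phase_delay(1, 0, band=(2.0, 100.0))
        assert est is not None
        assert est.tau_ms == pytest.approx(k * 4.0, abs=1.0)

    def test_delay_invariant_to_channel_gain(self):
        spec = cp.CouplingSpec(regime="broadband_efferent", efferent_gain=1.0)
        from cmcpipe.synth import draw_timings
        timings = draw_timings(96, np.random.default_rng(2))
        lfp, emg = cp.simulate_pair(spec, timings, fs=FS, seed=6)
        ev = np.array([t.grip_onset for t in timings])
        ex, _ = cp.extract_epochs(lfp, ev, (0.0, 0.512), FS)
        ey, _ = cp.extract_epochs(emg, ev, (0.0, 0.512), FS)

        def tau(gx, gy):
            m = MVARCausality(order=15, fs=FS).fit(
                np.stack([gx * ex, gy * ey], axis=-1))
            return m.phase_delay(1, 0, band=(2.0, 100.0)).tau_ms

        assert tau(1.0, 1.0) == pytest.approx(tau(7.5, 0.02), abs=1e-6)

    def test_symmetric_coupling_gives_equal_delays(self):
        # a symmetric one-lag loop: both directions must report the same
        # (minimal) lag -- neither side leads the other
        rng = np.random.default_rng(7)
        A = np.zeros((1, 2, 2))
        A[0] = [[0.4, 0.3], [0.3, 0.4]]
        y = cp.simulate_var(A, np.eye(2), 128 * 400, rng)
        model = MVARCausality(order=4, fs=FS).fit(y.reshape(400, 128, 2))
        eff = model.phase_delay(1, 0, band=(2.0, 100.0))
        aff = model.phase_delay(0, 1, band=(2.0, 100.0))
        assert eff is not None and aff is not None
        assert eff.tau_ms == pytest.approx(aff.tau_ms, abs=1.0)
        assert eff.tau_ms == pytest.approx(4.0, abs=1.2)  # one-lag coupling

    def test_loop_time_sums_both_directions(self):
        a = cp.DelayEstimate(30.0, -0.1, 0.0, 0.01, (15, 30), 8)
        b = cp.DelayEstimate(27.0, -0.1, 0.0, 0.01, (15, 30), 8)
        assert cp.loop_time(a, b) == pytest.approx(57.0)
        assert cp.loop_time(a, None) is None
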