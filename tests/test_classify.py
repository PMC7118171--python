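"""Pattern classification: contour features, GMM/EM, Grubbs, latency."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import cmcpipe as cp
from cmcpipe.classify import BB, NB, NONE, fit_gmm_1d
from cmcpipe.coherence import WaveletCoherenceMap


def make_map(coh, threshold=0.0409, dt=0.004, df=1.0, t0=-1.0):
    """WaveletCoherenceMap from a raw (n_freqs, n_times) array."""
    coh = np.asarray(coh, dtype=float)
    nf, nt = coh.shape
    return WaveletCoherenceMap(
        coh=coh,
        freqs=np.arange(2.0, 2.0 + nf * df, df)[:nf],
        times=t0 + np.arange(nt) * dt,
        n_trials=128,
        alpha=0.005,
        threshold=threshold,
        edge_valid=np.ones(nt, dtype=bool),
    )


class TestContourIntegral:
    def test_no_significant_bins_gives_zero(self):
        cmap = make_map(np.full((10, 500), 0.01))
        assert cp.contour_integral(cmap, (-1.0, 1.0)) == 0.0

    def test_flat_map_level_arithmetic(self):
        level = 0.0409 + 0.015
        cmap = make_map(np.full((10, 250), level))
        # exactly two contour levels (S, S+0.01) lie at or below the map
        area = 10 * 250 * 0.004 * 1.0
        assert cp.contour_integral(cmap, (-1.0, 1.0)) == pytest.approx(2 * area)

    def test_empty_window_rejected(self):
        with pytest.raises(ValueError):
            cp.contour_integral(make_map(np.zeros((5, 100))), (5.0, 6.0))

    @settings(deadline=None, max_examples=20, derandomize=True)
    @given(st.integers(min_value=0, max_value=9999))
    def test_monotone_in_map_values(self, seed):
        rng = np.random.default_rng(seed)
        base = rng.uniform(0, 0.2, (8, 100))
        cmap_lo = make_map(base.copy())
        bumped = base.copy()
        i, j = rng.integers(8), rng.integers(100)
        bumped[i, j] = min(1.0, bumped[i, j] + 0.3)
        cmap_hi = make_map(bumped)
        assert (cp.contour_integral(cmap_hi, (-1.0, 1.0))
                >= cp.contour_integral(cmap_lo, (-1.0, 1.0)))


class TestGrubbs:
    def test_equal_values_no_outliers(self):
        assert not cp.grubbs_test(np.full(10, 3.3)).any()

    def test_gross_outlier_flagged(self):
        flags = cp.grubbs_test(np.array([0.0, 0.0, 0.0, 0.0, 100.0]))
        assert list(flags) == [False, False, False, False, True]

    def test_tiny_sample_untestable(self):
        assert not cp.grubbs_test(np.array([0.0, 9.0])).any()


class TestGMM:
    def test_separated_clusters_fully_recovered(self):
        rng = np.random.default_rng(0)
        x = np.concatenate([rng.normal(0, 0.1, 40), rng.normal(10, 0.1, 60)])
        fit = fit_gmm_1d(x)
        assert not fit.unimodal
        hard = np.argmax(fit.responsibilities, axis=1)
        # all members of each cluster share a component
        assert len(set(hard[:40])) == 1 and len(set(hard[40:])) == 1
        assert hard[0] != hard[-1]

    def test_identical_points_unimodal(self):
        fit = fit_gmm_1d(np.full(50, 2.0) + 1e-9 * np.arange(50))
        assert fit.unimodal

    def test_weight_recovery_at_n500(self):
        rng = np.random.default_rng(1)
        x = np.concatenate([rng.normal(0, 1, 200), rng.normal(6, 1, 300)])
        fit = fit_gmm_1d(x)
        w = np.sort(fit.weights)
        assert w[0] == pytest.approx(0.4, abs=0.05)
        assert np.sort(fit.means) == pytest.approx([0.0, 6.0], abs=0.2)

    def test_loglik_path_monotone(self):
        rng = np.random.default_rng(2)
        x = np.concatenate([rng.normal(0, 1, 100), rng.normal(4, 0.5, 100)])
        fit = fit_gmm_1d(x)
        assert np.all(np.diff(fit.loglik_path) >= -1e-9)

    def test_permutation_invariance(self):
        rng = np.random.default_rng(3)
        x = np.concatenate([rng.normal(0, 1, 80), rng.normal(5, 1, 80)])
        a = fit_gmm_1d(x)
        b = fit_gmm_1d(x[rng.permutation(len(x))])
        np.testing.assert_allclose(np.sort(a.means), np.sort(b.means), atol=1e-6)

    def test_agrees_with_sklearn_mixture(self):
        from sklearn.mixture import GaussianMixture

        rng = np.random.default_rng(4)
        x = np.concatenate([rng.normal(-2, 0.5, 150), rng.normal(3, 1.0, 150)])
        ours = fit_gmm_1d(x)
        ref = GaussianMixture(2, n_init=5, random_state=0).fit(x[:, None])
        np.testing.assert_allclose(np.sort(ours.means),
                                   np.sort(ref.means_.ravel()), atol=0.05)


class TestClassifier:
    def _features(self, rng, n_nb=20, n_bb=15, n_none=5):
        ci = np.concatenate([
            10 ** rng.normal(0.8, 0.2, n_nb),     # narrow-band cluster
            10 ** rng.normal(3.2, 0.2, n_bb),     # broad-band cluster
            np.zeros(n_none),
        ])
        width = np.concatenate([
            rng.uniform(4, 16, n_nb), rng.uniform(60, 110, n_bb),
            np.zeros(n_none),
        ])
        labels = np.array([NB] * n_nb + [BB] * n_bb + [NONE] * n_none)
        return np.column_stack([ci, width]), labels

    def test_labels_partition_and_match_clusters(self):
        rng = np.random.default_rng(0)
        X, want = self._features(rng)
        clf = cp.CoherencePatternClassifier()
        got = clf.fit_predict(X)
        assert set(got) <= {NB, BB, NONE}
        assert np.mean(got == want) == 1.0
        assert not clf.unimodal_

    def test_zero_feature_pairs_labelled_none(self):
        rng = np.random.default_rng(1)
        X, _ = self._features(rng)
        got = cp.CoherencePatternClassifier().fit_predict(X)
        assert np.all(got[X[:, 0] == 0] == NONE)

    def test_wide_outlier_in_nb_cluster_reassigned_bb(self):
        rng = np.random.default_rng(2)
        X, want = self._features(rng, n_nb=24, n_bb=15, n_none=0)
        X[0, 1] = 80.0  # NB-cluster member with a grossly broad band
        got = cp.CoherencePatternClassifier().fit_predict(X)
        assert got[0] == BB
        assert np.mean(got[1:] == want[1:]) == 1.0

    def test_unimodal_population_all_nb(self):
        rng = np.random.default_rng(3)
        ci = 10 ** rng.normal(1.0, 0.3, 127)
        X = np.column_stack([ci, rng.uniform(5, 15, 127)])
        clf = cp.CoherencePatternClassifier()
        got = clf.fit_predict(X)
        assert clf.unimodal_
        assert np.all(got == NB)

    def test_too_few_pairs_rejected(self):
        with pytest.raises(ValueError):
            cp.CoherencePatternClassifier().fit(np.ones((5, 2)))

    def test_predict_on_new_points(self):
        rng = np.random.default_rng(4)
        X, _ = self._features(rng)
        clf = cp.CoherencePatternClassifier().fit(X)
        new = np.array([[10.0, 10.0], [2000.0, 90.0], [0.0, 0.0]])
        assert list(clf.predict(new)) == [NB, BB, NONE]


class TestOnsetLatency:
    def test_uniform_onset_recovered(self):
        coh = np.zeros((10, 500))
        onset_idx = 226  #, -1 s grid, 4 ms steps -> t = -0.096 s
        coh[:, onset_idx:] = 0.5
        lat = cp.onset_latency(make_map(coh, dt=0.004, t0=-1.0), (2.0, 12.0))
        assert lat.latency_ms == pytest.approx(-96.0, abs=1e-9)

    def test_single_significant_bin(self):
        coh = np.zeros((10, 500))
        coh[3, 100] = 0.9
        lat = cp.onset_latency(make_map(coh), (2.0, 12.0))
        assert lat.latency_ms == pytest.approx((-1.0 + 100 * 0.004) * 1000)

    def test_no_significance_returns_none(self):
        assert cp.onset_latency(make_map(np.zeros((5, 100))), (2.0, 7.0)) is None

    def test_staggered_gates_yield_latency_difference(self):
        # broad-band onset programmed 90 ms before the narrow-band onset
        coh_bb = np.zeros((20, 500))
        coh_bb[:, 200:] = 0.5    # t = -0.2 s
        coh_nb = np.zeros((20, 500))
        coh_nb[:, 222:] = 0.5    # t = -0.112 s within ~1 bin of +90 ms
        lat_bb = cp.onset_latency(make_map(coh_bb), (2.0, 22.0))
        lat_nb = cp.onset_latency(make_map(coh_nb), (2.0, 22.0))
        assert lat_nb.latency_ms - lat_bb.latency_ms == pytest.approx(88.0, abs=8.0)
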