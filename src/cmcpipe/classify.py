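"""Classification of LFP-EMG coherence patterns: broad-band vs narrow-band.

Each analyzed pair is summarized by two features:

* the **contour integral** of its wavelet coherence map inside the grip
  (0 to 1 s from grip onset) and hold (-1 to 0 s from release onset)
  windows: for contour levels from the significance threshold S to 1 in
  fixed steps, the significant area (bin count x dt x df) at or above each
  level is summed, so strength, bandwidth and temporal extent all
  contribute;
* the **frequency width** (Hz) of the significant band in the fixed-window
  coherence spectrum, used as a supplementary dimension.

A two-component 1-D Gaussian mixture, fitted by EM on log10 contour
integrals, separates the two populations; the smaller-mean component is
narrow-band (NB), the larger broad-band (BB).  NB members are then screened
for outliers in the width dimension (iterative two-sided Grubbs test at
p < 0.05); outliers wider than 25 Hz are reassigned to BB.  When a
single-Gaussian model wins on BIC the distribution is declared unimodal and
every pair with significant coherence is NB (the cortical case).

Coherence-onset latency is the median over frequency bins of the earliest
significant time in the map.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from sklearn.base import BaseEstimator

from .coherence import WaveletCoherenceMap, longest_run

NB, BB, NONE = "NB", "BB", "none"


# ------------------------------------------------------------------ features
def contour_integral(
    cmap: WaveletCoherenceMap,
    window: tuple[float, float],
    level_step: float = 0.01,
) -> float:
    """Sum of significant areas (s x Hz) at each contour level in a window."""
    t0, t1 = window
    tsel = (cmap.times >= t0) & (cmap.times < t1) & cmap.edge_valid
    if not np.any(tsel):
        raise ValueError("empty window for contour integration")
    vals = cmap.coh[:, tsel]
    dt = float(np.median(np.diff(cmap.times)))
    df = float(np.median(np.diff(cmap.freqs)))
    levels = np.arange(cmap.threshold, 1.0, level_step)
    counts = (vals[None, :, :] >= levels[:, None, None]).sum(axis=(1, 2))
    return float(counts.sum() * dt * df)


def frequency_width(sig_mask: np.ndarray, delta_f: float) -> float:
    """Width (Hz) of the significant band in a fixed-window spectrum.

    Measured as the longest contiguous run of significant bins times the
    bin width, so isolated point-wise false positives (or narrow harmonic
    blips away from the main band) do not inflate the width of the band.
    """
    return float(longest_run(sig_mask) * delta_f)


# ------------------------------------------------------------------- Grubbs
def _grubbs_critical(n: int, alpha: float) -> float:
    t = stats.t.ppf(1.0 - alpha / (2.0 * n), n - 2)
    return (n - 1) / np.sqrt(n) * np.sqrt(t**2 / (n - 2 + t**2))


def grubbs_test(values: np.ndarray, alpha: float = 0.05) -> np.ndarray:
    """Iterative two-sided Smirnov-Grubbs outlier flags.

    The most extreme point is tested against the critical value at level
    ``alpha`` and removed if it exceeds it; the test repeats on the
    remainder.  With n < 3 no test is possible and nothing is flagged.
    """
    values = np.asarray(values, dtype=float)
    flags = np.zeros(values.shape, dtype=bool)
    active = np.ones(values.shape, dtype=bool)
    while active.sum() >= 3:
        x = values[active]
        sd = x.std(ddof=1)
        if sd == 0:
            break
        dev = np.abs(x - x.mean()) / sd
        imax = int(np.argmax(dev))
        if dev[imax] <= _grubbs_critical(len(x), alpha):
            break
        idx = np.flatnonzero(active)[imax]
        flags[idx] = True
        active[idx] = False
    return flags


# ------------------------------------------------------------------ 1-D GMM
@dataclass
class GMMFit:
    """Two-component (or collapsed one-component) 1-D Gaussian mixture."""

    means: np.ndarray
    variances: np.ndarray
    weights: np.ndarray
    log_likelihood: float
    loglik_path: np.ndarray
    responsibilities: np.ndarray
    n_iter: int
    bic1: float = np.nan
    bic2: float = np.nan
    unimodal: bool = False


def _gmm_loglik(x, means, variances, weights):
    comp = (
        np.log(weights)[None, :]
        - 0.5 * np.log(2 * np.pi * variances)[None, :]
        - 0.5 * (x[:, None] - means[None, :]) ** 2 / variances[None, :]
    )
    m = comp.max(axis=1, keepdims=True)
    lse = m[:, 0] + np.log(np.exp(comp - m).sum(axis=1))
    return comp, lse


def fit_gmm_1d(
    x: np.ndarray,
    tol: float = 1e-8,
    max_iter: int = 500,
    var_floor_frac: float = 1e-6,
) -> GMMFit:
    """Deterministic EM for a two-component 1-D Gaussian mixture.

    Initialization at the 25th/75th percentiles with equal weights and the
    data variance; the variance floor is ``var_floor_frac`` of the data
    variance, and the per-iteration log-likelihood trace is retained (it is
    non-decreasing up to the floor).
    """
    x = np.asarray(x, dtype=float)
    n = len(x)
    if n < 2:
        raise ValueError("at least two points are required")
    data_var = max(x.var(), 1e-300)
    floor = var_floor_frac * data_var
    means = np.percentile(x, [25.0, 75.0]).astype(float)
    if means[0] == means[1]:
        means = means + np.array([-1e-6, 1e-6])
    variances = np.array([data_var, data_var])
    weights = np.array([0.5, 0.5])
    path = []
    resp = np.full((n, 2), 0.5)
    for it in range(max_iter):
        comp, lse = _gmm_loglik(x, means, variances, weights)
        ll = float(lse.sum())
        path.append(ll)
        resp = np.exp(comp - lse[:, None])
        nk = resp.sum(axis=0)
        nk = np.maximum(nk, 1e-12)
        weights = nk / n
        means = (resp * x[:, None]).sum(axis=0) / nk
        variances = (resp * (x[:, None] - means[None, :]) ** 2).sum(axis=0) / nk
        variances = np.maximum(variances, floor)
        if it > 0 and abs(path[-1] - path[-2]) < tol:
            break
    _, lse = _gmm_loglik(x, means, variances, weights)
    ll = float(lse.sum())
    # single-Gaussian reference for the unimodality decision
    ll1 = float(
        stats.norm.logpdf(x, loc=x.mean(), scale=np.sqrt(data_var)).sum()
    )
    bic1 = -2.0 * ll1 + 2.0 * np.log(n)
    bic2 = -2.0 * ll + 5.0 * np.log(n)
    return GMMFit(
        means=means, variances=variances, weights=weights,
        log_likelihood=ll, loglik_path=np.asarray(path),
        responsibilities=resp, n_iter=len(path),
        bic1=bic1, bic2=bic2, unimodal=bool(bic1 <= bic2),
    )


# --------------------------------------------------------------- classifier
@dataclass
class PatternLabel:
    label: str  # NB | BB | none
    posterior: float
    outlier: bool = False


class CoherencePatternClassifier(BaseEstimator):
    """NB/BB classifier over (contour integral, frequency width) features.

    Parameters
    ----------
    width_threshold : float
        Frequency-width criterion (Hz) above which an NB-assigned Grubbs
        outlier is reassigned to BB.
    grubbs_alpha : float
        Level of the iterative two-sided Grubbs outlier test.
    log_eps : float
        Offset added before the log10 transform of contour integrals.

    Fitted attributes: ``gmm_`` (:class:`GMMFit`), ``labels_``,
    ``nb_component_``, ``unimodal_``.
    """

    def __init__(self, width_threshold: float = 25.0, grubbs_alpha: float = 0.05,
                 log_eps: float = 1e-12):
        self.width_threshold = width_threshold
        self.grubbs_alpha = grubbs_alpha
        self.log_eps = log_eps

    def fit(self, X, y=None) -> "CoherencePatternClassifier":
        """Fit on features (n_pairs, 2): contour integral, frequency width.

        Pairs with zero contour integral (no significant coherence in
        either window) are labelled ``none`` and excluded from the mixture.
        """
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] != 2:
            raise ValueError("expected features of shape (n_pairs, 2)")
        ci, width = X[:, 0], X[:, 1]
        nonzero = ci > 0
        if nonzero.sum() < 10:
            raise ValueError("need at least 10 pairs with nonzero features")
        logci = np.log10(ci[nonzero] + self.log_eps)
        gmm = fit_gmm_1d(logci)
        labels = np.array([NONE] * len(ci), dtype=object)
        posterior = np.zeros(len(ci))
        if gmm.unimodal:
            labels[nonzero] = NB
            posterior[nonzero] = 1.0
        else:
            nb_comp = int(np.argmin(gmm.means))
            assign_nb = gmm.responsibilities[:, nb_comp] >= 0.5
            sub = np.full(assign_nb.shape, BB, dtype=object)
            sub[assign_nb] = NB
            post = np.where(
                assign_nb,
                gmm.responsibilities[:, nb_comp],
                1.0 - gmm.responsibilities[:, nb_comp],
            )
            # width screen: Grubbs outliers above the width criterion -> BB
            nb_idx = np.flatnonzero(assign_nb)
            if nb_idx.size >= 3:
                flags = grubbs_test(width[nonzero][nb_idx], self.grubbs_alpha)
                wide = width[nonzero][nb_idx] > self.width_threshold
                sub[nb_idx[flags & wide]] = BB
            labels[nonzero] = sub
            posterior[nonzero] = post
            self.nb_component_ = nb_comp
        self.gmm_ = gmm
        self.labels_ = labels
        self.posterior_ = posterior
        self.unimodal_ = gmm.unimodal
        return self

    def fit_predict(self, X, y=None) -> np.ndarray:
        return self.fit(X).labels_

    def predict(self, X) -> np.ndarray:
        """Assign labels to new feature rows with the fitted mixture."""
        if not hasattr(self, "gmm_"):
            raise RuntimeError("classifier is not fitted")
        X = np.asarray(X, dtype=float)
        ci, width = X[:, 0], X[:, 1]
        labels = np.array([NONE] * len(ci), dtype=object)
        nonzero = ci > 0
        if self.unimodal_:
            labels[nonzero] = NB
            return labels
        logci = np.log10(ci[nonzero] + self.log_eps)
        comp, lse = _gmm_loglik(
            logci, self.gmm_.means, self.gmm_.variances, self.gmm_.weights
        )
        resp_nb = np.exp(comp - lse[:, None])[:, self.nb_component_]
        sub = np.where(resp_nb >= 0.5, NB, BB).astype(object)
        sub[(sub == NB) & (width[nonzero] > self.width_threshold)] = BB
        labels[nonzero] = sub
        return labels


# ------------------------------------------------------------------ latency
@dataclass
class OnsetLatency:
    """Coherence-onset latency: median over per-frequency earliest times."""

    latency_ms: float
    earliest_times: np.ndarray = field(repr=False)
    band: tuple[float, float] = (0.0, np.inf)


def onset_latency(
    cmap: WaveletCoherenceMap, band: tuple[float, float]
) -> OnsetLatency | None:
    """Median earliest significant time (ms, relative to alignment event).

    For every frequency bin inside ``band`` that contains significance, the
    earliest significant time is taken; the latency is the median of that
    distribution.  Returns None when no bin in the band is significant.
    """
    fsel = (cmap.freqs >= band[0]) & (cmap.freqs <= band[1])
    sig = cmap.significant[fsel]
    earliest = []
    for row in sig:
        idx = np.flatnonzero(row)
        if idx.size:
            earliest.append(cmap.times[idx[0]])
    if not earliest:
        return None
    earliest = np.asarray(earliest)
    return OnsetLatency(
        latency_ms=float(np.median(earliest) * 1000.0),
        earliest_times=earliest,
        band=band,
    )
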