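"""Multivariate autoregressive (MVAR) spectral causality.

A VAR(p) model ``y(n) = sum_k A_k y(n-k) + eps(n)`` is fitted by pooled
ordinary least squares across disjoint epoch segments (order fixed at
p = 15, i.e. 60 ms of history at 250 Hz).  Its frequency-domain transform

* ``A(f) = sum_k A_k exp(-i 2 pi f k T)``
* ``Abar(f) = I - A(f)``, ``H(f) = Abar(f)^-1``
* ``S(f) = H(f) V H(f)^H``

yields two complementary causality measures:

* **directed coherence** ``dc_{i<-j}(f) = |H_ij|^2 V_jj / S_ii`` -- total
  (direct + indirect) causal influence, normalized to the receiver, so
  rows sum to one for diagonal V; used for causality *detection* with the
  same per-bin significance threshold as ordinary coherence;
* **(generalized) partial directed coherence**
  ``pdc_{i<-j}(f) = (1/V_ii)|Abar_ij|^2 / sum_m (1/V_mm)|Abar_mj|^2`` --
  direct influence only, normalized to the sender (columns sum to one);
  the phase of ``Abar_ij(f)`` over the detected band supports constant-lag
  estimation that is robust inside closed loops.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator

from .coherence import DelayEstimate, delay_from_phase, significance_threshold
from .synth import companion_spectral_radius


# --------------------------------------------------------------- pure maths
def spectral_transform(
    coefs: np.ndarray, cov: np.ndarray, freqs: np.ndarray, fs: float
) -> dict[str, np.ndarray]:
    """Frequency-domain transform of VAR coefficients.

    Returns ``A``, ``Abar``, ``H`` and the spectral matrix ``S`` as
    (n_freqs, m, m) complex arrays.
    """
    coefs = np.asarray(coefs, dtype=float)
    cov = np.asarray(cov, dtype=float)
    freqs = np.asarray(freqs, dtype=float)
    p, m, _ = coefs.shape
    T = 1.0 / fs
    k = np.arange(1, p + 1)
    # (n_freqs, p) phase factors
    ph = np.exp(-2j * np.pi * freqs[:, None] * k[None, :] * T)
    A = np.tensordot(ph, coefs, axes=(1, 0))  # (n_freqs, m, m)
    Abar = np.eye(m)[None, :, :] - A
    H = np.linalg.inv(Abar)
    S = H @ cov[None, :, :] @ np.conj(np.swapaxes(H, 1, 2))
    return {"A": A, "Abar": Abar, "H": H, "S": S, "freqs": freqs}


def directed_coherence(transfer: dict[str, np.ndarray], cov: np.ndarray) -> np.ndarray:
    """Receiver-normalized directed coherence dc_{i<-j}(f), (n_freqs, m, m)."""
    H = transfer["H"]
    S = transfer["S"]
    s_ii = np.real(np.einsum("fii->fi", S))
    if np.any(s_ii <= 0):
        raise ValueError("non-positive receiver power encountered")
    v_jj = np.diag(np.asarray(cov, dtype=float))
    return np.abs(H) ** 2 * v_jj[None, None, :] / s_ii[:, :, None]


def partial_directed_coherence(
    transfer: dict[str, np.ndarray], cov: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Generalized PDC magnitudes and the complex direction terms Abar_ij.

    Weights are inverse residual variances 1/V_kk; columns (fixed sender j)
    sum to one at every frequency.
    """
    Abar = transfer["Abar"]
    v = np.diag(np.asarray(cov, dtype=float))
    if np.any(v <= 0):
        raise ValueError("residual variances must be positive")
    w = 1.0 / v
    num = w[None, :, None] * np.abs(Abar) ** 2
    den = num.sum(axis=1, keepdims=True)
    return num / np.maximum(den, 1e-300), Abar


# ---------------------------------------------------------------- estimator
@dataclass
class _FitData:
    coefs: np.ndarray
    cov: np.ndarray
    nobs: int


def _pooled_ols(segments: np.ndarray, order: int) -> _FitData:
    """Pooled least squares over disjoint segments, per-segment demeaned.

    Only predictions whose full lag history lies inside a segment enter the
    regression; the residual covariance carries a degrees-of-freedom
    correction for the m*p regression coefficients per equation.
    """
    segs = np.asarray(segments, dtype=float)
    if segs.ndim != 3:
        raise ValueError("segments must be (n_segments, n_samples, n_channels)")
    n_seg, n_samp, m = segs.shape
    p = order
    if p >= n_samp:
        raise ValueError("order must be smaller than the segment length")
    segs = segs - segs.mean(axis=1, keepdims=True)
    # lagged design: rows are (segment, t) with t = p..n_samp-1
    ys = segs[:, p:, :].reshape(-1, m)
    cols = [segs[:, p - k: n_samp - k, :].reshape(-1, m) for k in range(1, p + 1)]
    X = np.concatenate(cols, axis=1)  # (N, m*p)
    nobs = X.shape[0]
    B, *_ = np.linalg.lstsq(X, ys, rcond=None)
    rank = np.linalg.matrix_rank(X)
    if rank < m * p:
        raise ValueError("rank-deficient regressor matrix; cannot fit MVAR")
    resid = ys - X @ B
    dof = max(nobs - m * p, 1)
    cov = resid.T @ resid / dof
    coefs = B.reshape(p, m, m).transpose(0, 2, 1)  # A_k maps y(n-k) -> y(n)
    return _FitData(coefs=coefs, cov=cov, nobs=nobs)


class MVARCausality(BaseEstimator):
    """Bivariate (or small multichannel) MVAR spectral-causality estimator.

    Parameters
    ----------
    order : int
        Model order p (default 15; 60 ms at 250 Hz).
    fs : float
        Sampling rate of the segments (Hz).
    alpha : float
        Per-bin significance level for directed-coherence detection, on the
        convention that the DC significance limit is comparable with the
        ordinary-coherence threshold from L segments.

    Fitted attributes
    -----------------
    coef_ : (order, m, m) coefficient stack A_k
    resid_cov_ : (m, m) residual covariance V
    nobs_, n_segments_, spectral_radius_, stable_
    """

    def __init__(self, order: int = 15, fs: float = 250.0, alpha: float = 0.005):
        self.order = order
        self.fs = fs
        self.alpha = alpha

    def fit(self, X, y=None) -> "MVARCausality":
        """Fit on ``X`` of shape (n_segments, n_samples, n_channels)."""
        fitted = _pooled_ols(np.asarray(X), self.order)
        self.coef_ = fitted.coefs
        self.resid_cov_ = fitted.cov
        self.nobs_ = fitted.nobs
        self.n_segments_ = np.asarray(X).shape[0]
        self.n_channels_ = fitted.coefs.shape[1]
        self.spectral_radius_ = companion_spectral_radius(self.coef_)
        self.stable_ = bool(self.spectral_radius_ < 1.0)
        return self

    # ------------------------------------------------------------- measures
    def _check_fitted(self) -> None:
        if not hasattr(self, "coef_"):
            raise RuntimeError("estimator is not fitted")

    def default_freqs(self, n_fft: int = 128) -> np.ndarray:
        """Grid matching the 128-point segment-coherence bins (DC dropped)."""
        return np.fft.rfftfreq(n_fft, d=1.0 / self.fs)[1:]

    def transfer(self, freqs: np.ndarray | None = None) -> dict[str, np.ndarray]:
        self._check_fitted()
        freqs = self.default_freqs() if freqs is None else np.asarray(freqs)
        return spectral_transform(self.coef_, self.resid_cov_, freqs, self.fs)

    def directed_coherence(self, freqs: np.ndarray | None = None) -> np.ndarray:
        self._check_fitted()
        return directed_coherence(self.transfer(freqs), self.resid_cov_)

    def partial_directed_coherence(
        self, freqs: np.ndarray | None = None
    ) -> tuple[np.ndarray, np.ndarray]:
        self._check_fitted()
        return partial_directed_coherence(self.transfer(freqs), self.resid_cov_)

    def dc_threshold(self) -> float:
        self._check_fitted()
        return significance_threshold(self.alpha, self.n_segments_)

    def dc_significance(
        self, freqs: np.ndarray | None = None, band: tuple[float, float] | None = None
    ) -> np.ndarray:
        """Boolean (n_freqs, m, m) mask of DC-significant bins (off-diagonal)."""
        freqs = self.default_freqs() if freqs is None else np.asarray(freqs)
        dc = self.directed_coherence(freqs)
        mask = dc > self.dc_threshold()
        for i in range(mask.shape[1]):
            mask[:, i, i] = False
        if band is not None:
            inband = (freqs >= band[0]) & (freqs <= band[1])
            mask &= inband[:, None, None]
        return mask

    def phase_delay(
        self,
        target: int,
        source: int,
        freqs: np.ndarray | None = None,
        band: tuple[float, float] | None = None,
        min_bins: int = 3,
    ) -> DelayEstimate | None:
        """Constant-lag estimate for the direction ``source -> target``.

        The phase of the complex PDC direction term ``Abar_{target,source}``
        is unwrapped over the contiguous DC-significant bins (optionally
        restricted to ``band``) and regressed on frequency; the recovered
        ``tau_ms`` is the lag by which the source leads the target.
        """
        freqs = self.default_freqs() if freqs is None else np.asarray(freqs)
        _, Abar = self.partial_directed_coherence(freqs)
        mask = self.dc_significance(freqs, band)[:, target, source]
        phase = np.angle(Abar[:, target, source])
        return delay_from_phase(freqs, phase, mask, min_bins=min_bins)


def loop_time(eff: DelayEstimate | None, aff: DelayEstimate | None) -> float | None:
    """Round-trip time (ms): efferent + afferent delay, when both exist."""
    if eff is None or aff is None:
        return None
    return eff.tau_ms + aff.tau_ms
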