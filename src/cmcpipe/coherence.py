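"""Wavelet and fixed-window coherence with significance, phase and delay.

Two coherence estimators are provided:

* trial-averaged wavelet (Gabor) coherence over [-1, +0.5] s epochs around
  grip or release onset, for time-frequency pattern analysis;
* fixed-window segment coherence over 128-point (512 ms) windows, one
  segment per trial, for spectral comparison, phase and delay estimation.

The point-wise significance threshold for a coherence estimate from L
independent segments at level alpha is ``S = 1 - alpha**(1/(L-1))``
(Rosenberg-style); with alpha = 0.005 and L = 128 this gives S = 0.0409.

A constant conduction delay between two signals appears as a linear
phase-frequency relationship; the delay in ms is recovered from the fitted
slope A (rad/Hz) as ``tau = -(1000 / 2 pi) * A``.  A negative slope
(positive tau) means the first signal leads the second.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import fft as sp_fft
from scipy import stats


def phase_confidence_interval(coh: float | np.ndarray, L: int) -> np.ndarray:
    """95% half-width (rad) of a cross-spectral phase estimate.

    ``1.96 * sqrt((1/2L) (1/Coh - 1))``: zero at coherence one, unbounded
    as coherence vanishes.
    """
    coh = np.asarray(coh, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        return 1.96 * np.sqrt((1.0 / (2.0 * L)) * (1.0 / coh - 1.0))


def significance_threshold(alpha: float, L: int) -> float:
    """Point-wise coherence significance level from L disjoint segments."""
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must lie in (0, 1)")
    if L < 2:
        raise ValueError("at least two segments are required")
    return 1.0 - alpha ** (1.0 / (L - 1))


# ------------------------------------------------------------------- wavelet
@dataclass
class TimeFrequencyMap:
    """Complex Gabor coefficients per trial: (n_trials, n_freqs, n_times)."""

    coeffs: np.ndarray
    freqs: np.ndarray
    times: np.ndarray
    sigma: float
    edge_valid: np.ndarray  # (n_times,) False inside the cone of influence


def gabor_kernel(freq: float, fs: float, sigma: float = 0.128) -> np.ndarray:
    """Complex Gabor wavelet: Gaussian envelope (SD ``sigma`` s) carrier."""
    half = int(np.ceil(3.0 * sigma * fs))
    t = np.arange(-half, half + 1) / fs
    kern = np.exp(-(t**2) / (2.0 * sigma**2)) * np.exp(2j * np.pi * freq * t)
    return kern / np.abs(kern).sum()


def gabor_transform(
    epochs: np.ndarray,
    fs: float,
    freqs: np.ndarray,
    times: np.ndarray | None = None,
    sigma: float = 0.128,
    pad_samples: int = 0,
) -> TimeFrequencyMap:
    """Per-trial complex Gabor transform of trial-aligned epochs.

    ``epochs`` is (n_trials, n_samples) and may include ``pad_samples`` of
    real (or reflection-padded) context on each side which is trimmed from
    the output; samples whose wavelet support (2 sigma) extends beyond the
    padded data are flagged in ``edge_valid``.
    """
    epochs = np.atleast_2d(np.asarray(epochs, dtype=float))
    freqs = np.asarray(freqs, dtype=float)
    if np.any(freqs >= fs / 2) or np.any(freqs <= 0):
        raise ValueError("frequencies must lie in (0, Nyquist)")
    n_total = epochs.shape[1]
    n_core = n_total - 2 * pad_samples
    half = int(np.ceil(3.0 * sigma * fs))
    nfft = sp_fft.next_fast_len(n_total + 2 * half)
    sig_f = np.fft.fft(epochs, n=nfft, axis=-1)  # (n_trials, nfft)
    bank = np.stack([np.fft.fft(gabor_kernel(f, fs, sigma), n=nfft) for f in freqs])
    conv = np.fft.ifft(sig_f[:, None, :] * bank[None, :, :], axis=-1)
    start = half + pad_samples
    coeffs = conv[:, :, start: start + n_core]
    if times is None:
        times = np.arange(n_core) / fs
    guard = int(np.ceil(2.0 * sigma * fs)) - pad_samples
    edge_valid = np.ones(n_core, dtype=bool)
    if guard > 0:
        edge_valid[:guard] = False
        edge_valid[n_core - guard:] = False
    return TimeFrequencyMap(coeffs=coeffs, freqs=freqs, times=np.asarray(times),
                            sigma=sigma, edge_valid=edge_valid)


@dataclass
class WaveletCoherenceMap:
    """Trial-averaged time-frequency coherence with significance mask."""

    coh: np.ndarray  # (n_freqs, n_times) in [0, 1]
    freqs: np.ndarray
    times: np.ndarray
    n_trials: int
    alpha: float
    threshold: float
    edge_valid: np.ndarray

    @property
    def significant(self) -> np.ndarray:
        return (self.coh > self.threshold) & self.edge_valid[None, :]


def wavelet_coherence(
    x: TimeFrequencyMap, y: TimeFrequencyMap, alpha: float = 0.005
) -> WaveletCoherenceMap:
    """Coherence between two sets of trial-wise Gabor maps.

    ``|mean_j X_j conj(Y_j)|^2 / (P_X P_Y)`` with P the trial-averaged
    wavelet power; the significance threshold treats the N trials as the
    independent segments of the fixed-window estimator.
    """
    if x.coeffs.shape != y.coeffs.shape:
        raise ValueError("maps must share trial count and grids")
    n = x.coeffs.shape[0]
    if n < 2:
        raise ValueError("coherence needs at least two trials")
    cross = np.mean(x.coeffs * np.conj(y.coeffs), axis=0)
    px = np.mean(np.abs(x.coeffs) ** 2, axis=0)
    py = np.mean(np.abs(y.coeffs) ** 2, axis=0)
    coh = np.abs(cross) ** 2 / np.maximum(px * py, 1e-300)
    return WaveletCoherenceMap(
        coh=coh, freqs=x.freqs, times=x.times, n_trials=n, alpha=alpha,
        threshold=significance_threshold(alpha, n),
        edge_valid=x.edge_valid & y.edge_valid,
    )


# ----------------------------------------------------------- fixed segments
def mains_exclusion_mask(freqs: np.ndarray, mains: float | None,
                         half_width: float = 5.0) -> np.ndarray:
    """True for bins kept after deleting +/-5 Hz around the mains frequency."""
    freqs = np.asarray(freqs, dtype=float)
    if mains is None:
        return np.ones(freqs.shape, dtype=bool)
    return np.abs(freqs - mains) > half_width


@dataclass
class CoherenceSpectrum:
    """Fixed-window coherence with power, phase and confidence limits.

    Mains-contaminated bins are deleted and neighbours concatenated, so
    ``freqs`` may be non-contiguous; ``delta_f`` is the native resolution.
    """

    freqs: np.ndarray
    coh: np.ndarray
    power_x: np.ndarray  # one-sided, uV^2
    power_y: np.ndarray
    phase: np.ndarray
    phase_ci: np.ndarray  # 95% half-width (rad); NaN where undefined
    L: int
    alpha: float
    threshold: float
    delta_f: float
    mains_excluded: tuple[float, float] | None = None
    cross: np.ndarray = field(default=None, repr=False)

    @property
    def significant(self) -> np.ndarray:
        return self.coh > self.threshold


def segment_coherence(
    seg_x: np.ndarray,
    seg_y: np.ndarray,
    fs: float = 250.0,
    alpha: float = 0.005,
    mains: float | None = None,
    demean: bool = True,
) -> CoherenceSpectrum:
    """Coherence between two stacks of 128-point segments (one per trial).

    Power is one-sided with the 2/(Nfft^2 L) normalization (units uV^2 for
    uV inputs); the normalization cancels in the coherence.  The DC bin is
    dropped; mains bins (+/-5 Hz) are deleted when ``mains`` is given.
    """
    seg_x = np.atleast_2d(np.asarray(seg_x, dtype=float))
    seg_y = np.atleast_2d(np.asarray(seg_y, dtype=float))
    if seg_x.shape != seg_y.shape:
        raise ValueError("segment stacks must have identical shape")
    L, n = seg_x.shape
    if L < 2:
        raise ValueError("at least two segments are required")
    if demean:
        seg_x = seg_x - seg_x.mean(axis=1, keepdims=True)
        seg_y = seg_y - seg_y.mean(axis=1, keepdims=True)
    fx = np.fft.rfft(seg_x, axis=1)
    fy = np.fft.rfft(seg_y, axis=1)
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    norm = 2.0 / (n**2 * L)
    px = norm * np.sum(np.abs(fx) ** 2, axis=0)
    py = norm * np.sum(np.abs(fy) ** 2, axis=0)
    cross = np.sum(np.conj(fx) * fy, axis=0)
    sxx = np.sum(np.abs(fx) ** 2, axis=0)
    syy = np.sum(np.abs(fy) ** 2, axis=0)
    coh = np.abs(cross) ** 2 / np.maximum(sxx * syy, 1e-300)

    keep = mains_exclusion_mask(freqs, mains) & (freqs > 0)
    freqs, coh, px, py, cross = (a[keep] for a in (freqs, coh, px, py, cross))
    phase = np.angle(cross)
    ci = np.where(coh > 0, phase_confidence_interval(coh, L), np.nan)
    phase = np.where(np.abs(cross) > 0, phase, np.nan)
    return CoherenceSpectrum(
        freqs=freqs, coh=coh, power_x=px, power_y=py, phase=phase,
        phase_ci=ci, L=L, alpha=alpha,
        threshold=significance_threshold(alpha, L),
        delta_f=fs / n,
        mains_excluded=(mains - 5.0, mains + 5.0) if mains is not None else None,
        cross=cross,
    )


def phase_and_confidence(spectrum: CoherenceSpectrum) -> tuple[np.ndarray, np.ndarray]:
    """Cross-spectral phase and its 95% confidence half-width (rad)."""
    return spectrum.phase, spectrum.phase_ci


# ------------------------------------------------------------ delay fitting
@dataclass
class DelayEstimate:
    """Constant-delay estimate from a phase-frequency regression.

    ``tau_ms = -(1000 / 2 pi) * slope``; positive tau means the first
    (reference) signal leads.  ``significant`` gates the fixed-delay claim
    on the slope t-test at p < 0.05.
    """

    tau_ms: float
    slope: float  # rad/Hz
    intercept: float
    p_value: float
    band: tuple[float, float]
    n_bins: int

    @property
    def significant(self) -> bool:
        return bool(np.isfinite(self.p_value) and self.p_value < 0.05)


def longest_run(mask: np.ndarray) -> int:
    """Length of the longest run of True values (0 for an empty mask)."""
    run = _longest_true_run(np.asarray(mask, dtype=bool))
    return 0 if run is None else run[1] - run[0]


def _longest_true_run(mask: np.ndarray) -> tuple[int, int] | None:
    best = None
    i = 0
    n = len(mask)
    while i < n:
        if mask[i]:
            j = i
            while j < n and mask[j]:
                j += 1
            if best is None or j - i > best[1] - best[0]:
                best = (i, j)
            i = j
        else:
            i += 1
    return best


def delay_from_phase(
    freqs: np.ndarray,
    phase: np.ndarray,
    sig_mask: np.ndarray,
    min_bins: int = 3,
) -> DelayEstimate | None:
    """Fit a line to the unwrapped phase over the longest significant band.

    Returns None (no estimate) when fewer than ``min_bins`` contiguous
    significant bins are available.
    """
    freqs = np.asarray(freqs, dtype=float)
    phase = np.asarray(phase, dtype=float)
    run = _longest_true_run(np.asarray(sig_mask, dtype=bool))
    if run is None or run[1] - run[0] < min_bins:
        return None
    i0, i1 = run
    f = freqs[i0:i1]
    ph = np.unwrap(phase[i0:i1])
    res = stats.linregress(f, ph)
    return DelayEstimate(
        tau_ms=-1000.0 / (2.0 * np.pi) * res.slope,
        slope=float(res.slope),
        intercept=float(res.intercept),
        p_value=float(res.pvalue),
        band=(float(f[0]), float(f[-1])),
        n_bins=i1 - i0,
    )
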