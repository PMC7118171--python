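"""Raw-session conditioning: filtering, downsampling, event detection,
cross-talk screening, and epoch extraction.

All filtering is zero-phase (forward-backward ``sosfiltfilt``): the
pipeline's core outputs are phase lags, and a causal filter would add a
direction-asymmetric phase shift.

Target analysis rate is 250 Hz (sampling interval T = 4 ms).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal
from scipy.ndimage import uniform_filter1d

log = logging.getLogger(__name__)

ANALYSIS_FS = 250.0


# ----------------------------------------------------------- event detection
@dataclass
class EventTable:
    """Per-trial grip / release onsets (s, from trial start); NaN = dropped."""

    grip_onset: np.ndarray
    release_onset: np.ndarray
    rate_threshold: float = 2.0

    @property
    def valid(self) -> np.ndarray:
        return np.isfinite(self.grip_onset) & np.isfinite(self.release_onset)


def _sustained_crossing(above: np.ndarray, n_sustain: int) -> int | None:
    """First index where ``above`` holds for ``n_sustain`` consecutive samples."""
    if n_sustain <= 1:
        idx = np.flatnonzero(above)
        return int(idx[0]) if idx.size else None
    run = np.convolve(above.astype(int), np.ones(n_sustain, dtype=int), mode="valid")
    idx = np.flatnonzero(run == n_sustain)
    return int(idx[0]) if idx.size else None


def force_rate(force: np.ndarray, fs: float, smooth_ms: float = 10.0) -> np.ndarray:
    """Smoothed force rate (N/s): central difference + moving average."""
    rate = np.gradient(np.asarray(force, dtype=float)) * fs
    n = max(1, int(round(smooth_ms * fs / 1000.0)))
    return uniform_filter1d(rate, size=n, mode="nearest")


def detect_trial_events(
    force: np.ndarray,
    fs: float = 1000.0,
    threshold: float = 2.0,
    sustain_ms: float = 50.0,
    smooth_ms: float = 10.0,
) -> tuple[float, float] | None:
    """Grip and release onset for one trial, or None when no crossing.

    Grip onset: first time the smoothed force rate exceeds ``threshold``
    and stays above it for ``sustain_ms``.  Release onset: the analogous
    sustained crossing below ``-threshold`` after the grip onset.
    """
    rate = force_rate(force, fs, smooth_ms)
    n_sustain = max(1, int(round(sustain_ms * fs / 1000.0)))
    ig = _sustained_crossing(rate > threshold, n_sustain)
    if ig is None:
        return None
    ir = _sustained_crossing(rate[ig:] < -threshold, n_sustain)
    if ir is None:
        return None
    return ig / fs, (ig + ir) / fs


def detect_events(
    force_trials: list[np.ndarray],
    fs: float = 1000.0,
    threshold: float = 2.0,
    sustain_ms: float = 50.0,
    smooth_ms: float = 10.0,
) -> EventTable:
    """Detect grip/release onsets on every trial's force trace."""
    grip = np.full(len(force_trials), np.nan)
    release = np.full(len(force_trials), np.nan)
    for i, tr in enumerate(force_trials):
        ev = detect_trial_events(tr, fs, threshold, sustain_ms, smooth_ms)
        if ev is None:
            log.info("trial %d: no sustained force-rate crossing; dropped", i)
            continue
        grip[i], release[i] = ev
    return EventTable(grip_onset=grip, release_onset=release, rate_threshold=threshold)


# ------------------------------------------------------------------ filtering
def preprocess_lfp(
    trace: np.ndarray,
    fs_in: float = 20000.0,
    fs_out: float = ANALYSIS_FS,
    band: tuple[float, float] = (3.0, 100.0),
) -> np.ndarray:
    """Band-pass (4th-order Butterworth, zero-phase) and decimate an LFP.

    The pass band (3-100 Hz) already bounds spectral content below the
    output Nyquist (125 Hz), so decimation is plain subsampling.
    """
    trace = np.asarray(trace, dtype=float)
    factor = fs_in / fs_out
    if abs(factor - round(factor)) > 1e-9:
        raise ValueError("fs_in must be an integer multiple of fs_out")
    if len(trace) < 3 * fs_in / band[0]:
        raise ValueError("trace shorter than three filter time-constants")
    sos = signal.butter(4, band, btype="band", fs=fs_in, output="sos")
    return signal.sosfiltfilt(sos, trace)[:: int(round(factor))]


def emg_bin_cutoff(bin_size: int, fs: float) -> float:
    """Effective low-pass cut-off of M-bin averaging: Fc = 0.443/M * Fs."""
    return 0.443 / bin_size * fs


def preprocess_emg(
    trace: np.ndarray,
    fs_in: float = 5000.0,
    highpass: float = 30.0,
    bin_size: int = 20,
) -> np.ndarray:
    """High-pass, rectify, and bin-average an EMG to a 250 Hz envelope.

    Zero-phase 4th-order Butterworth high-pass at 30 Hz, full-wave
    rectification, then non-overlapping ``bin_size``-sample means (an
    implicit low-pass at ~110 Hz for M = 20 at 5 kHz).  A trailing
    remainder shorter than one bin is dropped.
    """
    trace = np.asarray(trace, dtype=float)
    if len(trace) < 3 * fs_in / highpass:
        raise ValueError("trace shorter than three filter time-constants")
    sos = signal.butter(4, highpass, btype="high", fs=fs_in, output="sos")
    rectified = np.abs(signal.sosfiltfilt(sos, trace))
    n_bins = len(rectified) // bin_size
    if n_bins * bin_size != len(rectified):
        log.debug("dropping %d trailing samples", len(rectified) - n_bins * bin_size)
    return rectified[: n_bins * bin_size].reshape(n_bins, bin_size).mean(axis=1)


# -------------------------------------------------------- cross-talk screen
def crosstalk_index(
    emg_a: np.ndarray,
    emg_b: np.ndarray,
    fs: float = 1000.0,
    max_lag_ms: float = 25.0,
    n_diff: int = 3,
) -> tuple[np.ndarray, np.ndarray]:
    """Cross-talk correlation function r(tau) on thrice-differenced EMGs.

    Returns (lags in s, r) over tau in [-25, +25] ms; the screening index is
    max |r(tau)|.  Differentiation is first-order differencing applied
    ``n_diff`` times, which whitens genuine EMG but leaves instantaneous
    electrical mixing fully correlated.
    """
    a = np.diff(np.asarray(emg_a, dtype=float), n=n_diff)
    b = np.diff(np.asarray(emg_b, dtype=float), n=n_diff)
    if len(a) != len(b):
        raise ValueError("EMG traces must have equal length")
    max_lag = int(round(max_lag_ms * fs / 1000.0))
    a = (a - a.mean()) / max(a.std(), 1e-300)
    b = (b - b.mean()) / max(b.std(), 1e-300)
    n = len(a)
    full = signal.correlate(a, b, mode="full") / n
    mid = n - 1
    lags = np.arange(-max_lag, max_lag + 1)
    return lags / fs, full[mid + lags]


@dataclass
class CrosstalkResult:
    """Pairwise cross-talk indices and the per-channel exclusion decision."""

    table: pd.DataFrame  # columns: emg_a, emg_b, rmax, excluded
    excluded: set[str] = field(default_factory=set)
    threshold: float = 0.25


def _to_1khz(trace: np.ndarray, fs: float) -> tuple[np.ndarray, float]:
    if fs > 1000.0:
        factor = fs / 1000.0
        if abs(factor - round(factor)) < 1e-9:
            return signal.resample_poly(trace, 1, int(round(factor))), 1000.0
        return signal.resample_poly(trace, 1000, int(round(fs))), 1000.0
    return trace, fs


def crosstalk_screen(
    emgs: dict[str, np.ndarray],
    fs: float = 5000.0,
    threshold: float = 0.25,
    seed: int | np.random.Generator = 0,
    epoch_s: float = 60.0,
) -> CrosstalkResult:
    """Screen every simultaneous EMG pair for electrical cross-talk.

    Signals are brought to 1 kHz, differentiated three times (no
    rectification) and cross-correlated over +/-25 ms on a 1-minute epoch.
    When max |r| exceeds ``threshold``, one channel of the pair is excluded
    by a seeded random draw.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    prepared: dict[str, np.ndarray] = {}
    for label, tr in emgs.items():
        x, fs_eff = _to_1khz(np.asarray(tr, dtype=float), fs)
        if len(x) < epoch_s * fs_eff:
            warnings.warn(
                f"EMG {label!r}: epoch shorter than {epoch_s:.0f} s; "
                "cross-talk index computed on available length",
                stacklevel=2,
            )
        prepared[label] = x[: int(epoch_s * fs_eff)]
    labels = sorted(prepared)
    rows = []
    excluded: set[str] = set()
    for i, la in enumerate(labels):
        for lb in labels[i + 1:]:
            _, r = crosstalk_index(prepared[la], prepared[lb], fs=1000.0)
            rmax = float(np.max(np.abs(r)))
            victim = ""
            if rmax > threshold:
                pair = (la, lb)
                candidates = [c for c in pair if c not in excluded]
                if candidates and not set(pair) & excluded:
                    victim = candidates[int(rng.integers(len(candidates)))]
                    excluded.add(victim)
            rows.append({"emg_a": la, "emg_b": lb, "rmax": rmax, "excluded": victim})
    return CrosstalkResult(
        table=pd.DataFrame(rows, columns=["emg_a", "emg_b", "rmax", "excluded"]),
        excluded=excluded,
        threshold=threshold,
    )


# ------------------------------------------------------------------- epochs
def extract_epochs(
    trials: list[np.ndarray],
    events: np.ndarray,
    window: tuple[float, float],
    fs: float = ANALYSIS_FS,
    pad: float = 0.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Trial-aligned, half-open windows ``[start, stop)`` around per-trial events.

    Returns (epochs, trial_indices).  ``pad`` extends the cut on both sides
    (for wavelet edge handling); where padded samples would fall outside a
    trial, the trial signal is reflection-padded.  Trials whose *unpadded*
    window falls outside the recording, or with NaN events, are dropped.
    """
    n_core = int(round((window[1] - window[0]) * fs))
    n_pad = int(round(pad * fs))
    epochs, kept = [], []
    for i, (tr, ev) in enumerate(zip(trials, events)):
        if not np.isfinite(ev):
            continue
        i0 = int(round((ev + window[0]) * fs))
        if i0 < 0 or i0 + n_core > len(tr):
            log.info("trial %d: window outside recording; dropped", i)
            continue
        j0, j1 = i0 - n_pad, i0 + n_core + n_pad
        lo = max(0, -j0)
        hi = max(0, j1 - len(tr))
        seg = tr[j0 + lo: j1 - hi]
        if lo or hi:
            seg = np.pad(seg, (lo, hi), mode="reflect")
        epochs.append(seg)
        kept.append(i)
    if not epochs:
        return np.empty((0, n_core + 2 * n_pad)), np.array([], dtype=int)
    return np.asarray(epochs), np.asarray(kept, dtype=int)
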