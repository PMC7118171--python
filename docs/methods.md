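# Methods

This note documents the models, estimators, parameter choices, and known
limitations of `cmcpipe`. Everything stated here is computed by the test
suite or by `scripts/acceptance.py`; nothing is quoted from data the
package does not generate itself.

## Signal model and preprocessing

The pipeline operates on multi-trial grip–hold sessions: LFP channels
(natively 20 kHz), EMG channels (5 kHz), and an aggregate grip-force trace
(1 kHz), with a trial structure of rest (1.0–2.0 s), grip ramp, hold
(1.0–2.0 s), and release.

* **LFP conditioning** — zero-phase 4th-order Butterworth band-pass
  3–100 Hz, then plain subsampling to 250 Hz (the pass band already lies
  below the 125 Hz output Nyquist, so no extra anti-alias stage is
  needed).
* **EMG conditioning** — zero-phase 4th-order Butterworth high-pass at
  30 Hz, full-wave rectification, then non-overlapping 20-bin averaging
  to 250 Hz. Bin averaging is an implicit low-pass with
  Fc = 0.443/M·Fs ≈ 110 Hz for M = 20, Fs = 5 kHz.
* **Zero-phase filtering everywhere** — the pipeline's core outputs are
  phase *lags*; a causal filter would add a direction-asymmetric phase
  shift and bias every delay estimate. Forward–backward `sosfiltfilt` is
  used for all filters.
* **Event detection** — the force rate is a central difference smoothed by
  a 10 ms moving average; grip onset is the first crossing above +2 N/s
  sustained for 50 ms, release onset the analogous crossing below −2 N/s.
  Raw differencing of noisy force triggers spuriously; the smoothing and
  sustain criterion are the package's choices (validated: ramp onsets are
  recovered within ±20 ms; sub-threshold plateau jitter never triggers).
* **Cross-talk screen** — every simultaneous EMG pair is brought to 1 kHz,
  differentiated three times (first differences applied three times, which
  whitens genuine EMG but leaves instantaneous electrical mixing
  correlated), and cross-correlated over ±25 ms lags on a 1-minute epoch.
  If max |r| > 0.25 one channel of the pair is excluded by a seeded random
  draw, so the exclusion is reproducible.

## Coherence estimators

* **Fixed-window (segment) coherence** uses one 128-point segment per
  trial (grip window 0–512 ms after grip onset; hold window 768–256 ms
  before release onset), rectangular window (no taper), per-segment
  demeaning, one-sided power normalized by 2/(N_fft²·L) (the
  normalization cancels in the coherence). The frequency resolution is
  250/128 = 1.953125 Hz. Mains contamination is handled spectrally: bins
  within ±5 Hz of 50 or 60 Hz are deleted and the neighbouring frequencies
  concatenated, never interpolated.
* **Significance** — the point-wise threshold for L independent segments
  at level α is S = 1 − α^(1/(L−1)). The stringent α = 0.005 (S = 0.0409
  at L = 128) is used because the analysis cares about coherent *bands*;
  isolated significant bins are expected point-wise false positives. A
  pair is considered to carry coherence only when at least two contiguous
  fixed-window bins are significant.
* **Wavelet coherence** uses complex Gabor kernels with a Gaussian
  envelope of SD σ = 128 ms on epochs spanning −1 to +0.5 s around grip or
  release onset, on a 2–100 Hz grid in 1 Hz steps. Epoch cuts carry 0.5 s
  of real context on each side so wavelet support does not run off the
  analysis window; where context is unavailable the signal is
  reflection-padded and the affected samples are flagged (cone of
  influence). Significance re-uses the segment formula with L replaced by
  the trial count.
* **Phase and confidence** — the cross-spectral phase θ(f) = arg Σ F₁*F₂
  carries 95% limits Δθ = 1.96·√((1/2L)(1/Coh − 1)).

Calibration: for independent inputs with L = 128, the per-bin rate of
exceeding S(0.005, 128) is 0.005 within a 99% binomial interval over >10⁴
simulated bins (test suite).

## MVAR causality and delay estimation

A VAR(p) model with p = 15 (60 ms of history at 250 Hz) is fitted by
ordinary least squares pooled across disjoint 128-point segments, with
per-segment demeaning (epochs have phase-dependent offsets); only
predictions whose full lag history lies inside a segment enter the
regression, and the residual covariance carries a degrees-of-freedom
correction. Stability is checked via the companion-matrix spectral radius.

From A(f) = Σₖ Aₖ e^(−i2πfkT), Ā(f) = I − A(f), H(f) = Ā(f)⁻¹ and
S(f) = H V Hᴴ the package computes:

* **Directed coherence** γ_{i←j}(f) = |H_ij(f)|²·V_jj / S_ii(f), with V_jj
  the innovation variance of the source. This receiver-side normalization
  satisfies Σⱼ γ_{i←j}(f) = 1 for diagonal V (verified to 1e−10 on random
  stable models). DC detects causal direction: a direction counts as
  significant when ≥2 bins in the analysis band exceed the
  ordinary-coherence threshold for L segments (the DC significance limit
  is taken as comparable to the coherence limit).
* **Generalized PDC** π_{i←j}(f) = (1/V_ii)|Ā_ij|² / Σₘ (1/V_mm)|Ā_mj|²,
  sender-normalized (columns sum to 1), nonzero iff direct coupling
  coefficients exist. Because Ā_ij collects only the direct cross
  coefficients, its phase is robust to closed-loop recirculation, which
  biases delay estimates read from H(f).
* **Delay** — the phase arg Ā_ij(f), unwrapped over the longest contiguous
  run of DC-significant bins (≥3 required), is regressed on frequency;
  τ = −(1000/2π)·slope, gated by the slope t-test at p < 0.05. Positive τ
  means the source leads the target. Delays are invariant to channel gain
  rescaling.

Validation (test suite): an 8 ms programmed efferent conduction delay is
recovered within ±2 ms; a 30/27 ms bidirectional beta loop within ±4 ms
per direction with a round trip within 57 ± 6 ms; fitted-model DC matches
the closed-form DC of the generating coefficients within 0.02 RMS; on 200
unidirectional fixtures the programmed direction is the only significant
one in ≥95% of cases.

## Pattern classification

Features per pair: the contour integral (for levels from S to 1 in 0.01
steps, the significant area — bin count × Δt × Δf — at or above each
level, summed; windows 0–1 s from grip onset and −1–0 s from release
onset) and the frequency width of the significant fixed-window band,
measured as the *longest contiguous* significant run × Δf so isolated
false-positive or harmonic bins do not inflate a narrow band.

The mixture is fitted on log₁₀(contour integral + ε): the feature is
positive and spans orders of magnitude between beta-limited and broadband
patterns. EM is deterministic (means initialized at the 25th/75th
percentiles, equal weights, data variance; tolerance 1e−8; ≤500
iterations; variance floor 1e−6 of the data variance; the log-likelihood
trace is retained and non-decreasing). Unimodality is decided by
BIC(1) ≤ BIC(2), in which case all banded pairs are NB — the typical
cortical population. Otherwise the smaller-mean component is NB, and NB
members flagged by an iterative two-sided Grubbs test (α = 0.05) on width
*and* wider than 25 Hz are reassigned BB.

Pairs with fewer than two contiguous significant bins in both windows are
labelled `none`. When fewer than 10 banded pairs are available (a mixture
cannot be fitted meaningfully), the pipeline falls back to the 25 Hz width
rule alone; the result bundle records which rule was applied.

Coherence-onset latency is the median over in-band frequency bins of the
earliest significant time in the wavelet map, reported in ms relative to
grip onset (negative = before onset); BB latencies use the full 2–100 Hz
band, NB latencies the 15–30 Hz beta band.

## Group statistics

* **Pooled significance** — per frequency, the proportion of pairs whose
  coherence exceeds S; the significance limit is the smallest k/n whose
  exact binomial tail P(Bin(n, 0.005) ≥ k) is below 0.05. The exact tail
  is used because the 0.005 base rate is far outside the normal
  approximation's validity (n = 100 gives k = 3).
* **Coherence-difference test** — Z(f) compares bias-corrected
  atanh-transformed group-mean coherences with DF = 2 × pairs × bins per
  group; whole pairs (entire spectra) are permuted between groups 10,000
  times, preserving within-pair frequency correlation, and the 2.5th/97.5th
  percentiles per frequency form the significance envelope.
* **Circular statistics** — Rayleigh test for non-uniformity of per-pair
  phase angles (each pair contributes the circular mean of θ(f) over its
  significant beta bins), and the Mardia–Watson–Wheeler uniform-scores
  test (χ² with 2 df) for two-group inhomogeneity.
* **Latency comparison** — Welch t-test (unequal variances) between BB and
  NB onset-latency distributions.
* **Intermuscle connections** — muscles co-significant at one recording
  site form unordered pairs; counts accumulate over sites.

All tests hold their nominal type-I error under seeded null simulations
within 99% binomial tolerance (test suite).

## Synthetic sessions: what they emulate and what they do not

The generator produces ground-truth-labelled sessions with the statistical
structure the analysis assumes — it makes no biophysical claims. Per
LFP–EMG pair one of three regimes applies:

* `broadband_efferent` — the muscle drive is a gain-scaled copy of a
  broadband LFP at a fixed conduction delay (default 8 ms) plus
  independent noise, active over the whole trial: the motoneuron-pool
  signature.
* `beta_loop` — a bivariate system with AR(2) resonant-pole innovations
  centred mid-band (default 20 Hz carrier via poles of modulus 0.95),
  cross-coupled LFP→EMG at the efferent lag (default 30 ms) and EMG→LFP at
  the afferent lag (default 27 ms) with gains 0.04. Keeping the joint
  system a finite-order VAR means a closed-form oracle spectrum exists for
  every fixture. Cross-gains are multiplied by a 50 ms raised-cosine gate
  over the grip or hold epoch, so phase-restricted coherence carries no
  edge transients. Stability (companion spectral radius < 1) is asserted
  at construction.
* `uncoupled` — independent noises; the calibration null.

**EMG envelope model.** Muscle output is returned as a nonnegative
envelope: half-wave-rectified (tonic baseline + oscillatory drive) plus
amplitude noise, with the baseline at two drive SDs. The analysis consumes
rectified EMG, and an envelope with a tonic level under the oscillation is
what rectified EMG of an active muscle looks like; crucially, clipping is
rare at this baseline, so the drive — and with it every programmed
conduction delay — survives linearly into the envelope. Rectifying the
zero-mean drive itself would clip half the waveform and measurably bias
recovered efferent delays (≈ +8 ms in our measurements), which is why that
variant is not used. Residual clipping and amplitude noise still produce
weak harmonic coherence away from the main band, which is one reason the
band width feature uses the longest contiguous run.

**Two generation levels.** The coupling engine always runs at 250 Hz.
Native-rate sessions upsample the LFP to 20 kHz (plus high-frequency
noise) and synthesize interference EMG at 5 kHz as the envelope modulating
a 30 Hz–2 kHz broadband carrier, exercising the preprocessing chain; the
250 Hz path feeds the analysis mathematics directly and keeps tests fast.
Force traces are piecewise ramps (default 5 N/s up, −6 N/s down, well
beyond the ±2 N/s detection threshold) with 10 Hz-low-passed sensor noise
of 0.01 N SD.

**Seeding.** One root seed; timing, force, per-pair, extra-EMG and
raw-noise streams are spawned from it in a fixed order, and per-trial
streams are spawned per pair, so identical (scenario, seed) reproduce
byte-identical sessions.

**What passing tests do not show.** The generator's regimes are linear
(plus rectification); real LFP–EMG coupling is nonstationary within
phases, subject to amplitude–phase coupling, volume conduction, and
electrode artifacts none of which are modelled. Recovery of programmed
delays and labels therefore certifies the *estimators*, not the
interpretation of any particular biological dataset. Empirical quantities
of real recordings (pair counts, peak frequencies, median delays) are
data-dependent and outside what synthetic validation can establish.

## Numerical choices and problem sizes

* Delays are quantized to the 4 ms sampling interval; a programmed 30/27 ms
  loop is representable as 32/28 ms, and recovery tolerances (±1 sample
  + regression error) account for this.
* Delay-recovery fixtures use 128 trials (broadband) and 512 trials pooled
  over both windows (beta loop): slope noise at smaller sizes is of the
  same order as the quantization error, and these sizes put the estimator
  noise well inside it. Calibration suites use ≥10⁴ bins; direction
  detection uses 200 fixtures of 64 trials; phase-specificity uses 50
  fixtures of 100 trials (the minimum trial count the pipeline itself enforces).
* EM variance floor 1e−6 of data variance; degenerate inputs (all-equal
  samples, zero-variance groups, constant phase) return defined, flagged
  results rather than NaNs.
* Site pooling merges LFPs within 150 μm by single linkage and averages
  member trials.

## Known limitations

* No multitaper spectra, no LFP–LFP coherence, no time-varying MVAR, no
  model-order selection (p is fixed at 15 by design).
* The DC significance limit re-uses the ordinary-coherence threshold; a
  surrogate-based limit would be more exact but is not implemented.
* The Z-difference test's degrees of freedom follow the stated
  2 × pairs × bins convention; its inference is therefore calibrated by
  the permutation envelope, not by the asymptotic normal scale.
* With fewer than 10 banded pairs the NB/BB decision degrades to the fixed
  25 Hz width rule.
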