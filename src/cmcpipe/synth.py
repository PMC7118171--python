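"""Ground-truth-labelled synthetic grip-task sessions.

The generator emulates the statistical structure the analysis pipeline
assumes, without modelling biophysics.  Three coupling regimes are available
per LFP-EMG pair:

``broadband_efferent``
    The LFP stands in for motoneuron-pool activity: the muscle drive is a
    gain-scaled copy of the broadband LFP at a fixed conduction delay plus
    independent noise, active over the whole trial.

``beta_loop``
    A bivariate discrete-time system whose innovations are shaped by AR(2)
    resonant poles centred in the beta band; cross-coupling terms
    (LFP->EMG at the efferent lag, EMG->LFP at the afferent lag) are gated
    to the dynamic grip or static hold phase by a 50 ms raised-cosine
    envelope so phase-restricted coherence carries no edge transients.

``uncoupled``
    Independent noises; the null for calibration tests.

Muscle output is returned as a nonnegative envelope
(baseline + half-wave-rectified drive + noise), mimicking rectified,
bin-averaged EMG: the analysis consumes rectified EMG, and rectifying a raw
synthetic signal downstream would distort programmed delays.  The
half-wave rectification keeps half of the drive linearly, so programmed
lags survive into the envelope.

Sessions can be generated directly at the 250 Hz analysis rate (fast path
for coherence/causality tests) or at native rates (20 kHz LFP, 5 kHz EMG,
1 kHz force) for preprocessing tests; both share one coupling engine.

Seeding: one root seed; per-trial and per-channel-group streams are derived
with ``numpy.random.SeedSequence.spawn`` in a fixed order, so identical
(config, seed) reproduce identical samples.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
from scipy import signal

from .session import Channel, SessionDataset, TrialTiming, LFP, EMG, FORCE

REGIMES = ("broadband_efferent", "beta_loop", "uncoupled")


@dataclass
class CouplingSpec:
    """Ground-truth coupling between one LFP and one EMG channel.

    Delays are in milliseconds, gains dimensionless, ``band`` in Hz.
    ``active_phase`` restricts the cross-coupling of a beta loop to the
    dynamic grip or static hold epoch (broadband coupling is always
    phase-unrestricted).
    """

    regime: str = "uncoupled"
    efferent_delay: float = 8.0
    afferent_delay: float = 27.0
    efferent_gain: float = 0.04
    afferent_gain: float = 0.04
    band: tuple[float, float] = (15.0, 30.0)
    active_phase: str = "both"
    pole_modulus: float = 0.95
    noise_sd: float = 1.0

    def __post_init__(self) -> None:
        if self.regime not in REGIMES:
            raise ValueError(f"unknown regime {self.regime!r}")
        if self.efferent_delay < 0 or self.afferent_delay < 0:
            raise ValueError("delays must be nonnegative")
        if self.active_phase not in ("grip", "hold", "both"):
            raise ValueError(f"unknown active_phase {self.active_phase!r}")
        if not 0 < self.band[0] < self.band[1]:
            raise ValueError("band must be an increasing positive interval")

    # ------------------------------------------------------------ linear part
    def delay_samples(self, fs: float) -> tuple[int, int]:
        d_eff = int(round(self.efferent_delay * fs / 1000.0))
        d_aff = int(round(self.afferent_delay * fs / 1000.0))
        return d_eff, d_aff

    def ar2_poly(self, fs: float) -> tuple[float, float]:
        """AR(2) recursion coefficients for a resonance at mid-band."""
        f0 = 0.5 * (self.band[0] + self.band[1])
        if f0 >= fs / 2:
            raise ValueError("band centre above Nyquist")
        w = 2.0 * np.pi * f0 / fs
        r = self.pole_modulus
        return 2.0 * r * np.cos(w), -(r * r)

    def var_coefficients(self, fs: float) -> tuple[np.ndarray, np.ndarray]:
        """True VAR coefficient stack (p, 2, 2) and innovation covariance.

        Channel order (lfp, emg-drive); the cross-gains are taken at their
        active (gate = 1) value.  This is the closed-form oracle for
        spectral-causality tests.
        """
        if self.regime == "broadband_efferent":
            d_eff, _ = self.delay_samples(fs)
            if d_eff < 1:
                raise ValueError("efferent delay below one sample")
            A = np.zeros((d_eff, 2, 2))
            A[d_eff - 1, 1, 0] = self.efferent_gain
            V = np.diag([self.noise_sd**2, self.noise_sd**2])
            return A, V
        if self.regime == "uncoupled":
            return np.zeros((1, 2, 2)), np.diag([self.noise_sd**2] * 2)
        c1, c2 = self.ar2_poly(fs)
        d_eff, d_aff = self.delay_samples(fs)
        if min(d_eff, d_aff) < 1:
            raise ValueError("beta-loop delay below one sample at this rate")
        p = max(2, d_eff, d_aff)
        A = np.zeros((p, 2, 2))
        A[0, 0, 0] = A[0, 1, 1] = c1
        A[1, 0, 0] = A[1, 1, 1] = c2
        A[d_aff - 1, 0, 1] += self.afferent_gain
        A[d_eff - 1, 1, 0] += self.efferent_gain
        V = np.diag([self.noise_sd**2, self.noise_sd**2])
        return A, V

    def companion_radius(self, fs: float) -> float:
        A, _ = self.var_coefficients(fs)
        return companion_spectral_radius(A)

    def require_stable(self, fs: float) -> None:
        rho = self.companion_radius(fs)
        if rho >= 1.0:
            raise ValueError(
                f"unstable coupling spec (companion spectral radius {rho:.3f})"
            )


def companion_spectral_radius(coefs: np.ndarray) -> float:
    """Spectral radius of the companion matrix of a VAR coefficient stack."""
    p, m, _ = coefs.shape
    comp = np.zeros((m * p, m * p))
    comp[:m, :] = np.concatenate(list(coefs), axis=1)
    if p > 1:
        comp[m:, :-m] = np.eye(m * (p - 1))
    return float(np.max(np.abs(np.linalg.eigvals(comp))))


def simulate_var(
    coefs: np.ndarray, cov: np.ndarray, n_samples: int, rng: np.random.Generator,
    burn_in: int = 200,
) -> np.ndarray:
    """Simulate a stationary VAR process; returns (n_samples, m)."""
    p, m, _ = coefs.shape
    if companion_spectral_radius(coefs) >= 1.0:
        raise ValueError("VAR coefficients are unstable")
    chol = np.linalg.cholesky(cov)
    total = n_samples + burn_in
    eps = rng.standard_normal((total, m)) @ chol.T
    y = np.zeros((total, m))
    for n in range(total):
        acc = eps[n].copy()
        kmax = min(p, n)
        for k in range(1, kmax + 1):
            acc += coefs[k - 1] @ y[n - k]
        y[n] = acc
    return y[burn_in:]


# --------------------------------------------------------------------- force
def simulate_force(
    timing: TrialTiming,
    fs: float = 1000.0,
    rng: np.random.Generator | None = None,
    ramp_slope: float = 5.0,
    release_slope: float = -6.0,
    noise_sd: float = 0.01,
) -> np.ndarray:
    """Piecewise-smooth grip-force trace (N) for one trial.

    Near zero at rest, ramp exceeding +2 N/s from ``grip_onset`` to a
    plateau, plateau with low-amplitude noise through the hold, descending
    ramp below -2 N/s from ``release_onset``.
    """
    if fs < 100:
        raise ValueError("force sampling rate must be at least 100 Hz")
    if ramp_slope <= 2.0 or release_slope >= -2.0:
        raise ValueError("ramp slopes must exceed the 2 N/s event threshold")
    rng = np.random.default_rng() if rng is None else rng
    n = int(round(timing.total_duration * fs))
    t = np.arange(n) / fs
    plateau = ramp_slope * timing.ramp_duration
    f = np.zeros(n)
    ramp = (t >= timing.grip_onset) & (t < timing.grip_onset + timing.ramp_duration)
    f[ramp] = ramp_slope * (t[ramp] - timing.grip_onset)
    hold = (t >= timing.grip_onset + timing.ramp_duration) & (t < timing.release_onset)
    f[hold] = plateau
    rel = t >= timing.release_onset
    f[rel] = np.clip(plateau + release_slope * (t[rel] - timing.release_onset), 0.0, None)
    if noise_sd > 0:
        # smooth (10 Hz low-passed) sensor noise; rate stays well below 2 N/s
        sos = signal.butter(2, 10.0, btype="low", fs=fs, output="sos")
        f = f + signal.sosfiltfilt(sos, noise_sd * rng.standard_normal(n))
    return f


# --------------------------------------------------------------- pair engine
def _phase_gate(timing: TrialTiming, phase: str, fs: float, n: int) -> np.ndarray:
    """Smooth 0/1 gate over the active epoch (50 ms raised-cosine edges)."""
    if phase == "both":
        return np.ones(n)
    t0, t1 = timing.phase_interval(phase)
    t = np.arange(n) / fs
    gate = ((t >= t0) & (t < t1)).astype(float)
    ramp = max(1, int(round(0.050 * fs)))
    win = np.hanning(2 * ramp + 1)
    win /= win.sum()
    return np.convolve(gate, win, mode="same")


def _half_wave(x: np.ndarray) -> np.ndarray:
    return np.maximum(x, 0.0)


def _envelope(drive: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Nonnegative synthetic EMG envelope from an internal muscle drive.

    The oscillatory drive rides on a tonic baseline (two drive SDs) before
    half-wave rectification, as in rectified EMG of an active muscle where
    oscillations modulate a positive envelope.  Rectifying the zero-mean
    drive itself would clip half the signal and measurably distort
    programmed conduction delays.
    """
    scale = max(np.std(drive), 1e-12)
    noise = 0.05 * scale * np.abs(rng.standard_normal(drive.shape))
    return _half_wave(2.0 * scale + drive) + noise


def _simulate_trial_drives(
    spec: CouplingSpec, timing: TrialTiming, fs: float, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """(lfp, emg-drive) for one trial at rate ``fs`` (pre-envelope)."""
    n = int(round(timing.total_duration * fs))
    sd = spec.noise_sd
    if spec.regime == "uncoupled":
        return sd * rng.standard_normal(n), sd * rng.standard_normal(n)
    if spec.regime == "broadband_efferent":
        d_eff, _ = spec.delay_samples(fs)
        if d_eff < 1:
            raise ValueError("efferent delay below one sample at this rate")
        x = sd * rng.standard_normal(n)
        e = sd * rng.standard_normal(n)
        e[d_eff:] += spec.efferent_gain * x[:-d_eff]
        return x, e
    # beta loop: bivariate recursion with phase-gated cross-terms
    spec.require_stable(fs)
    c1, c2 = spec.ar2_poly(fs)
    d_eff, d_aff = spec.delay_samples(fs)
    gate = _phase_gate(timing, spec.active_phase, fs, n)
    wx = sd * rng.standard_normal(n)
    we = sd * rng.standard_normal(n)
    x = np.zeros(n)
    e = np.zeros(n)
    ga, ge = spec.afferent_gain, spec.efferent_gain
    start = max(2, d_eff, d_aff)
    x[:start] = wx[:start]
    e[:start] = we[:start]
    for i in range(start, n):
        g = gate[i]
        x[i] = c1 * x[i - 1] + c2 * x[i - 2] + g * ga * e[i - d_aff] + wx[i]
        e[i] = c1 * e[i - 1] + c2 * e[i - 2] + g * ge * x[i - d_eff] + we[i]
    return x, e


def simulate_pair(
    spec: CouplingSpec,
    timings: list[TrialTiming],
    fs: float = 250.0,
    seed: int | np.random.SeedSequence | None = 0,
) -> tuple[list[np.ndarray], list[np.ndarray]]:
    """Simulate (LFP trials, EMG-envelope trials) for one coupled pair."""
    if spec.regime == "beta_loop":
        spec.require_stable(fs)
        if min(spec.delay_samples(fs)) < 1:
            raise ValueError("delay below one sample is unrepresentable")
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    lfp_trials, emg_trials = [], []
    for timing, child in zip(timings, ss.spawn(len(timings))):
        rng = np.random.default_rng(child)
        x, drive = _simulate_trial_drives(spec, timing, fs, rng)
        lfp_trials.append(x)
        emg_trials.append(_envelope(drive, rng))
    return lfp_trials, emg_trials


def inject_crosstalk(emg_a: np.ndarray, emg_b: np.ndarray, mix: float) -> np.ndarray:
    """Electrical cross-talk mixture: ``(1-mix)*emg_b + mix*emg_a``."""
    if not 0.0 <= mix <= 1.0:
        raise ValueError("mix must lie in [0, 1]")
    if len(emg_a) != len(emg_b):
        raise ValueError("cross-talk traces must have equal length")
    return (1.0 - mix) * np.asarray(emg_b) + mix * np.asarray(emg_a)


# ------------------------------------------------------------------ scenario
@dataclass
class PairSpec:
    """One coupled LFP-EMG pair in a scenario."""

    lfp: str
    emg: str
    coupling: CouplingSpec
    structure: str = "spinal"
    site: tuple[float, float, float] | None = None


@dataclass
class ScenarioConfig:
    """Declarative description of a synthetic session."""

    pairs: list[PairSpec] = field(default_factory=list)
    extra_emgs: list[str] = field(default_factory=list)
    n_trials: int = 100
    fs: float = 250.0
    raw: bool = False
    mains_frequency: float = 50.0
    crosstalk: list[tuple[str, str, float]] = field(default_factory=list)
    ramp_slope: float = 5.0

    def __post_init__(self) -> None:
        if not self.pairs:
            raise ValueError("scenario needs at least one LFP-EMG pair")
        labels = [p.lfp for p in self.pairs] + [p.emg for p in self.pairs] + list(self.extra_emgs)
        if len(set(labels)) != len(labels):
            raise ValueError("channel labels must be unique")

    def to_dict(self) -> dict:
        d = asdict(self)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ScenarioConfig":
        d = dict(d)
        d["pairs"] = [
            PairSpec(
                lfp=p["lfp"], emg=p["emg"], structure=p.get("structure", "spinal"),
                site=tuple(p["site"]) if p.get("site") else None,
                coupling=CouplingSpec(**{k: tuple(v) if k == "band" else v
                                         for k, v in p["coupling"].items()}),
            )
            for p in d["pairs"]
        ]
        d["crosstalk"] = [tuple(c) for c in d.get("crosstalk", [])]
        return cls(**d)


@dataclass
class SyntheticSession:
    """A generated session plus its ground truth."""

    session: SessionDataset
    truth: dict[tuple[str, str], CouplingSpec]
    seed: int
    crosstalk_pairs: list[tuple[str, str, float]] = field(default_factory=list)

    def save(self, h5_path, truth_path=None) -> None:
        self.session.save(h5_path)
        if truth_path is not None:
            payload = {
                "seed": self.seed,
                "crosstalk_pairs": [list(c) for c in self.crosstalk_pairs],
                "truth": [
                    {"lfp": k[0], "emg": k[1], **asdict(v)}
                    for k, v in sorted(self.truth.items())
                ],
            }
            with open(truth_path, "w") as fh:
                json.dump(payload, fh, indent=1, sort_keys=True)


def default_scenario(n_trials: int = 100, raw: bool = False) -> ScenarioConfig:
    """Reference scenario: spinal broadband + grip-gated beta loop, cortical
    hold-gated beta loop, and one uncoupled control muscle."""
    return ScenarioConfig(
        pairs=[
            PairSpec("spinal_bb", "emg_1",
                     CouplingSpec(regime="broadband_efferent", efferent_delay=8.0,
                                  efferent_gain=1.0),
                     structure="spinal", site=(0.0, 0.0, 2000.0)),
            PairSpec("spinal_nb", "emg_2",
                     CouplingSpec(regime="beta_loop", efferent_delay=30.0,
                                  afferent_delay=27.0, active_phase="grip"),
                     structure="spinal", site=(500.0, 0.0, 1200.0)),
            PairSpec("cortical_nb", "emg_3",
                     CouplingSpec(regime="beta_loop", efferent_delay=30.0,
                                  afferent_delay=27.0, active_phase="hold"),
                     structure="cortical", site=(0.0, 5000.0, 800.0)),
        ],
        extra_emgs=["emg_4"],
        n_trials=n_trials,
        raw=raw,
    )


def draw_timings(n_trials: int, rng: np.random.Generator,
                 ramp_duration: float = 0.6) -> list[TrialTiming]:
    """Draw task timings: rest and hold durations uniform on 1.0-2.0 s."""
    timings = []
    for _ in range(n_trials):
        rest = rng.uniform(1.0, 2.0)
        hold = rng.uniform(1.0, 2.0)
        timings.append(
            TrialTiming(
                rest_duration=rest, hold_duration=hold, grip_onset=rest,
                release_onset=rest + ramp_duration + hold,
                ramp_duration=ramp_duration,
            )
        )
    return timings


def _upsample_nonneg(trials: list[np.ndarray], up: int) -> list[np.ndarray]:
    return [np.clip(signal.resample_poly(tr, up, 1), 0.0, None) for tr in trials]


def _raw_lfp(trials: list[np.ndarray], up: int, rng: np.random.Generator) -> list[np.ndarray]:
    out = []
    for tr in trials:
        raw = signal.resample_poly(tr, up, 1)
        out.append(raw + 0.05 * np.std(tr) * rng.standard_normal(raw.shape))
    return out


def _raw_emg(env_trials: list[np.ndarray], fs_raw: float,
             rng: np.random.Generator) -> list[np.ndarray]:
    """Interference-EMG model: envelope-modulated broadband carrier."""
    up = int(round(fs_raw / 250.0))
    sos = signal.butter(4, [30.0, 0.4 * fs_raw], btype="band", fs=fs_raw, output="sos")
    out = []
    for env in _upsample_nonneg(env_trials, up):
        carrier = signal.sosfiltfilt(sos, rng.standard_normal(env.shape))
        out.append(env * carrier)
    return out


def generate_session(config: ScenarioConfig, seed: int = 0) -> SyntheticSession:
    """Generate a fully labelled synthetic session.

    Channels are generated pair-group by pair-group (each coupled pair is one
    bivariate system); every other LFP-EMG combination is uncoupled by
    construction and labelled so in the truth table.
    """
    if config.n_trials < 100:
        warnings.warn(
            f"scenario requests {config.n_trials} trials (<100): pairs from "
            "this session will be excluded by the trial-count criterion",
            stacklevel=2,
        )
    root = np.random.SeedSequence(seed)
    ss_timing, ss_force, ss_pairs, ss_extra, ss_raw = root.spawn(5)
    timings = draw_timings(config.n_trials, np.random.default_rng(ss_timing))

    channels: dict[str, Channel] = {}
    truth: dict[tuple[str, str], CouplingSpec] = {}

    pair_seeds = ss_pairs.spawn(len(config.pairs))
    for pspec, pss in zip(config.pairs, pair_seeds):
        lfp_trials, emg_trials = simulate_pair(pspec.coupling, timings,
                                               fs=config.fs, seed=pss)
        channels[pspec.lfp] = Channel(pspec.lfp, LFP, config.fs, lfp_trials,
                                      structure=pspec.structure, site=pspec.site)
        channels[pspec.emg] = Channel(pspec.emg, EMG, config.fs, emg_trials)
        truth[(pspec.lfp, pspec.emg)] = pspec.coupling

    extra_seeds = ss_extra.spawn(len(config.extra_emgs))
    for label, ess in zip(config.extra_emgs, extra_seeds):
        rng = np.random.default_rng(ess)
        trials = [
            _envelope(rng.standard_normal(int(round(t.total_duration * config.fs))), rng)
            for t in timings
        ]
        channels[label] = Channel(label, EMG, config.fs, trials)

    # every unlisted LFP-EMG combination is uncoupled ground truth
    for lfp_label in [p.lfp for p in config.pairs]:
        for emg_label in [p.emg for p in config.pairs] + list(config.extra_emgs):
            truth.setdefault((lfp_label, emg_label), CouplingSpec(regime="uncoupled"))

    # cross-talk mixtures, applied to the stored EMG traces
    for emg_a, emg_b, mix in config.crosstalk:
        src, dst = channels[emg_a], channels[emg_b]
        dst.trials = [inject_crosstalk(a, b, mix) for a, b in zip(src.trials, dst.trials)]

    # force channel
    rng_force = np.random.default_rng(ss_force)
    force_fs = 1000.0 if config.raw else max(config.fs, 250.0)
    force_trials = [
        simulate_force(t, fs=force_fs, rng=rng_force, ramp_slope=config.ramp_slope)
        for t in timings
    ]
    channels["force"] = Channel("force", FORCE, force_fs, force_trials)

    if config.raw:
        rng_raw = np.random.default_rng(ss_raw)
        for ch in list(channels.values()):
            if ch.kind == LFP:
                ch.trials = _raw_lfp(ch.trials, int(round(20000 / config.fs)), rng_raw)
                ch.fs = 20000.0
            elif ch.kind == EMG:
                ch.trials = _raw_emg(ch.trials, 5000.0, rng_raw)
                ch.fs = 5000.0

    session = SessionDataset(
        channels=channels,
        timings=timings,
        mains_frequency=config.mains_frequency,
        provenance={
            "seed": seed,
            "generator": "cmcpipe.synth",
            "n_trials": config.n_trials,
            "low_trial_count": config.n_trials < 100,
        },
    )
    return SyntheticSession(session=session, truth=truth, seed=seed,
                            crosstalk_pairs=list(config.crosstalk))
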