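"""End-to-end orchestration: configuration, site pooling, per-pair analysis,
classification, group statistics, and result export.

The pipeline order mirrors the analysis protocol: cross-talk screen ->
preprocessing -> event detection -> epoch extraction -> wavelet and
fixed-window coherence -> NB/BB classification -> MVAR causality and delay
estimation -> group statistics.  Every exclusion (cross-talk, trial count,
window overflow) is logged with its reason into the result bundle.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import classify as cls
from . import coherence as coh
from . import group as grp
from . import preprocess as pre
from .mvar import MVARCausality, loop_time
from .session import Channel, SessionDataset, event_times, LFP, EMG, FORCE


@dataclass
class AnalysisConfig:
    """All tunable analysis parameters, serialized into every result bundle."""

    alpha: float = 0.005
    crosstalk_threshold: float = 0.25
    wavelet_window: tuple[float, float] = (-1.0, 0.5)
    wavelet_pad: float = 0.5
    grip_window: tuple[float, float] = (0.0, 0.512)
    hold_window: tuple[float, float] = (-0.768, -0.256)
    classify_grip_window: tuple[float, float] = (0.0, 1.0)
    classify_hold_window: tuple[float, float] = (-1.0, 0.0)
    beta_band: tuple[float, float] = (15.0, 30.0)
    full_band: tuple[float, float] = (2.0, 100.0)
    mvar_order: int = 15
    mains_frequency: float | None = None  # None: take from the session
    contour_level_step: float = 0.01
    min_trials: int = 100
    pool_radius_um: float = 150.0
    gabor_sigma: float = 0.128
    wavelet_freq_step: float = 1.0
    width_threshold: float = 25.0
    seed: int = 0
    fs_analysis: float = 250.0

    def wavelet_freqs(self) -> np.ndarray:
        lo, hi = self.full_band
        return np.arange(lo, hi + 1e-9, self.wavelet_freq_step)

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls_, d: dict) -> "AnalysisConfig":
        d = dict(d)
        for k in ("wavelet_window", "grip_window", "hold_window", "beta_band",
                  "full_band", "classify_grip_window", "classify_hold_window"):
            if k in d and d[k] is not None:
                d[k] = tuple(d[k])
        return cls_(**d)

    @classmethod
    def from_yaml(cls_, path) -> "AnalysisConfig":
        with open(path) as fh:
            return cls_.from_dict(yaml.safe_load(fh) or {})


# ------------------------------------------------------------- site pooling
def _single_linkage_clusters(coords: np.ndarray, radius: float) -> list[list[int]]:
    """Union-find single-linkage clustering under a distance threshold."""
    n = len(coords)
    parent = list(range(n))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(n):
        for j in range(i + 1, n):
            if np.linalg.norm(coords[i] - coords[j]) < radius:
                parent[find(i)] = find(j)
    groups: dict[int, list[int]] = {}
    for i in range(n):
        groups.setdefault(find(i), []).append(i)
    return list(groups.values())


def pool_nearby_sites(session: SessionDataset, radius: float = 150.0,
                      log: list | None = None) -> SessionDataset:
    """Average LFPs recorded at sites closer than ``radius`` um (single
    linkage), separately within spinal and cortical structures."""
    lfps = session.by_kind(LFP)
    with_coords = [c for c in lfps if c.site is not None]
    without = [c for c in lfps if c.site is None]
    if without and log is not None:
        log.append({"stage": "pool_sites", "reason": "missing coordinates",
                    "channels": [c.label for c in without]})
    new_channels = {c.label: c for c in session.channels.values()
                    if c.kind != LFP}
    for c in without:
        new_channels[c.label] = c
    for structure in sorted({c.structure for c in with_coords}):
        members = [c for c in with_coords if c.structure == structure]
        coords = np.array([c.site for c in members], dtype=float)
        for group_idx in _single_linkage_clusters(coords, radius):
            chans = [members[i] for i in sorted(group_idx)]
            if len(chans) == 1:
                new_channels[chans[0].label] = chans[0]
                continue
            label = "+".join(c.label for c in chans)
            pooled = [
                np.mean([c.trials[t] for c in chans], axis=0)
                for t in range(session.n_trials)
            ]
            new_channels[label] = Channel(
                label=label, kind=LFP, fs=chans[0].fs, trials=pooled,
                structure=structure, site=tuple(coords[sorted(group_idx)].mean(axis=0)),
            )
            if log is not None:
                log.append({"stage": "pool_sites", "reason": "pooled",
                            "channels": [c.label for c in chans]})
    return SessionDataset(
        channels=new_channels, timings=session.timings,
        mains_frequency=session.mains_frequency,
        provenance=dict(session.provenance, pooled_radius_um=radius),
    )


# ------------------------------------------------------------ result bundle
@dataclass
class ResultBundle:
    """Per-pair spectra, features, labels and delays plus group reports."""

    pair_table: pd.DataFrame
    spectra: dict = field(default_factory=dict, repr=False)
    maps: dict = field(default_factory=dict, repr=False)
    group_report: dict = field(default_factory=dict)
    exclusions: list = field(default_factory=list)
    config: dict = field(default_factory=dict)

    def save(self, outdir) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.pair_table.to_csv(outdir / "pairs.csv", index=False)
        rows = []
        for (lfp, emg, window), spec in sorted(self.spectra.items()):
            for f, c, s in zip(spec.freqs, spec.coh, spec.significant):
                rows.append({"lfp": lfp, "emg": emg, "window": window,
                             "frequency_hz": f, "coherence": c,
                             "significant": bool(s)})
        pd.DataFrame(rows).to_csv(outdir / "coherence.csv", index=False)
        with open(outdir / "group_report.json", "w") as fh:
            json.dump(self.group_report, fh, indent=1, sort_keys=True, default=_jsonable)
        with open(outdir / "exclusions.json", "w") as fh:
            json.dump(self.exclusions, fh, indent=1, default=_jsonable)
        with open(outdir / "config.json", "w") as fh:
            json.dump(self.config, fh, indent=1, sort_keys=True, default=_jsonable)


def _jsonable(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (set, tuple)):
        return list(obj)
    raise TypeError(f"not JSON-serializable: {type(obj)}")


# -------------------------------------------------------------- orchestration
def _preprocess_session(session: SessionDataset, config: AnalysisConfig,
                        log: list) -> SessionDataset:
    """Bring every channel to the 250 Hz analysis rate."""
    fs = config.fs_analysis
    channels = {}
    for ch in session.channels.values():
        if ch.kind == LFP and ch.fs > fs:
            trials = [pre.preprocess_lfp(t, fs_in=ch.fs, fs_out=fs) for t in ch.trials]
            channels[ch.label] = Channel(ch.label, LFP, fs, trials,
                                         ch.structure, ch.site)
        elif ch.kind == EMG and ch.fs > fs:
            bin_size = int(round(ch.fs / fs))
            trials = [pre.preprocess_emg(t, fs_in=ch.fs, bin_size=bin_size)
                      for t in ch.trials]
            channels[ch.label] = Channel(ch.label, EMG, fs, trials,
                                         ch.structure, ch.site)
        else:
            channels[ch.label] = ch
    return SessionDataset(channels=channels, timings=session.timings,
                          mains_frequency=session.mains_frequency,
                          provenance=session.provenance)


def _pair_epochs(lfp: Channel, emg: Channel, events: np.ndarray,
                 window, fs, pad=0.0):
    ex, kx = pre.extract_epochs(lfp.trials, events, window, fs, pad)
    ey, ky = pre.extract_epochs(emg.trials, events, window, fs, pad)
    common = np.intersect1d(kx, ky)
    return (ex[np.isin(kx, common)], ey[np.isin(ky, common)])


def run_pipeline(session: SessionDataset, config: AnalysisConfig | None = None,
                 events: pre.EventTable | None = None) -> ResultBundle:
    """Run the full analysis on one session and return a result bundle.

    Deterministic given the config seed; pairs excluded by the cross-talk
    screen or the minimum-trial criterion never reach the analysis stage.
    """
    config = config or AnalysisConfig()
    log: list[dict] = []
    mains = (session.mains_frequency if config.mains_frequency is None
             else config.mains_frequency)

    session = pool_nearby_sites(session, config.pool_radius_um, log)

    # ---- trial-count qualification
    qualified = session.n_trials >= config.min_trials
    if not qualified:
        log.append({"stage": "trial_count", "reason":
                    f"{session.n_trials} trials < {config.min_trials}"})

    # ---- cross-talk screen on raw-est EMGs available
    emgs = {c.label: np.concatenate(c.trials) for c in session.by_kind(EMG)}
    emg_fs = session.by_kind(EMG)[0].fs if session.by_kind(EMG) else config.fs_analysis
    screen = pre.crosstalk_screen(emgs, fs=emg_fs,
                                  threshold=config.crosstalk_threshold,
                                  seed=config.seed)
    for label in sorted(screen.excluded):
        log.append({"stage": "crosstalk", "reason": "|r|max above threshold",
                    "channel": label})

    # ---- preprocessing to the analysis rate
    session = _preprocess_session(session, config, log)
    fs = config.fs_analysis

    # ---- events from the force channel (fall back to stored timings)
    if events is None:
        force = [c for c in session.channels.values() if c.kind == FORCE]
        if force:
            events = pre.detect_events(force[0].trials, fs=force[0].fs)
        else:
            events = pre.EventTable(
                grip_onset=event_times(session.timings, "grip"),
                release_onset=event_times(session.timings, "release"),
            )
            log.append({"stage": "events", "reason":
                        "no force channel; ground-truth timings used"})

    grip_ev = events.grip_onset
    release_ev = events.release_onset
    freqs_wav = config.wavelet_freqs()
    pad_n = int(round(config.wavelet_pad * fs))

    analyzable = [
        (l, e) for l in session.lfp_labels
        for e in session.emg_labels if e not in screen.excluded
    ]
    if not qualified:
        analyzable = []

    rows = []
    spectra: dict = {}
    maps: dict = {}
    for lfp_label, emg_label in analyzable:
        lfp = session.channels[lfp_label]
        emg = session.channels[emg_label]
        row: dict = {"lfp": lfp_label, "emg": emg_label,
                     "structure": lfp.structure}

        # wavelet coherence around grip and release onsets
        cmaps = {}
        for name, ev in (("grip", grip_ev), ("release", release_ev)):
            ex, ey = _pair_epochs(lfp, emg, ev, config.wavelet_window, fs,
                                  pad=config.wavelet_pad)
            if len(ex) < 2:
                log.append({"stage": "epochs", "pair": [lfp_label, emg_label],
                            "reason": f"not enough {name}-aligned epochs"})
                continue
            t0 = config.wavelet_window[0]
            n_core = int(round((config.wavelet_window[1] - t0) * fs))
            times = t0 + np.arange(n_core) / fs
            tx = coh.gabor_transform(ex, fs, freqs_wav, times=times,
                                     sigma=config.gabor_sigma, pad_samples=pad_n)
            ty = coh.gabor_transform(ey, fs, freqs_wav, times=times,
                                     sigma=config.gabor_sigma, pad_samples=pad_n)
            cmaps[name] = coh.wavelet_coherence(tx, ty, alpha=config.alpha)
        maps[(lfp_label, emg_label)] = cmaps

        # fixed-window coherence (grip / hold)
        for name, ev, window in (
            ("grip", grip_ev, config.grip_window),
            ("hold", release_ev, config.hold_window),
        ):
            ex, ey = _pair_epochs(lfp, emg, ev, window, fs)
            if len(ex) < 2:
                continue
            spec = coh.segment_coherence(ex, ey, fs=fs, alpha=config.alpha,
                                         mains=mains)
            spectra[(lfp_label, emg_label, name)] = spec
            row[f"n_sig_{name}"] = int(spec.significant.sum())

            # MVAR causality on the same segments
            segs = np.stack([ex, ey], axis=-1)
            model = MVARCausality(order=config.mvar_order, fs=fs,
                                  alpha=config.alpha).fit(segs)
            if not model.stable_:
                log.append({"stage": "mvar", "pair": [lfp_label, emg_label],
                            "window": name, "reason": "unstable fit"})
                continue
            mf = spec.freqs
            eff = model.phase_delay(1, 0, freqs=mf, band=config.full_band)
            aff = model.phase_delay(0, 1, freqs=mf, band=config.full_band)
            row[f"tau_eff_{name}_ms"] = eff.tau_ms if eff else np.nan
            row[f"tau_aff_{name}_ms"] = aff.tau_ms if aff else np.nan
            lt = loop_time(eff, aff)
            row[f"loop_ms_{name}"] = lt if lt is not None else np.nan

        # classification features from the grip/release maps
        ci = 0.0
        if "grip" in cmaps:
            ci += cls.contour_integral(cmaps["grip"], config.classify_grip_window,
                                       config.contour_level_step)
        if "release" in cmaps:
            ci += cls.contour_integral(cmaps["release"], config.classify_hold_window,
                                       config.contour_level_step)
        width = 0.0
        for name in ("grip", "hold"):
            spec = spectra.get((lfp_label, emg_label, name))
            if spec is not None:
                width = max(width, cls.frequency_width(spec.significant,
                                                       spec.delta_f))
        # a pair carries coherence only when a significant *band* (at least
        # two contiguous fixed-window bins) appears in grip or hold; stray
        # single bins at alpha = 0.005 are point-wise false positives
        band_bins = max(
            (coh.longest_run(spectra[k].significant)
             for k in ((lfp_label, emg_label, "grip"), (lfp_label, emg_label, "hold"))
             if k in spectra),
            default=0,
        )
        row["contour_integral"] = ci
        row["frequency_width_hz"] = width
        row["has_band"] = band_bins >= 2
        rows.append(row)

    pair_table = pd.DataFrame(rows)
    group_report: dict = {}

    # ---- classification across pairs with a significant band
    if rows:
        gated = pair_table["has_band"].to_numpy(dtype=bool)
        feats = pair_table.loc[gated, ["contour_integral",
                                       "frequency_width_hz"]].to_numpy()
        labels = np.array([cls.NONE] * len(pair_table), dtype=object)
        if gated.sum() >= 10:
            clf = cls.CoherencePatternClassifier(
                width_threshold=config.width_threshold)
            labels[gated] = clf.fit_predict(feats)
            group_report["classification"] = {"rule": "gmm",
                                              "unimodal": clf.unimodal_}
        elif gated.sum() >= 1:
            # too few pairs for a mixture fit: fall back to the frequency-
            # width criterion (wide significant band = broad-band pattern)
            labels[gated] = np.where(feats[:, 1] > config.width_threshold,
                                     cls.BB, cls.NB)
            group_report["classification"] = {"rule": "width_threshold"}
            log.append({"stage": "classify",
                        "reason": "fewer than 10 banded pairs; width rule"})
        if "classification" in group_report:
            pair_table["label"] = labels
            group_report["classification"].update(
                n_nb=int(np.sum(labels == cls.NB)),
                n_bb=int(np.sum(labels == cls.BB)),
                n_none=int(np.sum(labels == cls.NONE)),
            )

    # ---- onset latencies within each label's own band
    if "label" in pair_table.columns:
        lats = []
        for row in pair_table.itertuples():
            cmaps = maps.get((row.lfp, row.emg), {})
            lat = np.nan
            if row.label != cls.NONE and "grip" in cmaps:
                band = (config.full_band if row.label == cls.BB
                        else config.beta_band)
                ol = cls.onset_latency(cmaps["grip"], band)
                lat = ol.latency_ms if ol else np.nan
            lats.append(lat)
        pair_table["latency_ms"] = lats
        bb = pair_table.loc[pair_table["label"] == cls.BB, "latency_ms"].dropna()
        nb = pair_table.loc[pair_table["label"] == cls.NB, "latency_ms"].dropna()
        if len(bb) >= 2 and len(nb) >= 2:
            lc = grp.latency_comparison(bb.to_numpy(), nb.to_numpy())
            group_report["latency_welch"] = asdict(lc)

    # ---- pooled significance per window over all analyzed pairs
    for name in ("grip", "hold"):
        masks = [s.significant for (l, e, w), s in spectra.items() if w == name]
        if len(masks) >= 2:
            any_spec = next(s for (l, e, w), s in spectra.items() if w == name)
            ps = grp.pooled_significance(np.asarray(masks), any_spec.freqs,
                                         base_rate=config.alpha)
            group_report[f"pooled_{name}"] = {
                "limit": ps.limit, "n_pairs": ps.n_pairs,
                "n_freqs_above": int(ps.significant.sum()),
            }

    if not analyzable:
        group_report["diagnostic"] = "no qualifying pairs"

    return ResultBundle(
        pair_table=pair_table, spectra=spectra, maps=maps,
        group_report=group_report, exclusions=log, config=config.to_dict(),
    )
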