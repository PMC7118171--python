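"""Session container: multi-channel, multi-trial recordings with task events.

A :class:`SessionDataset` is the unit of I/O for the whole pipeline.  Channels
may run at different sampling rates (raw LFP at 20 kHz, raw EMG at 5 kHz,
force at 1 kHz, or everything at the 250 Hz analysis rate); each channel
stores one array per trial because trial durations vary (rest and hold
periods are drawn from 1.0-2.0 s).

Sessions round-trip through a single HDF5 file (datasets named
``channels/<label>/<trial>``) with ground truth, when present, in a JSON
sidecar written by :mod:`cmcpipe.synth`.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
import h5py

LFP = "lfp"
EMG = "emg"
FORCE = "force"


@dataclass
class TrialTiming:
    """Event times of one grip-hold trial, seconds from trial start.

    The task sequence is rest (1.0-2.0 s), grip (force ramp), hold
    (1.0-2.0 s), release.  ``grip_onset`` marks the start of the force ramp
    and ``release_onset`` the start of the descending ramp.
    """

    rest_duration: float
    hold_duration: float
    grip_onset: float
    release_onset: float
    ramp_duration: float = 0.6
    tail_duration: float = 1.1

    def __post_init__(self) -> None:
        if self.release_onset <= self.grip_onset:
            raise ValueError(
                f"release_onset ({self.release_onset}) must follow grip_onset "
                f"({self.grip_onset})"
            )
        if self.rest_duration <= 0 or self.hold_duration <= 0:
            raise ValueError("durations must be positive")

    @property
    def total_duration(self) -> float:
        return self.release_onset + self.ramp_duration + self.tail_duration

    def phase_interval(self, phase: str) -> tuple[float, float]:
        """Time interval (s) of the dynamic grip or static hold phase."""
        if phase == "grip":
            return (self.grip_onset, self.grip_onset + self.ramp_duration)
        if phase == "hold":
            return (self.grip_onset + self.ramp_duration, self.release_onset)
        if phase == "both":
            return (self.grip_onset, self.release_onset)
        raise ValueError(f"unknown phase {phase!r}")


@dataclass
class Channel:
    """One recorded channel: label, kind, rate and per-trial traces."""

    label: str
    kind: str  # lfp | emg | force
    fs: float
    trials: list[np.ndarray] = field(default_factory=list)
    structure: str = "none"  # spinal | cortical | none
    site: tuple[float, float, float] | None = None  # x, y, depth in um

    def __post_init__(self) -> None:
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")
        if self.kind not in (LFP, EMG, FORCE):
            raise ValueError(f"unknown channel kind {self.kind!r}")


@dataclass
class SessionDataset:
    """Multi-trial session: channels, trial timings, and provenance."""

    channels: dict[str, Channel]
    timings: list[TrialTiming]
    mains_frequency: float = 50.0
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        n = self.n_trials
        for ch in self.channels.values():
            if len(ch.trials) != n:
                raise ValueError(
                    f"channel {ch.label!r} has {len(ch.trials)} trials, "
                    f"expected {n}"
                )

    @property
    def n_trials(self) -> int:
        return len(self.timings)

    def by_kind(self, kind: str) -> list[Channel]:
        return [c for c in self.channels.values() if c.kind == kind]

    @property
    def lfp_labels(self) -> list[str]:
        return [c.label for c in self.by_kind(LFP)]

    @property
    def emg_labels(self) -> list[str]:
        return [c.label for c in self.by_kind(EMG)]

    def content_hash(self) -> str:
        """SHA-256 over all samples and timings; used for determinism checks."""
        h = hashlib.sha256()
        for label in sorted(self.channels):
            ch = self.channels[label]
            h.update(label.encode())
            for tr in ch.trials:
                h.update(np.ascontiguousarray(tr, dtype=np.float64).tobytes())
        for t in self.timings:
            h.update(json.dumps(asdict(t), sort_keys=True).encode())
        return h.hexdigest()

    # ------------------------------------------------------------------ I/O
    def save(self, path) -> None:
        with h5py.File(path, "w") as f:
            f.attrs["mains_frequency"] = self.mains_frequency
            f.attrs["provenance"] = json.dumps(self.provenance, sort_keys=True)
            tgrp = f.create_group("timings")
            arr = np.array(
                [
                    [t.rest_duration, t.hold_duration, t.grip_onset,
                     t.release_onset, t.ramp_duration, t.tail_duration]
                    for t in self.timings
                ]
            )
            tgrp.create_dataset("table", data=arr)
            cgrp = f.create_group("channels")
            for label in sorted(self.channels):
                ch = self.channels[label]
                g = cgrp.create_group(label)
                g.attrs["kind"] = ch.kind
                g.attrs["fs"] = ch.fs
                g.attrs["structure"] = ch.structure
                if ch.site is not None:
                    g.attrs["site"] = np.asarray(ch.site, dtype=float)
                for i, tr in enumerate(ch.trials):
                    g.create_dataset(str(i), data=np.asarray(tr, dtype=np.float64))

    @classmethod
    def load(cls, path) -> "SessionDataset":
        with h5py.File(path, "r") as f:
            timings = [
                TrialTiming(*row) for row in np.asarray(f["timings/table"])
            ]
            channels = {}
            for label, g in f["channels"].items():
                site = g.attrs.get("site")
                ch = Channel(
                    label=label,
                    kind=str(g.attrs["kind"]),
                    fs=float(g.attrs["fs"]),
                    structure=str(g.attrs["structure"]),
                    site=tuple(site) if site is not None else None,
                    trials=[
                        np.asarray(g[str(i)]) for i in range(len(g.keys()))
                    ],
                )
                channels[label] = ch
            return cls(
                channels=channels,
                timings=timings,
                mains_frequency=float(f.attrs["mains_frequency"]),
                provenance=json.loads(f.attrs["provenance"]),
            )


def event_times(timings: Sequence[TrialTiming], which: str) -> np.ndarray:
    """Vector of grip or release onset times (s from trial start)."""
    if which == "grip":
        return np.array([t.grip_onset for t in timings])
    if which == "release":
        return np.array([t.release_onset for t in timings])
    raise ValueError(f"unknown event {which!r}")
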