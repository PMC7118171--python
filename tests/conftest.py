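"""Shared fixtures: small synthetic sessions and epoch helpers.

Everything is generated programmatically with fixed seeds; heavier shared
artifacts (the default-scenario pipeline run) are session-scoped so several
tests can assert against one computation.
"""

from __future__ import annotations

import numpy as np
import pytest

import cmcpipe as cp
from cmcpipe.synth import draw_timings


FS = 250.0
GRIP_WINDOW = (0.0, 0.512)
HOLD_WINDOW = (-0.768, -0.256)


def pair_segments(spec, n_trials=128, seed=7, timing_seed=2, windows=("grip",)):
    """Simulate a coupled pair and cut fixed analysis windows.

    Returns (n_segments, 128, 2) arrays stacking (lfp, emg)."""
    timings = draw_timings(n_trials, np.random.default_rng(timing_seed))
    lfp, emg = cp.simulate_pair(spec, timings, fs=FS, seed=seed)
    out = []
    for name in windows:
        if name == "grip":
            ev = np.array([t.grip_onset for t in timings])
            window = GRIP_WINDOW
        else:
            ev = np.array([t.release_onset for t in timings])
            window = HOLD_WINDOW
        ex, _ = cp.extract_epochs(lfp, ev, window, FS)
        ey, _ = cp.extract_epochs(emg, ev, window, FS)
        out.append(np.stack([ex, ey], axis=-1))
    return np.concatenate(out, axis=0)


@pytest.fixture(scope="session")
def default_synth():
    """Reference 100-trial synthetic session with ground truth."""
    return cp.generate_session(cp.default_scenario(n_trials=100), seed=11)


@pytest.fixture(scope="session")
def default_bundle(default_synth):
    """Full pipeline result on the reference session (computed once)."""
    return cp.run_pipeline(default_synth.session, cp.AnalysisConfig())
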