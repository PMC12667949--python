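"""Shared fixtures: deterministic RNGs, synthetic tracks, cached simulations."""

import numpy as np
import pytest

import boutlab as bl
from boutlab.pipeline import analyze_recording
from boutlab.segmentation import SegmentationParams
from boutlab.track_io import RecordingMeta, TrackSeries, attach_clock


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def meta():
    return RecordingMeta(condition="DD", repeat_id="r0", frame_rate=166.0)


def positions_for_speed(speed, frame_rate):
    """Positions whose central-difference speed reproduces ``speed`` exactly.

    Solves x[i+1] = x[i-1] + 2*speed[i]/fr (interior) with the one-sided
    endpoint convention x[1] - x[0] = speed[0]/fr, motion along +x only.
    """
    s = np.asarray(speed, dtype=float)
    n = len(s)
    x = np.zeros(n)
    x[1] = s[0] / frame_rate
    for i in range(1, n - 1):
        x[i + 1] = x[i - 1] + 2.0 * s[i] / frame_rate
    return x


@pytest.fixture
def make_speed_track(meta):
    """Build a TrackSeries whose measured speed equals a given profile."""

    def _make(speed, frame_rate=200.0, pitch=None, epoch_id="e0"):
        s = np.asarray(speed, dtype=float)
        n = len(s)
        tr = TrackSeries(
            epoch_id=epoch_id,
            t=np.arange(n) / frame_rate,
            x=positions_for_speed(s, frame_rate),
            z=np.zeros(n),
            pitch=np.zeros(n) if pitch is None else np.asarray(pitch, dtype=float),
            frame_rate=frame_rate,
        )
        m = RecordingMeta(condition="DD", frame_rate=frame_rate)
        return attach_clock(tr, m), m

    return _make


def gaussian_pulse_speed(n, peak_idx, peak, sigma_frames, floor=0.0):
    """Gaussian speed pulse on a frame grid (generator's bout profile)."""
    u = np.arange(n, dtype=float) - peak_idx
    return floor + peak * np.exp(-(u**2) / (2.0 * sigma_frames**2))


def simulate_and_analyze(params, repeat_id="r0"):
    """Generator -> segmentation -> kinematics tables, one call."""
    tracks, meta, log = bl.generate_recording(params, repeat_id=repeat_id)
    bdf, idf = analyze_recording(tracks, meta, SegmentationParams())
    return tracks, meta, log, bdf, idf


@pytest.fixture(scope="session")
def dark_run():
    """A cached half-hour dark-strategy recording with its analysis tables."""
    p = bl.preset("dark_strategy", seed=7, duration_h=0.5)
    return simulate_and_analyze(p)


@pytest.fixture(scope="session")
def light_run():
    """A cached quarter-hour light-strategy recording (many short bouts)."""
    p = bl.preset("light_strategy", seed=8, duration_h=0.25)
    return simulate_and_analyze(p)
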