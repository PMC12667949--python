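"""Swim-bout segmentation: speed, threshold detection, windows, IBIs.

Larval zebrafish swim in discrete bouts — short bursts of speed separated by
inactive inter-bout intervals (IBIs).  Bouts are detected as maximal runs of
smoothed swim speed above a 5 mm/s threshold; each detected bout is
represented by a peak-aligned 450 ms window (−250 ms … +200 ms around the
time of peak speed, 75 samples at 166 Hz).  IBIs span from the end of one
bout's super-threshold run to the start of the next.
"""

from __future__ import annotations

import dataclasses
import logging
import math
from typing import Sequence

import numpy as np

from .track_io import RecordingMeta, TrackSeries, assign_phase

logger = logging.getLogger(__name__)

#: detection threshold, mm/s
SPEED_THRESHOLD = 5.0


@dataclasses.dataclass
class SegmentationParams:
    """Tunable segmentation parameters.

    threshold : mm/s; speed above this counts as swimming.
    smooth_window : frames (odd); centered moving average applied to speed.
    min_duration : s; super-threshold runs shorter than this are discarded
        (default ≈ 3 frames at 166 Hz, suppressing single-frame noise).
    merge_gap : s; runs separated by a sub-threshold dip shorter than this
        are merged into one bout.
    pre, post : s; window extent before/after the speed peak.  The window
        holds ``floor(pre*fr) + floor(post*fr) + 1`` samples.
    """

    threshold: float = SPEED_THRESHOLD
    smooth_window: int = 3
    min_duration: float = 0.018
    merge_gap: float = 0.05
    pre: float = 0.25
    post: float = 0.20

    def window_frames(self, frame_rate: float) -> tuple[int, int]:
        return int(self.pre * frame_rate), int(self.post * frame_rate)


@dataclasses.dataclass
class BoutRuns:
    """Super-threshold runs in one epoch (frame indices; ``end`` exclusive)."""

    start: np.ndarray
    end: np.ndarray
    peak: np.ndarray
    truncated: np.ndarray  # bool; window would cross the epoch boundary

    def __len__(self) -> int:
        return len(self.start)


@dataclasses.dataclass
class SwimBout:
    """One detected bout: a peak-aligned window plus its super-threshold run.

    Window arrays are views into the epoch arrays (no copies).  ``prev_ibi``
    / ``next_ibi`` are indices into the companion IBI list, or ``None`` at
    epoch edges.
    """

    epoch_id: str
    peak_index: int
    peak_time: float
    peak_clock: float | None
    phase: str | None
    window_t: np.ndarray
    window_speed: np.ndarray
    window_pitch: np.ndarray
    window_x: np.ndarray
    window_z: np.ndarray
    run_start: int
    run_end: int
    run_x: np.ndarray
    run_z: np.ndarray
    above_threshold_span: tuple[float, float]
    prev_ibi: int | None = None
    next_ibi: int | None = None


@dataclasses.dataclass
class InterBoutInterval:
    """Inactivity span between two consecutive bouts of one epoch.

    ``duration`` runs between super-threshold run edges ("the time between
    two bouts"); ``drift`` is the pitch difference between the window edges
    of the flanking bouts (end of previous bout's window to start of the
    next bout's window), so bout rotation and IBI drift tile the pitch
    trajectory without overlap.  Nose-down drift is negative.
    """

    epoch_id: str
    duration: float
    start_pitch: float
    end_pitch: float
    drift: float
    phase: str | None
    mid_clock: float | None
    preceding_bout: int
    following_bout: int


def compute_speed(track: TrackSeries, smooth_window: int = 3) -> np.ndarray:
    """Swim speed (mm/s) from positions by central differences + smoothing.

    Interior frames use the central difference
    ``fr * sqrt(dx^2 + dz^2) / 2`` over neighbours i−1, i+1; the endpoints
    use one-sided differences.  A centered moving average of length
    ``smooth_window`` (odd, >= 1) is then applied.  Output length equals the
    track length and speed is non-negative.
    """
    if smooth_window < 1 or smooth_window % 2 == 0:
        raise ValueError("smooth_window must be odd and >= 1")
    n = track.n
    if n < smooth_window or n < 2:
        raise ValueError("epoch shorter than smoothing window")
    fr = track.frame_rate
    x, z = track.x, track.z
    dx = np.empty(n)
    dz = np.empty(n)
    dx[1:-1] = (x[2:] - x[:-2]) / 2.0
    dz[1:-1] = (z[2:] - z[:-2]) / 2.0
    dx[0], dz[0] = x[1] - x[0], z[1] - z[0]
    dx[-1], dz[-1] = x[-1] - x[-2], z[-1] - z[-2]
    speed = fr * np.hypot(dx, dz)
    if smooth_window > 1:
        # centered moving average, edges replicated (cumsum formulation)
        h = smooth_window // 2
        padded = np.concatenate((np.repeat(speed[0], h), speed, np.repeat(speed[-1], h)))
        cs = np.concatenate(([0.0], np.cumsum(padded)))
        speed = (cs[smooth_window:] - cs[:-smooth_window]) / smooth_window
        np.maximum(speed, 0.0, out=speed)  # guard tiny negative round-off
    return speed


def detect_bouts(
    speed: np.ndarray,
    frame_rate: float,
    threshold: float = SPEED_THRESHOLD,
    min_duration: float = 0.018,
    merge_gap: float = 0.05,
    window: tuple[int, int] | None = None,
) -> BoutRuns:
    """Find super-threshold runs and their peaks.

    Maximal runs with ``speed > threshold`` are extracted; runs shorter than
    ``min_duration`` are discarded first, then surviving runs separated by a
    sub-threshold gap shorter than ``merge_gap`` are merged (filtering before
    merging keeps the bout count non-increasing in ``merge_gap`` — noise
    blips cannot seed merges).  One peak per run: the argmax of speed,
    earliest frame on ties.  ``window = (pre_frames, post_frames)`` marks
    runs whose peak-centered window would cross the epoch boundary as
    truncated.
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    speed = np.asarray(speed, dtype=float)
    above = speed > threshold
    edges = np.flatnonzero(np.diff(np.concatenate(([False], above, [False]))))
    starts, ends = edges[0::2], edges[1::2]

    min_frames = max(1, math.ceil(min_duration * frame_rate - 1e-9))
    keep = (ends - starts) >= min_frames
    starts, ends = starts[keep], ends[keep]

    if len(starts) > 1 and merge_gap > 0:
        gap_s = (starts[1:] - ends[:-1]) / frame_rate
        boundary = gap_s >= merge_gap  # True -> keep the break
        seg_start = np.concatenate(([True], boundary))
        seg_end = np.concatenate((boundary, [True]))
        starts, ends = starts[seg_start], ends[seg_end]

    peaks = np.array(
        [s + int(np.argmax(speed[s:e])) for s, e in zip(starts, ends)], dtype=int
    )
    if window is not None:
        pre_f, post_f = window
        truncated = (peaks - pre_f < 0) | (peaks + post_f >= len(speed))
    else:
        truncated = np.zeros(len(peaks), dtype=bool)
    return BoutRuns(start=starts, end=ends, peak=peaks, truncated=truncated)


def segment_epoch(
    track: TrackSeries,
    params: SegmentationParams | None = None,
    meta: RecordingMeta | None = None,
    _bout_offset: int = 0,
    _ibi_offset: int = 0,
) -> tuple[list[SwimBout], list[InterBoutInterval]]:
    """Segment one epoch into peak-aligned bouts and the IBIs between them.

    Truncated bouts (window crossing the epoch boundary) are excluded; IBIs
    link adjacent surviving runs only, so with ``k >= 1`` bouts and none
    truncated the epoch yields ``k - 1`` IBIs.  Phase labels require
    ``track.clock_t`` (set by :func:`~boutlab.track_io.attach_clock`) and
    ``meta``.
    """
    params = params or SegmentationParams()
    fr = track.frame_rate
    pre_f, post_f = params.window_frames(fr)
    speed = compute_speed(track, params.smooth_window)
    runs = detect_bouts(
        speed,
        fr,
        threshold=params.threshold,
        min_duration=params.min_duration,
        merge_gap=params.merge_gap,
        window=(pre_f, post_f),
    )
    n_trunc = int(runs.truncated.sum())
    if n_trunc:
        logger.debug("epoch %s: %d truncated bout(s) excluded", track.epoch_id, n_trunc)

    window_t = np.arange(-pre_f, post_f + 1) / fr
    have_clock = track.clock_t is not None and meta is not None

    bouts: list[SwimBout] = []
    kept_adjacent: list[bool] = []  # bout i adjacent (in run order) to bout i-1
    prev_kept = False
    for i in range(len(runs)):
        if runs.truncated[i]:
            prev_kept = False
            continue
        p = int(runs.peak[i])
        s, e = int(runs.start[i]), int(runs.end[i])
        sl = slice(p - pre_f, p + post_f + 1)
        clock = float(track.clock_t[p]) if have_clock else None
        bouts.append(
            SwimBout(
                epoch_id=track.epoch_id,
                peak_index=p,
                peak_time=float(track.t[p]),
                peak_clock=clock,
                phase=None,
                window_t=window_t,
                window_speed=speed[sl],
                window_pitch=track.pitch[sl],
                window_x=track.x[sl],
                window_z=track.z[sl],
                run_start=s,
                run_end=e,
                run_x=track.x[s:e],
                run_z=track.z[s:e],
                above_threshold_span=(float(track.t[s]), float(track.t[e - 1])),
            )
        )
        kept_adjacent.append(prev_kept)
        prev_kept = True

    ibis: list[InterBoutInterval] = []
    for j in range(1, len(bouts)):
        if not kept_adjacent[j]:
            continue  # a truncated run sits between these bouts
        prev_b, next_b = bouts[j - 1], bouts[j]
        duration = next_b.above_threshold_span[0] - prev_b.above_threshold_span[1]
        start_pitch = float(prev_b.window_pitch[-1])
        end_pitch = float(next_b.window_pitch[0])
        if have_clock:
            mid_t = 0.5 * (prev_b.above_threshold_span[1] + next_b.above_threshold_span[0])
            mid_idx = min(max(int(round((mid_t - track.t[0]) * fr)), 0), track.n - 1)
            mid_clock = float(track.clock_t[mid_idx])
        else:
            mid_clock = None
        phase = None
        k = len(ibis)
        ibis.append(
            InterBoutInterval(
                epoch_id=track.epoch_id,
                duration=float(duration),
                start_pitch=start_pitch,
                end_pitch=end_pitch,
                drift=end_pitch - start_pitch,
                phase=phase,
                mid_clock=mid_clock,
                preceding_bout=_bout_offset + j - 1,
                following_bout=_bout_offset + j,
            )
        )
        prev_b.next_ibi = _ibi_offset + k
        next_b.prev_ibi = _ibi_offset + k

    # vectorized phase labels (one assign_phase call per epoch)
    if have_clock:
        if bouts:
            for b, ph in zip(bouts, assign_phase([b.peak_clock for b in bouts], meta)):
                b.phase = str(ph)
        if ibis:
            for i, ph in zip(ibis, assign_phase([i.mid_clock for i in ibis], meta)):
                i.phase = str(ph)
    return bouts, ibis


def segment_recording(
    tracks: Sequence[TrackSeries],
    meta: RecordingMeta | None = None,
    params: SegmentationParams | None = None,
) -> tuple[list[SwimBout], list[InterBoutInterval]]:
    """Segment every epoch of a recording; bout/IBI links use global indices."""
    params = params or SegmentationParams()
    all_bouts: list[SwimBout] = []
    all_ibis: list[InterBoutInterval] = []
    for tr in tracks:
        b, i = segment_epoch(
            tr, params, meta, _bout_offset=len(all_bouts), _ibi_offset=len(all_ibis)
        )
        all_bouts.extend(b)
        all_ibis.extend(i)
    return all_bouts, all_ibis
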