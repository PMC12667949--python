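"""Per-bout and per-IBI kinematic parameters.

For each peak-aligned bout the pipeline measures:

* **peak speed** (mm/s) — speed at the window center;
* **bout duration** (ms) — full width at half maximum (FWHM) of the speed
  profile, with half-max crossings located by linear interpolation;
* **displacement** (mm) — summed Euclidean step length while speed stays
  above the detection threshold;
* **direction** (deg) — elevation of the instantaneous trajectory at the
  peak, ``atan2(dz, |dx|)``, up positive (|dx| folds left/right swimming
  onto one vertical convention);
* **rotation** (deg) — net pitch change across the window endpoints
  (−250 ms to +200 ms), nose-up positive.

Each IBI carries its duration and the signed pitch **drift** (nose-down
negative) between the window edges of its flanking bouts.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from .segmentation import InterBoutInterval, SwimBout


@dataclasses.dataclass
class BoutKinematics:
    peak_speed: float
    duration_fwhm: float  # ms
    fwhm_censored: bool
    displacement: float  # mm
    direction: float  # deg, NaN if undefined
    rotation: float  # deg


@dataclasses.dataclass
class IBIKinematics:
    duration: float  # s
    drift: float  # deg


# ---------------------------------------------------------------------------
# vectorized cores (operate on stacked (n, W) window arrays)
# ---------------------------------------------------------------------------

def fwhm_from_profiles(
    window_speed: np.ndarray, frame_rate: float, peak_index: int
) -> tuple[np.ndarray, np.ndarray]:
    """FWHM (ms) of speed profiles peaking at column ``peak_index``.

    Crossings of half the peak value are located by linear interpolation
    between the straddling frames: the last crossing before the peak and the
    first after it.  If the profile never falls below half-max on a side,
    the window edge is used and the profile is flagged censored.

    Returns ``(fwhm_ms, censored)``, shaped like the leading dimension.
    """
    w = np.atleast_2d(np.asarray(window_speed, dtype=float))
    n, width = w.shape
    p = peak_index
    peak = w[:, p]
    if np.any(peak <= 0):
        raise ValueError("non-positive peak speed")
    half = 0.5 * peak
    below = w < half[:, None]

    # left side: walk from the peak toward the window start
    left = below[:, p::-1]  # column 0 = peak
    has_l = left.any(axis=1)
    j = np.argmax(left, axis=1)  # first below-half frame, >= 1 where has_l
    jl = np.where(has_l, np.maximum(j, 1), 1)
    lo = w[np.arange(n), p - jl]
    hi = w[np.arange(n), p - jl + 1]
    frac = np.where(hi > lo, (half - lo) / np.where(hi > lo, hi - lo, 1.0), 0.0)
    t_left = np.where(has_l, (-jl + frac) / frame_rate, -p / frame_rate)

    # right side
    right = below[:, p:]
    has_r = right.any(axis=1)
    k = np.argmax(right, axis=1)
    kr = np.where(has_r, np.maximum(k, 1), 1)
    lo_r = w[np.arange(n), p + kr]
    hi_r = w[np.arange(n), p + kr - 1]
    frac_r = np.where(hi_r > lo_r, (half - lo_r) / np.where(hi_r > lo_r, hi_r - lo_r, 1.0), 0.0)
    t_right = np.where(has_r, (kr - frac_r) / frame_rate, (width - 1 - p) / frame_rate)

    fwhm_ms = (t_right - t_left) * 1000.0
    censored = ~(has_l & has_r)
    if np.ndim(window_speed) == 1:
        return fwhm_ms[0], censored[0]
    return fwhm_ms, censored


def rotation_from_windows(window_pitch: np.ndarray) -> np.ndarray:
    """Net pitch change across the window: pitch at +200 ms minus at −250 ms."""
    wp = np.asarray(window_pitch, dtype=float)
    return wp[..., -1] - wp[..., 0]


def direction_at_peak(
    window_x: np.ndarray, window_z: np.ndarray, peak_index: int, eps: float = 0.0
) -> np.ndarray:
    """Elevation (deg) of the central-difference velocity at the peak frame.

    Positive is upward; ``|dx|`` makes left- and right-swimming equivalent.
    Zero net motion at the peak yields NaN (direction undefined).
    """
    wx = np.atleast_2d(np.asarray(window_x, dtype=float))
    wz = np.atleast_2d(np.asarray(window_z, dtype=float))
    p = peak_index
    dx = np.abs(wx[:, p + 1] - wx[:, p - 1])
    dz = wz[:, p + 1] - wz[:, p - 1]
    deg = np.degrees(np.arctan2(dz, dx))
    deg = np.where((dx == 0) & (dz == 0), np.nan, deg)
    if np.ndim(window_x) == 1:
        return float(deg[0])
    return deg


# ---------------------------------------------------------------------------
# per-bout wrappers (spec-level operations)
# ---------------------------------------------------------------------------

def _frame_rate_of(bout: SwimBout) -> float:
    return 1.0 / (bout.window_t[1] - bout.window_t[0])


def _peak_col(bout: SwimBout) -> int:
    return int(np.searchsorted(bout.window_t, 0.0))


def bout_duration_fwhm(bout: SwimBout) -> tuple[float, bool]:
    """Bout duration (ms): width at half maximum of the speed profile."""
    return fwhm_from_profiles(bout.window_speed, _frame_rate_of(bout), _peak_col(bout))


def bout_displacement(bout: SwimBout) -> float:
    """Euclidean distance (mm) traveled while speed stays super-threshold."""
    dx = np.diff(bout.run_x)
    dz = np.diff(bout.run_z)
    return float(np.sum(np.hypot(dx, dz)))


def bout_direction(bout: SwimBout) -> float:
    """Trajectory elevation (deg) at the time of peak speed; NaN if still."""
    return direction_at_peak(bout.window_x, bout.window_z, _peak_col(bout))


def bout_rotation(bout: SwimBout) -> float:
    """Net pitch change (deg) between −250 ms and +200 ms around the peak."""
    return float(rotation_from_windows(bout.window_pitch))


def ibi_drift(ibi: InterBoutInterval) -> float:
    """Signed pitch drift (deg) across the IBI; nose-down drift is negative."""
    return ibi.end_pitch - ibi.start_pitch


def measure_bout(bout: SwimBout) -> BoutKinematics:
    fwhm, cens = bout_duration_fwhm(bout)
    p = _peak_col(bout)
    return BoutKinematics(
        peak_speed=float(bout.window_speed[p]),
        duration_fwhm=float(fwhm),
        fwhm_censored=bool(cens),
        displacement=bout_displacement(bout),
        direction=bout_direction(bout),
        rotation=bout_rotation(bout),
    )


# ---------------------------------------------------------------------------
# tables
# ---------------------------------------------------------------------------

def bout_table(bouts: list[SwimBout], ibis: list[InterBoutInterval]) -> pd.DataFrame:
    """One row per bout with all kinematics and links to flanking IBIs.

    Columns ``prev_ibi_s`` / ``prev_drift_deg`` (and the ``next_*`` pair)
    are NaN where the bout has no neighbour on that side.
    """
    if not bouts:
        return pd.DataFrame(
            columns=[
                "epoch_id", "peak_time", "peak_clock", "phase", "peak_speed",
                "duration_fwhm_ms", "fwhm_censored", "displacement_mm",
                "direction_deg", "rotation_deg", "start_time", "start_x",
                "start_z", "prev_ibi", "next_ibi", "prev_ibi_s",
                "prev_drift_deg", "next_ibi_s", "next_drift_deg",
            ]
        )
    fr = _frame_rate_of(bouts[0])
    p = _peak_col(bouts[0])
    ws = np.stack([b.window_speed for b in bouts])
    wp = np.stack([b.window_pitch for b in bouts])
    wx = np.stack([b.window_x for b in bouts])
    wz = np.stack([b.window_z for b in bouts])
    fwhm, cens = fwhm_from_profiles(ws, fr, p)
    disp = np.array([bout_displacement(b) for b in bouts])

    def _link(attr: str, field: str) -> np.ndarray:
        return np.array(
            [
                getattr(ibis[getattr(b, attr)], field) if getattr(b, attr) is not None else np.nan
                for b in bouts
            ]
        )

    return pd.DataFrame(
        {
            "epoch_id": [b.epoch_id for b in bouts],
            "peak_time": [b.peak_time for b in bouts],
            "peak_clock": [b.peak_clock for b in bouts],
            "phase": [b.phase for b in bouts],
            "peak_speed": ws[:, p],
            "duration_fwhm_ms": fwhm,
            "fwhm_censored": cens,
            "displacement_mm": disp,
            "direction_deg": direction_at_peak(wx, wz, p),
            "rotation_deg": rotation_from_windows(wp),
            "start_time": [b.peak_time - p / fr for b in bouts],
            "start_x": wx[:, 0],
            "start_z": wz[:, 0],
            "prev_ibi": [b.prev_ibi if b.prev_ibi is not None else -1 for b in bouts],
            "next_ibi": [b.next_ibi if b.next_ibi is not None else -1 for b in bouts],
            "prev_ibi_s": _link("prev_ibi", "duration"),
            "prev_drift_deg": _link("prev_ibi", "drift"),
            "next_ibi_s": _link("next_ibi", "duration"),
            "next_drift_deg": _link("next_ibi", "drift"),
        }
    )


def ibi_table(ibis: list[InterBoutInterval]) -> pd.DataFrame:
    """One row per IBI: duration, drift, phase and flanking bout indices."""
    return pd.DataFrame(
        {
            "epoch_id": [i.epoch_id for i in ibis],
            "duration_s": [i.duration for i in ibis],
            "drift_deg": [i.drift for i in ibis],
            "phase": [i.phase for i in ibis],
            "mid_clock": [i.mid_clock for i in ibis],
            "preceding_bout": [i.preceding_bout for i in ibis],
            "following_bout": [i.following_bout for i in ibis],
        }
    )
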