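"""Multi-bout navigation metrics over 5-bout epochs.

A *navigation epoch* is a sliding window of five consecutive bouts within
one tracking epoch (stride 1, so a tracking epoch with ``k >= 5`` bouts
yields ``k - 4`` navigation epochs).  Two rates are computed per epoch:

* **displacement per second** — straight-line (not path) distance between
  the window-start positions of bouts 1 and 5, divided by the time elapsed
  between those window starts;
* **directional change per second** — the four absolute changes in swim
  direction between consecutive bouts, summed and divided by elapsed time.
"""

from __future__ import annotations

import dataclasses
import logging

import numpy as np
import pandas as pd

from .stats import scott_bins

logger = logging.getLogger(__name__)

EPOCH_BOUTS = 5


@dataclasses.dataclass
class NavigationEpoch:
    """Five consecutive bouts and the two derived rates."""

    epoch_id: str
    start_x: np.ndarray  # (5,) window-start positions, mm
    start_z: np.ndarray
    start_times: np.ndarray  # (5,) window-start times, s
    directions: np.ndarray  # (5,) deg
    elapsed: float  # s
    displacement_per_s: float
    dirchange_per_s: float
    phase: str | None = None


def displacement_per_second(start_x, start_z, elapsed: float) -> float:
    """Euclidean distance between first and fifth bout starts over elapsed.

    A closed loop returning to its start scores 0 regardless of path length.
    """
    sx = np.asarray(start_x, dtype=float)
    sz = np.asarray(start_z, dtype=float)
    if elapsed <= 0:
        raise ValueError("elapsed must be positive")
    return float(np.hypot(sx[-1] - sx[0], sz[-1] - sz[0]) / elapsed)


def directional_change_per_second(directions, elapsed: float) -> float:
    """Summed |direction change| between consecutive bouts, per second."""
    d = np.asarray(directions, dtype=float)
    if np.any(np.isnan(d)):
        raise ValueError("undefined direction in sequence")
    if elapsed <= 0:
        raise ValueError("elapsed must be positive")
    return float(np.sum(np.abs(np.diff(d))) / elapsed)


def build_navigation_epochs(bout_df: pd.DataFrame) -> pd.DataFrame:
    """Sliding 5-bout windows per tracking epoch (stride 1).

    Windows containing an undefined (NaN) bout direction are skipped with a
    logged count.  The phase label is taken from the middle (third) bout.
    Returns one row per navigation epoch with ``displacement_per_s``,
    ``dirchange_per_s``, ``elapsed`` and member bout row indices.
    """
    rows = []
    n_skipped = 0
    for eid, sub in bout_df.groupby("epoch_id", sort=False):
        sub = sub.sort_values("peak_time")
        k = len(sub)
        if k < EPOCH_BOUTS:
            continue
        sx = sub["start_x"].to_numpy()
        sz = sub["start_z"].to_numpy()
        st = sub["start_time"].to_numpy()
        dirs = sub["direction_deg"].to_numpy()
        phases = sub["phase"].to_numpy()
        idx = sub.index.to_numpy()
        absdiff = np.abs(np.diff(dirs))
        csum = np.concatenate(([0.0], np.cumsum(absdiff)))
        nan_ok = np.isfinite(dirs)
        for i in range(k - EPOCH_BOUTS + 1):
            j = i + EPOCH_BOUTS - 1
            if not nan_ok[i : j + 1].all():
                n_skipped += 1
                continue
            elapsed = st[j] - st[i]
            if elapsed <= 0:
                n_skipped += 1
                continue
            rows.append(
                {
                    "epoch_id": eid,
                    "t_start": st[i],
                    "phase": phases[i + 2],
                    "elapsed": elapsed,
                    "displacement_per_s": float(np.hypot(sx[j] - sx[i], sz[j] - sz[i]) / elapsed),
                    "dirchange_per_s": float((csum[j] - csum[i]) / elapsed),
                    "bout_rows": ",".join(str(v) for v in idx[i : j + 1]),
                }
            )
    if n_skipped:
        logger.debug("skipped %d navigation window(s) with undefined direction", n_skipped)
    cols = [
        "epoch_id", "t_start", "phase", "elapsed",
        "displacement_per_s", "dirchange_per_s", "bout_rows",
    ]
    return pd.DataFrame(rows, columns=cols)


def direction_histogram(directions, bins="scott"):
    """Angular histogram of bout directions (deg, within [-90, 90]).

    ``bins`` is ``"scott"`` (Scott's-rule widths), an int, or explicit
    edges.  Returns ``(counts, edges)``; counts sum to the number of finite
    directions.  Empty input yields an empty histogram.
    """
    d = np.asarray(directions, dtype=float)
    d = d[np.isfinite(d)]
    if d.size == 0:
        return np.array([], dtype=int), np.array([])
    if isinstance(bins, str) and bins == "scott":
        edges = scott_bins(d) if d.size >= 2 and np.std(d) > 0 else np.array([d.min(), d.max() + 1e-9])
    elif np.isscalar(bins):
        edges = np.linspace(d.min(), d.max(), int(bins) + 1)
    else:
        edges = np.asarray(bins, dtype=float)
    counts, edges = np.histogram(d, bins=edges)
    # np.histogram's closed right edge keeps the max in the last bin
    return counts, edges
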