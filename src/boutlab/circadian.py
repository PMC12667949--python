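"""Time-resolved analysis: binned medians, day/night summaries, rhythms.

Kinematic parameters are binned over a 48 h clock-anchored analysis window
(default 10 a.m. day 1 to 10 a.m. day 3): per experimental repeat, the
median within each bin (2 h bins for time-course plots, 0.5 h bins for
autocorrelation).  Binned-median series are z-scored within each repeat so
repeats with different baselines can be overlaid.  Day/night comparisons
exclude the transition hours flanking each light switch.  Rhythmicity is
detected from the autocorrelation of the binned-median series: a periodic
modulation produces a coefficient peak at its period (≈ 24 h for an
entrained circadian rhythm), located within an 18–30 h search band.
"""

from __future__ import annotations

import dataclasses
import logging
import warnings

import numpy as np
import pandas as pd

from .track_io import DAY, NIGHT, TRANSITION, RecordingMeta

logger = logging.getLogger(__name__)

DEFAULT_WINDOW = (10.0, 58.0)  # absolute hours: 10 a.m. day 1 .. 10 a.m. day 3


@dataclasses.dataclass
class BinnedSeries:
    """Per-repeat binned medians over the analysis window.

    ``medians`` and ``z_scores`` are DataFrames (repeat x bin); bin centers
    are hours since the window start.  Empty bins are NaN (missing), never
    zero.  z-scores use each repeat's own mean/SD over its non-empty bins,
    so each repeat has mean 0 and (population) SD 1.
    """

    bin_width: float
    bin_centers: np.ndarray
    medians: pd.DataFrame
    z_scores: pd.DataFrame
    repeat_ids: list

    @property
    def window_hours(self) -> float:
        return self.bin_width * len(self.bin_centers)


@dataclasses.dataclass
class AutocorrResult:
    """Per-repeat normalized autocorrelation of a binned-median series."""

    lags: np.ndarray  # hours
    coefficients: pd.DataFrame  # repeat x lag, value 1 at lag 0
    peak_lag: pd.Series  # per repeat, within the search band
    search_band: tuple[float, float]
    excluded: list  # repeats dropped for excess missing bins


def extract_analysis_window(
    df: pd.DataFrame,
    window: tuple[float, float] = DEFAULT_WINDOW,
    time_col: str = "abs_hours",
) -> pd.DataFrame:
    """Keep records whose clock-anchored time lies in ``[start, end)``.

    The left edge is closed: a record at exactly the window start is kept.
    A recording shorter than the window is retained with a warning.
    """
    lo, hi = window
    t = df[time_col].to_numpy()
    if len(t) and (t.min() > lo or t.max() < hi):
        logger.warning(
            "recording covers [%.2f, %.2f] h; shorter than analysis window [%.2f, %.2f]",
            t.min() if len(t) else np.nan, t.max() if len(t) else np.nan, lo, hi,
        )
    return df[(t >= lo) & (t < hi)]


def bin_medians(
    values,
    abs_hours,
    repeat_ids,
    bin_width: float = 2.0,
    window: tuple[float, float] = DEFAULT_WINDOW,
) -> BinnedSeries:
    """Per-repeat medians of a parameter in fixed-width bins.

    ``abs_hours`` are absolute (non-wrapping) hours since midnight of
    recording day 1; only records inside the window contribute.  Bins that
    receive no record stay NaN.
    """
    if (24.0 / bin_width) % 1 != 0:
        warnings.warn(
            f"bin_width {bin_width} h does not divide 24 h evenly; "
            "phase labels become heterogeneous within bins"
        )
    lo, hi = window
    nbins = int(round((hi - lo) / bin_width))
    values = np.asarray(values, dtype=float)
    hours = np.asarray(abs_hours, dtype=float)
    repeat_ids = np.asarray(repeat_ids)
    inside = (hours >= lo) & (hours < hi)
    d = pd.DataFrame(
        {
            "value": values[inside],
            "bin": ((hours[inside] - lo) / bin_width).astype(int),
            "repeat": repeat_ids[inside],
        }
    )
    med = d.groupby(["repeat", "bin"])["value"].median().unstack("bin")
    med = med.reindex(columns=range(nbins))
    z = med.copy()
    for rid in med.index:
        row = med.loc[rid].to_numpy(dtype=float)
        ok = np.isfinite(row)
        if ok.sum() >= 2 and np.std(row[ok]) > 0:
            z.loc[rid] = (row - row[ok].mean()) / np.std(row[ok])
        else:
            z.loc[rid] = np.nan
    centers = lo - lo + (np.arange(nbins) + 0.5) * bin_width
    return BinnedSeries(
        bin_width=bin_width,
        bin_centers=centers,
        medians=med,
        z_scores=z,
        repeat_ids=list(med.index),
    )


def day_night_summary(
    df: pd.DataFrame,
    value_col: str,
    repeat_col: str = "repeat_id",
    phase_col: str = "phase",
) -> dict:
    """Pooled median [IQR] per phase plus per-repeat medians, transitions excluded.

    Returns ``{"pooled": DataFrame(phase x [median, iqr, n]),
    "per_repeat": DataFrame(repeat x phase)}``.  A phase with zero records
    is simply missing from the tables (logged).
    """
    kept = df[df[phase_col] != TRANSITION]
    pooled_rows = {}
    for phase in (DAY, NIGHT):
        v = kept.loc[kept[phase_col] == phase, value_col].dropna().to_numpy()
        if v.size == 0:
            logger.warning("no records in phase %r for %s", phase, value_col)
            continue
        q1, q3 = np.percentile(v, [25, 75])
        pooled_rows[phase] = {"median": float(np.median(v)), "iqr": float(q3 - q1), "n": v.size}
    per_repeat = (
        kept.groupby([repeat_col, phase_col])[value_col].median().unstack(phase_col)
        if len(kept)
        else pd.DataFrame()
    )
    return {"pooled": pd.DataFrame(pooled_rows).T, "per_repeat": per_repeat}


def autocorrelation(
    series: BinnedSeries,
    max_lag: float = 36.0,
    search_band: tuple[float, float] = (18.0, 30.0),
    max_missing_frac: float = 0.2,
) -> AutocorrResult:
    """Lag-0-normalized autocorrelation of each repeat's binned medians.

    Per repeat: missing bins are linearly interpolated when they make up at
    most ``max_missing_frac`` of the series (otherwise the repeat is
    excluded with a logged reason); the coefficient at lag k is the Pearson
    correlation of the series with its k-lag shift over the overlapping
    span (each segment demeaned and scaled by its own SD, i.e. the
    per-overlap-count normalized cross-correlation).  With this estimator a
    pure periodic series attains exactly 1 at its period and the lag-0
    value is 1, so the curve is already normalized to lag 0.  ``peak_lag``
    is the argmax of the coefficient within the search band.
    """
    bw = series.bin_width
    max_k = int(round(max_lag / bw))
    n_bins = len(series.bin_centers)
    if n_bins < max_k + 2:
        raise ValueError(
            f"series has {n_bins} bins; too short for max_lag {max_lag} h at {bw} h bins"
        )
    lags = np.arange(max_k + 1) * bw
    band_lo, band_hi = search_band
    in_band = (lags >= band_lo) & (lags <= band_hi)

    coeffs = {}
    peaks = {}
    excluded = []
    for rid in series.repeat_ids:
        v = series.medians.loc[rid].to_numpy(dtype=float)
        missing = ~np.isfinite(v)
        if missing.mean() > max_missing_frac:
            logger.warning(
                "repeat %r excluded from autocorrelation: %.0f%% bins missing",
                rid, 100 * missing.mean(),
            )
            excluded.append(rid)
            continue
        if missing.any():
            idx = np.arange(n_bins)
            v = v.copy()
            v[missing] = np.interp(idx[missing], idx[~missing], v[~missing])
        if np.std(v) == 0:
            raise ValueError(f"repeat {rid!r}: zero-variance series has no rhythm")
        rho = np.empty(max_k + 1)
        rho[0] = 1.0
        for k in range(1, max_k + 1):
            a, b = v[: n_bins - k], v[k:]
            sa, sb = a.std(), b.std()
            if sa == 0 or sb == 0:
                rho[k] = 0.0
                continue
            rho[k] = np.mean((a - a.mean()) * (b - b.mean())) / (sa * sb)
        coeffs[rid] = rho
        peaks[rid] = float(lags[in_band][np.argmax(rho[in_band])])
    return AutocorrResult(
        lags=lags,
        coefficients=pd.DataFrame(coeffs, index=lags).T,
        peak_lag=pd.Series(peaks),
        search_band=search_band,
        excluded=excluded,
    )
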