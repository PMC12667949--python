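"""Postural compensation: robust regression of bout rotation on IBI drift.

Between bouts, a larva passively drifts nose-down; during the next bout it
rotates nose-up.  Regressing bout rotation on the drift of the preceding IBI
with Tukey bi-square (robust IRLS) regression yields a slope whose absolute
value is the **compensation gain**: 1 means the bout fully corrects the
drift accrued since the previous bout.  The **compensation residual**
(drift + subsequent rotation) is zero under perfect compensation, and its
median absolute deviation quantifies compensation precision.

Bouts are split by whether the flanking IBI is *long* or *short* relative to
the median dark-condition IBI duration, and the regression is run for both
the preceding and the following IBI; drift should predict the *following*
bout's rotation (compensation), not the other way around (anticipation).
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

#: Tukey bisquare tuning constant (95% Gaussian efficiency)
TUKEY_C = 4.685
#: consistency factor: scale = MAD_FACTOR * median(|residual|)
MAD_FACTOR = 1.4826

LONG, SHORT = "long", "short"


@dataclasses.dataclass
class CompensationFit:
    """Robust-regression result for one drift-rotation cell."""

    slope: float
    intercept: float
    gain: float  # |slope|
    r_squared: float  # unweighted, about the robust line
    n: int
    bootstrap_p: float | None = None
    converged: bool = True
    n_iter: int = 0
    ibi_class: str | None = None  # {"long", "short"}
    ibi_side: str | None = None  # {"previous", "next"}


@dataclasses.dataclass
class ResidualSummary:
    residuals: np.ndarray  # deg per bout
    variability: float  # deg, median absolute deviation


def _wls_line(x: np.ndarray, y: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Closed-form weighted least squares for intercept + slope."""
    sw = w.sum()
    mx = (w * x).sum() / sw
    my = (w * y).sum() / sw
    sxx = (w * (x - mx) ** 2).sum()
    if sxx == 0:
        raise ValueError("zero weighted variance in predictor")
    slope = (w * (x - mx) * (y - my)).sum() / sxx
    return np.array([my - slope * mx, slope])


def tukey_bisquare_line(
    x: np.ndarray,
    y: np.ndarray,
    c: float = TUKEY_C,
    tol: float = 1e-8,
    max_iter: int = 50,
) -> tuple[float, float, bool, int]:
    """Fit ``y = a + b*x`` by IRLS with Tukey bisquare weights.

    The robust scale is re-estimated each iteration as
    ``1.4826 * median(|residual|)``; weights are
    ``(1 - (r/(c*s))^2)^2`` inside ``|r| < c*s`` and zero outside.
    Convergence: max coefficient change below ``tol`` (or ``max_iter``).

    Returns ``(intercept, slope, converged, n_iter)``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    beta = _wls_line(x, y, np.ones_like(x))  # OLS start
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        r = y - beta[0] - beta[1] * x
        s = MAD_FACTOR * np.median(np.abs(r))
        if s == 0:  # perfect fit
            converged = True
            break
        u = r / (c * s)
        w = np.where(np.abs(u) < 1.0, (1.0 - u**2) ** 2, 0.0)
        if w.sum() == 0 or np.count_nonzero(w) < 2:
            break
        new = _wls_line(x, y, w)
        if np.max(np.abs(new - beta)) < tol:
            beta = new
            converged = True
            break
        beta = new
    return float(beta[0]), float(beta[1]), converged, it


def fit_compensation(
    drift: np.ndarray,
    rotation: np.ndarray,
    min_n: int = 10,
    c: float = TUKEY_C,
    tol: float = 1e-8,
    max_iter: int = 50,
) -> CompensationFit:
    """Robust fit of bout rotation against IBI drift.

    ``r_squared`` is the unweighted ``1 - SS_res/SS_tot`` of all points
    about the robust line (it can be negative when outliers dominate).
    Non-convergence yields a flagged result with the last iterate.
    """
    drift = np.asarray(drift, dtype=float)
    rotation = np.asarray(rotation, dtype=float)
    if drift.shape != rotation.shape or drift.ndim != 1:
        raise ValueError("drift and rotation must be 1-D arrays of equal length")
    if not (np.all(np.isfinite(drift)) and np.all(np.isfinite(rotation))):
        raise ValueError("inputs must be finite")
    n = len(drift)
    if n < min_n:
        raise ValueError(f"need at least {min_n} paired bouts, got {n}")
    if np.ptp(drift) == 0:
        raise ValueError("zero variance in drift")
    a, b, conv, it = tukey_bisquare_line(drift, rotation, c=c, tol=tol, max_iter=max_iter)
    resid = rotation - a - b * drift
    ss_tot = np.sum((rotation - rotation.mean()) ** 2)
    r2 = 1.0 - np.sum(resid**2) / ss_tot if ss_tot > 0 else np.nan
    return CompensationFit(
        slope=b, intercept=a, gain=abs(b), r_squared=float(r2), n=n,
        converged=conv, n_iter=it,
    )


def bootstrap_slope_p(
    drift: np.ndarray,
    rotation: np.ndarray,
    B: int = 1000,
    seed: int | np.random.Generator = 0,
) -> float:
    """Two-sided bootstrap p-value for the bi-square slope differing from 0.

    Case (pair) resampling — robust-fit residuals are not exchangeable under
    heteroscedasticity, so residual resampling is avoided.  The p-value is
    twice the add-one-corrected fraction of bootstrap slopes on the opposite
    side of zero from the point estimate, capped at 1.  Deterministic given
    ``seed``.
    """
    if B <= 0:
        raise ValueError("B must be positive")
    drift = np.asarray(drift, dtype=float)
    rotation = np.asarray(rotation, dtype=float)
    point = fit_compensation(drift, rotation).slope
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n = len(drift)
    slopes = np.empty(B)
    for i in range(B):
        idx = rng.integers(0, n, n)
        try:
            _, b, _, _ = tukey_bisquare_line(drift[idx], rotation[idx])
        except ValueError:  # degenerate resample
            b = point
        slopes[i] = b
    opposite = np.sum(slopes >= 0.0) if point < 0 else np.sum(slopes <= 0.0)
    return float(min(1.0, 2.0 * (opposite + 1) / (B + 1)))


def classify_ibi(
    durations: np.ndarray, reference: np.ndarray
) -> tuple[np.ndarray, float]:
    """Label IBIs ``long``/``short`` against the median reference duration.

    The reference is the pool of dark-condition IBI durations; an IBI is
    long iff its duration strictly exceeds the reference median (ties are
    short).  Returns ``(labels, threshold)``.
    """
    reference = np.asarray(reference, dtype=float)
    if reference.size == 0:
        raise ValueError("empty reference durations")
    threshold = float(np.median(reference))
    durations = np.asarray(durations, dtype=float)
    labels = np.where(durations > threshold, LONG, SHORT)
    return labels, threshold


def select_middle_bouts(bout_df: pd.DataFrame) -> pd.DataFrame:
    """Bouts with both a preceding and a following IBI in the same epoch —
    the middle bouts of 3-bout sequences (an epoch with k >= 3 bouts yields
    k − 2 of them)."""
    return bout_df[(bout_df["prev_ibi"] >= 0) & (bout_df["next_ibi"] >= 0)]


def compensation_residuals(drift: np.ndarray, rotation: np.ndarray) -> ResidualSummary:
    """Residual = drift + subsequent rotation; variability = MAD of residuals."""
    drift = np.asarray(drift, dtype=float)
    rotation = np.asarray(rotation, dtype=float)
    if drift.size == 0:
        raise ValueError("empty input")
    res = drift + rotation
    mad = float(np.median(np.abs(res - np.median(res))))
    return ResidualSummary(residuals=res, variability=mad)


def compensation_report(
    bout_df: pd.DataFrame,
    reference_durations: np.ndarray,
    bootstrap: int = 0,
    seed: int = 0,
    min_n: int = 10,
) -> pd.DataFrame:
    """Compensation table: (long/short IBI) x (previous/next IBI) [x group].

    Middle bouts only.  Each row reports the bi-square slope, R², n and —
    when ``bootstrap > 0`` — the bootstrap p-value, plus the long/short
    threshold used.  When a ``group_label`` column is present the layout is
    repeated per group (e.g. control vs lesion recordings).
    """
    mid = select_middle_bouts(bout_df)
    groups = (
        [(g, sub) for g, sub in mid.groupby("group_label", sort=False)]
        if "group_label" in mid.columns
        else [(None, mid)]
    )
    rows = []
    rng = np.random.default_rng(seed)
    for group, gmid in groups:
        for side, dur_col, drift_col in (
            ("previous", "prev_ibi_s", "prev_drift_deg"),
            ("next", "next_ibi_s", "next_drift_deg"),
        ):
            labels, thr = classify_ibi(gmid[dur_col].to_numpy(), reference_durations)
            for cls in (LONG, SHORT):
                sel = gmid[labels == cls]
                drift = sel[drift_col].to_numpy()
                rot = sel["rotation_deg"].to_numpy()
                row = {"ibi_class": cls, "ibi_side": side, "threshold_s": thr, "n": len(sel)}
                if group is not None:
                    row["group_label"] = group
                if len(sel) >= min_n and np.ptp(drift) > 0:
                    fit = fit_compensation(drift, rot, min_n=min_n)
                    row.update(
                        slope=fit.slope, gain=fit.gain, r_squared=fit.r_squared,
                        converged=fit.converged,
                    )
                    if bootstrap > 0:
                        row["bootstrap_p"] = bootstrap_slope_p(drift, rot, B=bootstrap, seed=rng)
                else:
                    row.update(slope=np.nan, gain=np.nan, r_squared=np.nan, converged=False)
                rows.append(row)
    return pd.DataFrame(rows)
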