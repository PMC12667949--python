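"""Statistical toolbox: median test, Scott's rule, repeat-median t-tests.

Swim-kinematic distributions are heavy-tailed and non-Gaussian, so pooled
group comparisons use Mood's median test with the standardized chi-squared
effect size χ²/N (analogous to a squared correlation; bounded by 1 for a
2x2 table).  Headline comparisons summarize each experimental repeat by its
median and compare the means of those medians with an independent t-test
plus Cohen's d.  Histogram bin widths follow Scott's rule.
"""

from __future__ import annotations

import dataclasses
import math
import warnings

import numpy as np
import pandas as pd
import scipy.stats


@dataclasses.dataclass
class MedianTestResult:
    chi2: float
    p: float
    effect_size: float  # chi2 / N
    contingency: np.ndarray  # 2 x K counts (above / not above pooled median)
    pooled_median: float


@dataclasses.dataclass
class RepeatTestResult:
    group_means: tuple[float, float]  # means of per-repeat medians
    t: float
    p: float
    cohen_d: float
    per_repeat_medians: pd.DataFrame


def median_test(*groups) -> MedianTestResult:
    """Mood's median test over K >= 2 samples.

    Counts above vs **not above** the pooled median (ties count as not
    above), chi-squared with K−1 df and no continuity correction.  The
    effect size is χ²/N.  All-identical values make the contingency table
    degenerate and raise ``ValueError``.
    """
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    groups = [np.asarray(g, dtype=float) for g in groups]
    for g in groups:
        if g.size < 1:
            raise ValueError("each group needs at least one value")
    try:
        chi2, p, med, table = scipy.stats.median_test(
            *groups, ties="below", correction=False
        )
    except ValueError as e:
        raise ValueError(f"degenerate contingency table: {e}") from e
    n = sum(g.size for g in groups)
    return MedianTestResult(
        chi2=float(chi2),
        p=float(p),
        effect_size=float(chi2) / n,
        contingency=np.asarray(table),
        pooled_median=float(med),
    )


def scott_bins(values) -> np.ndarray:
    """Histogram bin edges by Scott's rule: width ``3.49 * SD * n^(-1/3)``.

    The bin count is ``ceil(range / h)`` and the edges span exactly
    ``[min, max]``; doubling all values doubles the width and preserves the
    count.  Zero spread falls back to a single bin with a warning.
    """
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise ValueError("need at least 2 values")
    sd = float(np.std(v, ddof=1))
    lo, hi = float(v.min()), float(v.max())
    if sd == 0:
        warnings.warn("zero SD; falling back to a single bin")
        return np.array([lo, hi if hi > lo else lo + 1.0])
    h = 3.49 * sd * v.size ** (-1.0 / 3.0)
    nbins = max(1, math.ceil((hi - lo) / h - 1e-9))
    return np.linspace(lo, hi, nbins + 1)


def repeat_summary_test(
    values,
    repeat_ids,
    group_labels,
    equal_var: bool = True,
) -> RepeatTestResult:
    """Compare two groups by the means of their per-repeat medians.

    Each experimental repeat is collapsed to its median; the medians are
    compared with an independent two-sample t-test (equal-variance by
    default, Welch via ``equal_var=False``) and Cohen's d with pooled SD.
    d is positive when the first group's mean exceeds the second's and
    flips sign under group swap.  Fewer than 2 repeats in a group is an
    error (no variance estimate).
    """
    df = pd.DataFrame(
        {"value": np.asarray(values, dtype=float),
         "repeat": np.asarray(repeat_ids),
         "group": np.asarray(group_labels)}
    )
    glabels = list(pd.unique(df["group"]))
    if len(glabels) != 2:
        raise ValueError(f"expected exactly 2 groups, got {glabels}")
    med = df.groupby(["group", "repeat"])["value"].median()
    a = med.loc[glabels[0]].to_numpy()
    b = med.loc[glabels[1]].to_numpy()
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least 2 repeats")
    sp = math.sqrt(
        ((len(a) - 1) * a.var(ddof=1) + (len(b) - 1) * b.var(ddof=1))
        / (len(a) + len(b) - 2)
    )
    if sp == 0 and a.mean() == b.mean():  # degenerate: all medians identical
        t, p, d = 0.0, 1.0, 0.0
    else:
        t, p = scipy.stats.ttest_ind(a, b, equal_var=equal_var)
        d = (a.mean() - b.mean()) / sp if sp > 0 else math.inf

    return RepeatTestResult(
        group_means=(float(a.mean()), float(b.mean())),
        t=float(t),
        p=float(p),
        cohen_d=float(d),
        per_repeat_medians=med.unstack("repeat"),
    )


def summary_table(
    df: pd.DataFrame,
    parameters: dict[str, str],
    condition_col: str = "condition",
    contrast: tuple[str, str] | None = None,
) -> pd.DataFrame:
    """Pooled median [IQR] per parameter x condition, with a median-test
    contrast.

    ``parameters`` maps column name -> unit label.  When ``contrast`` names
    two conditions present in the data, a median-test p-value and χ²/N
    effect size are appended for that pair.  Conditions absent from the
    data are omitted with a warning.
    """
    conditions = [c for c in pd.unique(df[condition_col])]
    rows = []
    for col, unit in parameters.items():
        row: dict = {"parameter": col, "unit": unit}
        for cond in conditions:
            v = df.loc[df[condition_col] == cond, col].dropna().to_numpy()
            if v.size == 0:
                warnings.warn(f"no data for condition {cond!r}, parameter {col!r}")
                continue
            q1, q3 = np.percentile(v, [25, 75])
            row[f"{cond}_median"] = float(np.median(v))
            row[f"{cond}_iqr"] = float(q3 - q1)
            row[f"{cond}_n"] = int(v.size)
        if contrast is not None and all(c in conditions for c in contrast):
            g1 = df.loc[df[condition_col] == contrast[0], col].dropna().to_numpy()
            g2 = df.loc[df[condition_col] == contrast[1], col].dropna().to_numpy()
            if g1.size and g2.size:
                try:
                    mt = median_test(g1, g2)
                    row["p"] = mt.p
                    row["effect_size"] = mt.effect_size
                except ValueError:
                    row["p"] = np.nan
                    row["effect_size"] = np.nan
        rows.append(row)
    return pd.DataFrame(rows)
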