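"""End-to-end orchestration: config, staged runs, report tables, manifest.

A run takes one or more recordings (track files on disk and/or generator
scenarios), segments each into bouts and IBIs, measures kinematics, and
derives the compensation, navigation and circadian analyses plus pooled
summary tables.  Every output is a CSV in the run directory; a JSON
manifest records the full configuration, a config hash, the seed and the
record counts after each stage, so any table can be reproduced from the
manifest alone.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import circadian as circ
from . import compensation as comp
from . import navigation as nav
from . import stats as bstats
from .kinematics import bout_table, ibi_table
from .segmentation import SegmentationParams, segment_recording
from .simulate import SwimmerParams, generate_recording, preset
from .track_io import DAY, NIGHT, RecordingMeta, read_tracks

logger = logging.getLogger(__name__)

#: bout-table columns summarized in the kinematics report
BOUT_PARAMS = {
    "peak_speed": "mm/s",
    "displacement_mm": "mm",
    "duration_fwhm_ms": "ms",
    "rotation_deg": "deg",
    "direction_deg": "deg",
}
IBI_PARAMS = {"duration_s": "s", "drift_deg": "deg"}
NAV_PARAMS = {"displacement_per_s": "mm/s", "dirchange_per_s": "deg/s"}


@dataclasses.dataclass
class RunConfig:
    """Everything a pipeline run depends on.

    ``inputs`` are track-file paths; ``simulate`` entries are generator
    scenarios ``{"preset": name, "seed": int, "repeat_id": str,
    "overrides": {...}}``.  All stage parameters are explicit here; the
    manifest prints them all (no hidden defaults).
    """

    outdir: str = "run"
    inputs: list = dataclasses.field(default_factory=list)
    input_format: str | None = None
    simulate: list = dataclasses.field(default_factory=list)
    threshold: float = 5.0
    smooth_window: int = 3
    min_duration: float = 0.018
    merge_gap: float = 0.05
    bin_width_h: float = 2.0
    autocorr_bin_h: float = 0.5
    max_lag_h: float = 36.0
    analysis_window: tuple = (10.0, 58.0)
    apply_analysis_window: bool = False
    long_ibi_threshold: float | None = None  # None -> median of dark reference
    bootstrap_B: int = 0
    seed: int = 0
    reports: tuple = ("kinematics", "compensation", "navigation", "circadian")

    def segmentation_params(self) -> SegmentationParams:
        return SegmentationParams(
            threshold=self.threshold,
            smooth_window=self.smooth_window,
            min_duration=self.min_duration,
            merge_gap=self.merge_gap,
        )

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["analysis_window"] = list(self.analysis_window)
        d["reports"] = list(self.reports)
        return d

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        if "analysis_window" in d:
            d["analysis_window"] = tuple(d["analysis_window"])
        if "reports" in d:
            d["reports"] = tuple(d["reports"])
        return cls(**d)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    def hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def load_recordings(config: RunConfig) -> list[tuple[list, RecordingMeta]]:
    """Materialize every input: read track files, run generator scenarios."""
    recs = []
    for path in config.inputs:
        tf = read_tracks(path, config.input_format)
        if tf.rejected:
            logger.warning("%s: %d epoch(s) rejected", path, len(tf.rejected))
        recs.append((tf.tracks, tf.meta))
    for i, spec in enumerate(config.simulate):
        spec = dict(spec)
        name = spec.pop("preset")
        seed = spec.pop("seed", config.seed + i)
        repeat_id = spec.pop("repeat_id", f"sim{i}")
        overrides = spec.pop("overrides", {})
        if spec:
            raise ValueError(f"unknown simulate key(s): {sorted(spec)}")
        params = preset(name, seed=seed, **overrides)
        tracks, meta, _log = generate_recording(params, repeat_id=repeat_id)
        recs.append((tracks, meta))
    return recs


def analyze_recording(
    tracks, meta: RecordingMeta, params: SegmentationParams
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Segment + measure one recording; attach metadata columns."""
    bouts, ibis = segment_recording(tracks, meta, params)
    bdf = bout_table(bouts, ibis)
    idf = ibi_table(ibis)
    for df in (bdf, idf):
        df["condition"] = meta.condition
        df["repeat_id"] = meta.repeat_id
        df["group_label"] = meta.group_label
    if len(bdf):
        bdf["abs_hours"] = meta.recording_start_clock + bdf["peak_time"] / 3600.0
    else:
        bdf["abs_hours"] = pd.Series(dtype=float)
    if len(idf):
        # IBI midpoint time from linked bout peak times
        mid_t = (
            bdf["peak_time"].to_numpy()[idf["preceding_bout"].to_numpy()]
            + bdf["peak_time"].to_numpy()[idf["following_bout"].to_numpy()]
        ) / 2.0
        idf["abs_hours"] = meta.recording_start_clock + mid_t / 3600.0
    else:
        idf["abs_hours"] = pd.Series(dtype=float)
    return bdf, idf


def dark_ibi_reference(ibi_df: pd.DataFrame) -> np.ndarray:
    """IBI durations recorded in darkness, the long/short reference pool.

    DD recordings contribute their zeitgeber-day IBIs (the paper's default
    dark pool); LD recordings contribute night IBIs (lights off).  If no
    dark IBIs exist at all, all IBIs are used with a warning.
    """
    sel = (
        ((ibi_df["condition"] == "DD") & (ibi_df["phase"] == DAY))
        | ((ibi_df["condition"] == "LD") & (ibi_df["phase"] == NIGHT))
    )
    ref = ibi_df.loc[sel, "duration_s"].to_numpy()
    if ref.size == 0:
        logger.warning("no dark-condition IBIs; using all IBIs as reference")
        ref = ibi_df["duration_s"].to_numpy()
    return ref


def make_summary_tables(
    bout_df: pd.DataFrame, ibi_df: pd.DataFrame, nav_df: pd.DataFrame
) -> dict[str, pd.DataFrame]:
    """Pooled median [IQR] report tables.

    ``kinematics_day``: day-phase bout/IBI parameters per condition, with a
    median-test contrast between the first two conditions present.
    ``day_vs_night``: day vs night medians per condition x parameter.
    ``navigation_day``: navigation rates per condition.
    """
    out: dict[str, pd.DataFrame] = {}
    conditions = list(pd.unique(bout_df["condition"]))
    contrast = tuple(conditions[:2]) if len(conditions) >= 2 else None

    day_b = bout_df[bout_df["phase"] == DAY]
    day_i = ibi_df[ibi_df["phase"] == DAY]
    parts = []
    if len(day_b):
        parts.append(bstats.summary_table(day_b, BOUT_PARAMS, contrast=contrast))
    if len(day_i):
        parts.append(bstats.summary_table(day_i, IBI_PARAMS, contrast=contrast))
    if parts:
        out["kinematics_day"] = pd.concat(parts, ignore_index=True)

    rows = []
    for cond in conditions:
        for df, pmap in ((bout_df, BOUT_PARAMS), (ibi_df, IBI_PARAMS)):
            sub = df[df["condition"] == cond]
            for col, unit in pmap.items():
                summ = circ.day_night_summary(sub, col)["pooled"]
                row = {"condition": cond, "parameter": col, "unit": unit}
                for phase in (DAY, NIGHT):
                    if phase in summ.index:
                        row[f"{phase}_median"] = summ.loc[phase, "median"]
                        row[f"{phase}_iqr"] = summ.loc[phase, "iqr"]
                        row[f"{phase}_n"] = int(summ.loc[phase, "n"])
                d_vals = sub.loc[sub["phase"] == DAY, col].dropna()
                n_vals = sub.loc[sub["phase"] == NIGHT, col].dropna()
                if len(d_vals) and len(n_vals):
                    try:
                        mt = bstats.median_test(d_vals, n_vals)
                        row["p"], row["effect_size"] = mt.p, mt.effect_size
                    except ValueError:
                        pass
                rows.append(row)
    out["day_vs_night"] = pd.DataFrame(rows)

    if len(nav_df) and "condition" in nav_df.columns:
        day_n = nav_df[nav_df["phase"] == DAY]
        if len(day_n):
            out["navigation_day"] = bstats.summary_table(day_n, NAV_PARAMS, contrast=contrast)
    return out


def run_pipeline(config: RunConfig) -> dict[str, Any]:
    """Execute all stages and write every output CSV plus the manifest.

    Stage order: segmentation -> kinematics -> compensation / navigation /
    circadian -> summary tables.  Deterministic given the config (generator
    seeds live in the config).  Any stage failure aborts with the stage
    name; stages that have nothing to work on (e.g. no dark bouts for
    compensation) are skipped with a logged reason, not an error.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    counts: dict[str, int] = {}

    recs = load_recordings(config)
    seg = config.segmentation_params()
    bout_frames, ibi_frames = [], []
    for tracks, meta in recs:
        bdf, idf = analyze_recording(tracks, meta, seg)
        bout_frames.append(bdf)
        ibi_frames.append(idf)
    bout_df = pd.concat(bout_frames, ignore_index=True) if bout_frames else pd.DataFrame()
    ibi_df = pd.concat(ibi_frames, ignore_index=True) if ibi_frames else pd.DataFrame()
    counts["recordings"] = len(recs)
    counts["bouts"] = len(bout_df)
    counts["ibis"] = len(ibi_df)

    if config.apply_analysis_window and len(bout_df):
        n0 = len(bout_df)
        bout_df = circ.extract_analysis_window(bout_df, tuple(config.analysis_window))
        ibi_df = circ.extract_analysis_window(ibi_df, tuple(config.analysis_window))
        counts["bouts_in_window"] = len(bout_df)
        logger.info("analysis window: %d -> %d bouts", n0, len(bout_df))

    results: dict[str, Any] = {"bouts": bout_df, "ibis": ibi_df}
    bout_df.to_csv(outdir / "bouts.csv", index=False)
    ibi_df.to_csv(outdir / "ibis.csv", index=False)

    nav_df = pd.DataFrame()
    if "navigation" in config.reports and len(bout_df):
        navs = []
        for (cond, rep), sub in bout_df.groupby(["condition", "repeat_id"]):
            nd = nav.build_navigation_epochs(sub)
            nd["condition"] = cond
            nd["repeat_id"] = rep
            navs.append(nd)
        nav_df = pd.concat(navs, ignore_index=True) if navs else pd.DataFrame()
        counts["navigation_epochs"] = len(nav_df)
        nav_df.to_csv(outdir / "navigation.csv", index=False)
        results["navigation"] = nav_df

    if "compensation" in config.reports and len(bout_df):
        if config.long_ibi_threshold is not None:
            ref = np.array([config.long_ibi_threshold, config.long_ibi_threshold])
        else:
            ref = dark_ibi_reference(ibi_df)
        mid = comp.select_middle_bouts(bout_df)
        if len(mid) >= 10 and ref.size:
            report = comp.compensation_report(
                bout_df, ref, bootstrap=config.bootstrap_B, seed=config.seed
            )
            report.to_csv(outdir / "compensation.csv", index=False)
            results["compensation"] = report
            counts["middle_bouts"] = len(mid)
        else:
            logger.warning("compensation skipped: %d middle bouts", len(mid))

    if "circadian" in config.reports and len(bout_df):
        binned = circ.bin_medians(
            bout_df["duration_fwhm_ms"],
            bout_df["abs_hours"],
            bout_df["repeat_id"],
            bin_width=config.bin_width_h,
            window=tuple(config.analysis_window),
        )
        med = binned.medians.stack().rename("median").reset_index()
        med.columns = ["repeat_id", "bin", "median"]
        med["z"] = binned.z_scores.stack().reset_index(drop=True)
        med["bin_center_h"] = binned.bin_centers[med["bin"].to_numpy(dtype=int)]
        med.to_csv(outdir / "circadian_bout_duration.csv", index=False)
        results["circadian_binned"] = binned
        fine = circ.bin_medians(
            bout_df["duration_fwhm_ms"],
            bout_df["abs_hours"],
            bout_df["repeat_id"],
            bin_width=config.autocorr_bin_h,
            window=tuple(config.analysis_window),
        )
        try:
            ac = circ.autocorrelation(fine, max_lag=config.max_lag_h)
            ac.coefficients.T.to_csv(outdir / "autocorrelation.csv")
            results["autocorrelation"] = ac
        except ValueError as e:
            logger.warning("autocorrelation skipped: %s", e)

    tables = make_summary_tables(bout_df, ibi_df, nav_df) if len(bout_df) else {}
    for name, tbl in tables.items():
        tbl.to_csv(outdir / f"summary_{name}.csv", index=False)
    results["tables"] = tables

    manifest = {
        "config": config.to_dict(),
        "config_hash": config.hash(),
        "seed": config.seed,
        "counts": counts,
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    results["manifest"] = manifest
    return results
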