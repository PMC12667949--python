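"""Generative model of bout-based larval swimming.

The swimmer is an alternating renewal process: inactive inter-bout
intervals (IBIs) alternate with discrete swim bouts.

* **IBI** — duration ~ Gamma(shape, mean ``ibi_mean * c(t)``) where
  ``c(t) = 1 + A cos(2π (t − phase)/period)`` is the circadian modulation of
  the current strategy's mean.  During the IBI the pitch integrates a
  nose-down drift ``dθ = −ω dt + drift_noise dW`` and the fish sinks at
  ``sink_rate``.
* **Bout** — a Gaussian speed pulse sampled on the frame grid:
  ``s(u) = P exp(−u²/2σ_s²)`` with ``σ_s = τ / (2 sqrt(2 ln 2))`` so the
  pulse's full width at half maximum is exactly the drawn duration τ
  (LogNormal, circadian-modulated mean).  Peak speed P is LogNormal, swim
  direction φ ~ Normal(μ_φ, σ_φ) with a persistent ±1 horizontal heading
  that flips with small probability per bout.  Positions integrate the
  pulse along ``(±cos φ, sin φ)``.  The bout's pitch change is
  ``−g·(drift accrued since the previous bout's window end) + bias + ε``,
  applied as a raised-cosine ramp across the −250…+200 ms window so the
  endpoint-difference rotation of the analysis recovers it exactly, and so
  bout rotations and IBI drifts tile the pitch trajectory.

Light-dark (LD) schedules switch the *strategy parameter set* (dark: long,
infrequent, steep bouts; light: short, frequent, direction-variable bouts)
at the lights-on/off clock times, emulating the masking effect of light.
Under DD the dark set applies throughout, under LL the light set.

Every recording comes with a ground-truth event log so each analysis stage
can be checked against the generating parameters.  Identical parameters and
seed reproduce the tracks bitwise.

The defaults are anchored to day-time wild-type behavior: dark-strategy
bout-duration median ≈ 145 ms vs light ≈ 72 ms, IBI medians ≈ 1.6 s vs
0.55 s, dark IBI drift median ≈ −4.3°, and compensation gain 0.86.  Absolute
pitch is a random walk with drift (only pitch *increments* are analyzed);
absolute depth likewise sinks without bound since no arena walls are
modeled.
"""

from __future__ import annotations

import dataclasses
import math

import numpy as np
import pandas as pd

from .track_io import RecordingMeta, TrackSeries, attach_clock

_FWHM_SIGMA = 2.0 * math.sqrt(2.0 * math.log(2.0))  # FWHM = this * sigma


@dataclasses.dataclass
class StrategyParams:
    """Bout/IBI distribution parameters for one lighting strategy."""

    ibi_mean: float  # s, mean gap between bout windows
    ibi_shape: float  # gamma shape
    fwhm_mean: float  # ms, mean bout duration (FWHM of the speed pulse)
    fwhm_cv: float
    peak_speed_mean: float  # mm/s
    peak_speed_cv: float
    direction_mean: float  # deg, elevation; positive climbs
    direction_sd: float  # deg
    rotation_bias: float = 0.0  # deg, drift-independent nose-up steering

    def validate(self) -> None:
        for f in ("ibi_mean", "ibi_shape", "fwhm_mean", "fwhm_cv",
                  "peak_speed_mean", "peak_speed_cv", "direction_sd"):
            if getattr(self, f) <= 0:
                raise ValueError(f"StrategyParams.{f} must be > 0")


#: day-time dark-strategy defaults (DD zeitgeber day)
DARK = StrategyParams(
    ibi_mean=1.615, ibi_shape=1.5,
    fwhm_mean=149.7, fwhm_cv=0.25,
    peak_speed_mean=12.1, peak_speed_cv=0.4,
    direction_mean=13.0, direction_sd=4.0,
    rotation_bias=3.4,
)
#: day-time light-strategy defaults (LD/LL zeitgeber day)
LIGHT = StrategyParams(
    ibi_mean=0.222, ibi_shape=2.0,
    fwhm_mean=71.8, fwhm_cv=0.15,
    peak_speed_mean=14.55, peak_speed_cv=0.4,
    direction_mean=0.0, direction_sd=6.0,
    rotation_bias=0.65,
)


@dataclasses.dataclass
class SwimmerParams:
    """Full parameter set of the generative swimmer.

    ``drift_rate`` (ω, deg/s) is the nose-down pitch drift during IBIs
    (positive values make pitch decrease); ``gain`` is the fraction of the
    accrued drift corrected by the next bout's rotation; ``rotation_noise``
    (deg) is the SD of the rotation's stochastic part.  ``circadian_*``
    modulate the IBI and bout-duration means multiplicatively with peak at
    ``circadian_phase`` clock hours.  ``schedule`` selects which strategy
    set is active when.  ``pos_noise`` (mm) is per-frame tracking jitter
    added to positions; ``pitch_noise`` (deg) likewise for pitch.
    """

    frame_rate: float = 166.0
    drift_rate: float = 3.3  # deg/s, nose-down
    drift_noise: float = 0.3  # deg / sqrt(s)
    sink_rate: float = 0.2  # mm/s during IBIs
    dark: StrategyParams = dataclasses.field(default_factory=lambda: dataclasses.replace(DARK))
    light: StrategyParams = dataclasses.field(default_factory=lambda: dataclasses.replace(LIGHT))
    gain: float = 0.86
    rotation_noise: float = 3.0  # deg
    circadian_amplitude: float = 0.0
    circadian_period: float = 24.0  # h
    circadian_phase: float = 4.0  # clock h of peak modulation (mid-night)
    schedule: str = "DD"
    lights_on: float = 9.0
    lights_off: float = 23.0
    duration_h: float = 1.0
    start_clock: float = 10.0
    start_pitch: float = 5.0  # deg
    ibi_min: float = 0.05  # s, floor on drawn gaps
    min_peak_speed: float = 6.0  # mm/s; a bout is by definition detectable
    heading_flip_prob: float = 0.1  # per bout
    pos_noise: float = 0.005  # mm
    pitch_noise: float = 0.1  # deg
    pause_after_h: float | None = None  # optional feeding pause
    pause_duration_h: float = 0.5
    max_bouts: int | None = None
    seed: int = 0

    def validate(self) -> None:
        if self.frame_rate <= 0 or self.duration_h <= 0:
            raise ValueError("frame_rate and duration_h must be > 0")
        if not 0.0 <= self.circadian_amplitude < 1.0:
            raise ValueError("circadian_amplitude must lie in [0, 1)")
        if self.circadian_period <= 0:
            raise ValueError("circadian_period must be > 0")
        if self.schedule not in ("DD", "LD", "LL"):
            raise ValueError("schedule must be DD, LD or LL")
        if self.drift_rate <= 0 or self.drift_noise < 0 or self.sink_rate < 0:
            raise ValueError("drift parameters out of domain")
        if self.gain < 0 or self.rotation_noise < 0:
            raise ValueError("gain and rotation_noise must be >= 0")
        self.dark.validate()
        self.light.validate()


@dataclasses.dataclass
class GroundTruthLog:
    """Per-event ground truth emitted alongside the tracks.

    ``bouts`` columns: peak_time, fwhm_ms, peak_speed, direction_deg,
    rotation_deg, preceding_drift_deg, strategy, circadian_mult,
    run_start_t, run_end_t (threshold-crossing times of the analytic
    pulse).  ``ibis`` columns: start_t, end_t, duration_s (run-edge, the
    analysis definition of "time between two bouts") and drift_deg.
    """

    bouts: pd.DataFrame
    ibis: pd.DataFrame


def _lights_on_at(clock: float, p: SwimmerParams) -> bool:
    if p.schedule == "LL":
        return True
    if p.schedule == "DD":
        return False
    return p.lights_on <= clock < p.lights_off


def _lognormal(rng: np.random.Generator, mean: float, cv: float) -> float:
    s2 = math.log(1.0 + cv * cv)
    return float(rng.lognormal(math.log(mean) - 0.5 * s2, math.sqrt(s2)))


def generate_recording(
    params: SwimmerParams,
    repeat_id: str = "r0",
    threshold: float = 5.0,
) -> tuple[list[TrackSeries], RecordingMeta, GroundTruthLog]:
    """Simulate one recording: tracks + metadata + ground-truth log.

    ``threshold`` only affects the logged run-edge (threshold-crossing)
    times, for comparability with the analysis; it does not alter the
    dynamics.  Fully deterministic given ``params`` (including its seed).
    """
    params.validate()
    p = params
    fr = p.frame_rate
    rng = np.random.default_rng(p.seed)

    n = int(round(p.duration_h * 3600.0 * fr))
    pre_f = int(0.25 * fr)
    post_f = int(0.20 * fr)
    W = pre_f + post_f + 1

    pitch = np.empty(n)
    x = np.empty(n)
    z = np.empty(n)

    pitch_val = p.start_pitch
    x_val, z_val = 0.0, 0.0
    prev_we_pitch = pitch_val  # pitch at previous bout's window end
    heading = 1.0 if rng.random() < 0.5 else -1.0
    cur = 0
    n_bouts = 0
    A, per, pha = p.circadian_amplitude, p.circadian_period, p.circadian_phase
    u2 = (np.arange(W, dtype=float) - pre_f) ** 2  # squared frame offsets
    ramp_base = 0.5 * (1.0 - np.cos(np.pi * np.arange(W) / (W - 1)))

    bout_rows: list[dict] = []

    def _fill_drift(upto: int) -> None:
        """Advance pitch/x/z with pure IBI dynamics up to frame ``upto``."""
        nonlocal cur, pitch_val, z_val
        k = upto - cur
        if k <= 0:
            return
        steps = rng.standard_normal(k)
        steps *= p.drift_noise * math.sqrt(1.0 / fr)
        steps -= p.drift_rate / fr
        np.cumsum(steps, out=steps)
        steps += pitch_val
        pitch[cur:upto] = steps
        z[cur:upto] = z_val - p.sink_rate / fr * np.arange(1, k + 1)
        x[cur:upto] = x_val
        pitch_val = pitch[upto - 1]
        z_val = z[upto - 1]
        cur = upto

    while cur < n:
        abs_h = p.start_clock + cur / fr / 3600.0
        clock = abs_h % 24.0
        strat = p.light if _lights_on_at(clock, p) else p.dark
        mult = 1.0 + A * math.cos(2.0 * math.pi * (abs_h - pha) / per)

        gap = max(p.ibi_min, rng.gamma(strat.ibi_shape, strat.ibi_mean * mult / strat.ibi_shape))
        gap_f = max(1, int(round(gap * fr)))

        if (p.max_bouts is not None and n_bouts >= p.max_bouts) or cur + gap_f + W > n:
            _fill_drift(n)
            break

        _fill_drift(cur + gap_f)

        # ---- bout (strategy re-evaluated at the bout's own clock time, so
        # an LD switch takes effect with no carry-over) --------------------
        abs_h = p.start_clock + cur / fr / 3600.0
        strat = p.light if _lights_on_at(abs_h % 24.0, p) else p.dark
        mult = 1.0 + A * math.cos(2.0 * math.pi * (abs_h - pha) / per)
        tau_ms = _lognormal(rng, strat.fwhm_mean * mult, strat.fwhm_cv)
        peak = max(p.min_peak_speed, _lognormal(rng, strat.peak_speed_mean, strat.peak_speed_cv))
        phi = math.radians(rng.normal(strat.direction_mean, strat.direction_sd))
        if rng.random() < p.heading_flip_prob:
            heading = -heading

        sigma_f = (tau_ms / 1000.0) * fr / _FWHM_SIGMA  # pulse SD in frames
        sp = peak * np.exp(u2 / (-2.0 * sigma_f * sigma_f))
        inc = np.empty(W)  # trapezoid position increments, mm
        inc[0] = sp[0] / (2.0 * fr)
        np.add(sp[1:], sp[:-1], out=inc[1:])
        inc[1:] /= 2.0 * fr
        path = inc.cumsum()
        x[cur : cur + W] = x_val + heading * math.cos(phi) * path
        z[cur : cur + W] = z_val + math.sin(phi) * path

        accrued = pitch_val - prev_we_pitch
        rot = -p.gain * accrued + strat.rotation_bias + p.rotation_noise * rng.standard_normal()
        pitch[cur : cur + W] = pitch_val + rot * ramp_base

        peak_t = (cur + pre_f) / fr
        if peak > threshold:
            half_f = sigma_f * math.sqrt(2.0 * math.log(peak / threshold))
            run_start_t = (cur + pre_f - half_f) / fr
            run_end_t = (cur + pre_f + half_f) / fr
        else:  # sub-threshold bout: undetectable
            run_start_t = run_end_t = peak_t
        bout_rows.append(
            {
                "peak_time": peak_t,
                "fwhm_ms": tau_ms,
                "peak_speed": peak,
                "direction_deg": math.degrees(phi),
                "rotation_deg": rot,
                "preceding_drift_deg": accrued,
                "strategy": "light" if strat is p.light else "dark",
                "circadian_mult": mult,
                "run_start_t": run_start_t,
                "run_end_t": run_end_t,
            }
        )
        x_val = x[cur + W - 1]
        z_val = z[cur + W - 1]
        pitch_val = pitch[cur + W - 1]
        prev_we_pitch = pitch_val
        cur += W
        n_bouts += 1

    # observation noise (tracking jitter)
    if p.pos_noise > 0:
        x += rng.normal(0.0, p.pos_noise, n)
        z += rng.normal(0.0, p.pos_noise, n)
    if p.pitch_noise > 0:
        pitch += rng.normal(0.0, p.pitch_noise, n)

    # ---- epochs (the feeding pause breaks tracking) ----------------------
    meta = RecordingMeta(
        condition=p.schedule,
        repeat_id=repeat_id,
        lights_on_clock=p.lights_on,
        lights_off_clock=p.lights_off,
        frame_rate=fr,
        recording_start_clock=p.start_clock,
    )
    t = np.arange(n) / fr
    spans: list[tuple[int, int]] = []
    if p.pause_after_h is not None and p.pause_after_h * 3600 * fr < n:
        a = int(round(p.pause_after_h * 3600.0 * fr))
        b = min(n, a + int(round(p.pause_duration_h * 3600.0 * fr)))
        spans = [(0, a), (b, n)]
    else:
        spans = [(0, n)]
    tracks = []
    for i, (a, b) in enumerate(spans):
        if b - a < 2:
            continue
        tracks.append(
            attach_clock(
                TrackSeries(
                    epoch_id=f"e{i}",
                    t=t[a:b], x=x[a:b], z=z[a:b], pitch=pitch[a:b],
                    frame_rate=fr,
                ),
                meta,
            )
        )

    bouts_df = pd.DataFrame(
        bout_rows,
        columns=[
            "peak_time", "fwhm_ms", "peak_speed", "direction_deg", "rotation_deg",
            "preceding_drift_deg", "strategy", "circadian_mult",
            "run_start_t", "run_end_t",
        ],
    )
    if len(bouts_df) > 1:
        ibis_df = pd.DataFrame(
            {
                "start_t": bouts_df["run_end_t"].to_numpy()[:-1],
                "end_t": bouts_df["run_start_t"].to_numpy()[1:],
                "duration_s": bouts_df["run_start_t"].to_numpy()[1:]
                - bouts_df["run_end_t"].to_numpy()[:-1],
                "drift_deg": bouts_df["preceding_drift_deg"].to_numpy()[1:],
            }
        )
    else:
        ibis_df = pd.DataFrame(columns=["start_t", "end_t", "duration_s", "drift_deg"])
    return tracks, meta, GroundTruthLog(bouts=bouts_df, ibis=ibis_df)


PRESETS = ("dark_strategy", "light_strategy", "ld_masking", "circadian_dd")


def preset(name: str, seed: int = 0, **overrides) -> SwimmerParams:
    """Named scenario parameter sets.

    * ``dark_strategy`` — 12 h constant dark: long, infrequent bouts with
      large nose-up compensatory rotations (gain 0.86).
    * ``light_strategy`` — 12 h constant light: short, frequent,
      direction-variable bouts.
    * ``ld_masking`` — 48 h of a 14/10 light-dark cycle; the strategy set
      switches with the lights, masking any internal rhythm.
    * ``circadian_dd`` — 48 h constant dark with a 24 h modulation of bout
      and IBI durations (longer at circadian night).

    Extra keyword overrides are applied on top via ``dataclasses.replace``.
    """
    if name == "dark_strategy":
        p = SwimmerParams(schedule="DD", duration_h=12.0)
    elif name == "light_strategy":
        p = SwimmerParams(schedule="LL", duration_h=12.0)
    elif name == "ld_masking":
        p = SwimmerParams(schedule="LD", duration_h=48.0)
    elif name == "circadian_dd":
        p = SwimmerParams(schedule="DD", duration_h=48.0, circadian_amplitude=0.18)
    else:
        raise ValueError(f"unknown preset {name!r}; available: {', '.join(PRESETS)}")
    p = dataclasses.replace(p, seed=seed, **overrides)
    p.validate()
    return p


@dataclasses.dataclass
class RecoveryReport:
    """Truth-vs-pipeline comparison for one simulated recording."""

    n_true: int
    n_detected: int
    n_matched: int
    recall: float
    precision: float
    table: pd.DataFrame  # per-parameter bias and RMSE


def truth_vs_pipeline_report(
    log: GroundTruthLog,
    bout_df: pd.DataFrame,
    match_tol: float = 0.1,
    min_true_peak: float = 0.0,
) -> RecoveryReport:
    """Match pipeline bouts to ground truth and summarize recovery.

    Bouts are matched by nearest peak time within ``match_tol`` seconds.
    ``min_true_peak`` restricts the recall denominator to true bouts at or
    above that peak speed (sub-threshold bouts are undetectable by design).
    The table reports bias and RMSE of peak speed, duration, direction,
    rotation and preceding drift over matched pairs.
    """
    truth = log.bouts
    if min_true_peak > 0:
        truth_elig = truth[truth["peak_speed"] >= min_true_peak]
    else:
        truth_elig = truth
    det_t = np.sort(bout_df["peak_time"].to_numpy())
    order = np.argsort(bout_df["peak_time"].to_numpy())
    det = bout_df.iloc[order].reset_index(drop=True)

    pairs = []
    for ti, row in truth.iterrows():
        if len(det_t) == 0:
            break
        j = int(np.searchsorted(det_t, row["peak_time"]))
        best, bd = None, match_tol
        for jj in (j - 1, j):
            if 0 <= jj < len(det_t):
                d = abs(det_t[jj] - row["peak_time"])
                if d <= bd:
                    best, bd = jj, d
        if best is not None:
            pairs.append((ti, best))
    matched_true = {a for a, _ in pairs}
    matched_det = {b for _, b in pairs}
    n_true = len(truth_elig)
    n_matched_elig = len(matched_true & set(truth_elig.index))

    rows = []
    param_pairs = [
        ("peak_speed", "peak_speed", "peak_speed"),
        ("fwhm_ms", "fwhm_ms", "duration_fwhm_ms"),
        ("direction_deg", "direction_deg", "direction_deg"),
        ("rotation_deg", "rotation_deg", "rotation_deg"),
        ("preceding_drift_deg", "preceding_drift_deg", "prev_drift_deg"),
    ]
    if pairs:
        ti_idx = [a for a, _ in pairs]
        dj_idx = [b for _, b in pairs]
        for name, tcol, dcol in param_pairs:
            tv = truth.loc[ti_idx, tcol].to_numpy(dtype=float)
            dv = det.loc[dj_idx, dcol].to_numpy(dtype=float)
            ok = np.isfinite(tv) & np.isfinite(dv)
            if ok.sum() == 0:
                continue
            err = dv[ok] - tv[ok]
            rows.append(
                {"parameter": name, "n": int(ok.sum()),
                 "bias": float(err.mean()), "rmse": float(np.sqrt((err**2).mean()))}
            )
    return RecoveryReport(
        n_true=n_true,
        n_detected=len(det),
        n_matched=len(pairs),
        recall=n_matched_elig / n_true if n_true else np.nan,
        precision=len(matched_det) / len(det) if len(det) else np.nan,
        table=pd.DataFrame(rows, columns=["parameter", "n", "bias", "rmse"]),
    )
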