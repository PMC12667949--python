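"""Pose-track I/O: on-disk schema, validation, and photoperiod phase labels.

A recording is a collection of *epochs* — continuous, uniformly sampled
stretches of side-view tracking at a fixed frame rate.  Each epoch carries
time ``t`` (seconds since recording start, shared origin across epochs),
horizontal position ``x`` (mm), vertical position ``z`` (mm, up positive) and
``pitch`` (degrees, nose-up positive).  Gaps — the fish leaving the field of
view, the feeding pause — are epoch boundaries; nothing is interpolated
across them.

Two interchangeable on-disk formats are supported:

* **CSV** — columns ``epoch_id,t,x,z,pitch`` with a YAML sidecar
  (``<file>.yaml``) holding the recording metadata.
* **HDF5** — ``/epochs/<id>/{t,x,z,pitch}`` datasets, metadata as root
  attributes, with an ``epoch_order`` attribute preserving time order.

Round-tripping either format reproduces the arrays bitwise.
"""

from __future__ import annotations

import dataclasses
import logging
from pathlib import Path
from typing import Sequence

import h5py
import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger(__name__)

DAY = "day"
NIGHT = "night"
TRANSITION = "transition"
CONDITIONS = ("DD", "LD", "LL")

SCHEMA_COLUMNS = ("epoch_id", "t", "x", "z", "pitch")

#: tolerance on sample-spacing uniformity, seconds
UNIFORMITY_TOL = 1e-6


class SchemaError(ValueError):
    """Raised when a track file does not conform to the documented schema."""


@dataclasses.dataclass
class RecordingMeta:
    """Recording-level metadata.

    Parameters
    ----------
    condition : {"DD", "LD", "LL"}
        Photoperiod treatment: constant dark, 14/10 light-dark cycle, or
        constant light.
    repeat_id, box_id : str
        Experimental repeat and apparatus identifiers.
    group_label : str
        Free-text group (e.g. ``wild-type``, ``lesion``, ``mutant``).
    lights_on_clock, lights_off_clock : float
        Zeitgeber schedule in decimal clock hours; defaults 9.0 and 23.0
        (lights on 9 a.m. to 11 p.m.).  Under DD/LL these still define the
        *circadian* day/night used for phase labels.
    frame_rate : float
        Acquisition rate, Hz.
    recording_start_clock : float
        Clock time (hours) at ``t = 0``.
    analysis_window : (float, float)
        Span in absolute hours since midnight of recording day 1; default
        ``(10.0, 58.0)`` — 48 h starting 10 a.m. on day 1.
    """

    condition: str = "DD"
    repeat_id: str = "r0"
    box_id: str = "box0"
    group_label: str = "wild-type"
    lights_on_clock: float = 9.0
    lights_off_clock: float = 23.0
    frame_rate: float = 166.0
    recording_start_clock: float = 10.0
    analysis_window: tuple[float, float] = (10.0, 58.0)

    def validate(self) -> "RecordingMeta":
        if self.condition not in CONDITIONS:
            raise SchemaError(f"condition must be one of {CONDITIONS}, got {self.condition!r}")
        if not 0.0 <= self.lights_on_clock < self.lights_off_clock <= 24.0:
            raise SchemaError(
                "require 0 <= lights_on_clock < lights_off_clock <= 24, got "
                f"({self.lights_on_clock}, {self.lights_off_clock})"
            )
        if self.frame_rate <= 0:
            raise SchemaError("frame_rate must be positive")
        return self

    # -- serialization (field names of the sidecar YAML dialect) ------------
    def to_dict(self) -> dict:
        return {
            "condition": self.condition,
            "repeat_id": self.repeat_id,
            "box_id": self.box_id,
            "group_label": self.group_label,
            "lights_on": float(self.lights_on_clock),
            "lights_off": float(self.lights_off_clock),
            "frame_rate": float(self.frame_rate),
            "recording_start_clock": float(self.recording_start_clock),
            "analysis_window": [float(self.analysis_window[0]), float(self.analysis_window[1])],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "RecordingMeta":
        try:
            return cls(
                condition=d["condition"],
                repeat_id=str(d["repeat_id"]),
                box_id=str(d.get("box_id", "box0")),
                group_label=str(d.get("group_label", "wild-type")),
                lights_on_clock=float(d["lights_on"]),
                lights_off_clock=float(d["lights_off"]),
                frame_rate=float(d["frame_rate"]),
                recording_start_clock=float(d["recording_start_clock"]),
                analysis_window=tuple(d.get("analysis_window", (10.0, 58.0))),
            ).validate()
        except KeyError as e:  # pragma: no cover - error path
            raise SchemaError(f"metadata missing required field {e.args[0]!r}") from e


@dataclasses.dataclass
class TrackSeries:
    """One continuous tracking epoch.

    ``clock_t`` (wrapping clock hours per sample) is derived from the
    metadata via :func:`attach_clock`; it is ``None`` for a bare series.
    """

    epoch_id: str
    t: np.ndarray
    x: np.ndarray
    z: np.ndarray
    pitch: np.ndarray
    frame_rate: float
    clock_t: np.ndarray | None = None

    @property
    def n(self) -> int:
        return len(self.t)

    def validate(self, tol: float = UNIFORMITY_TOL) -> "TrackSeries":
        """Check epoch invariants; raise :class:`SchemaError` on violation."""
        if self.frame_rate <= 0:
            raise SchemaError(f"epoch {self.epoch_id}: frame_rate must be > 0")
        if self.n < 2:
            raise SchemaError(f"epoch {self.epoch_id}: needs at least 2 samples")
        for name in ("t", "x", "z", "pitch"):
            arr = getattr(self, name)
            if len(arr) != self.n:
                raise SchemaError(f"epoch {self.epoch_id}: field {name} length mismatch")
            if not np.all(np.isfinite(arr)):
                raise SchemaError(f"epoch {self.epoch_id}: non-finite value in {name}")
        dt = np.diff(self.t)
        if np.any(np.abs(dt - 1.0 / self.frame_rate) > tol):
            raise SchemaError(
                f"epoch {self.epoch_id}: non-uniform sampling beyond {tol} s tolerance"
            )
        return self


@dataclasses.dataclass
class TrackFile:
    """Result of :func:`read_tracks`: valid epochs, metadata, and rejections.

    ``rejected`` lists ``(epoch_id, reason)`` for epochs that violated the
    schema; they are reported, never silently dropped.
    """

    tracks: list[TrackSeries]
    meta: RecordingMeta
    rejected: list[tuple[str, str]] = dataclasses.field(default_factory=list)


def attach_clock(track: TrackSeries, meta: RecordingMeta) -> TrackSeries:
    """Fill ``clock_t`` (wrapping clock hours) from the recording metadata."""
    track.clock_t = (meta.recording_start_clock + track.t / 3600.0) % 24.0
    return track


def abs_hours(t_seconds, meta: RecordingMeta):
    """Absolute (non-wrapping) hours since midnight of recording day 1."""
    return meta.recording_start_clock + np.asarray(t_seconds, dtype=float) / 3600.0


def _in_wrapped_interval(ct: np.ndarray, lo: float, hi: float) -> np.ndarray:
    """Membership in [lo, hi) on the 24 h circle."""
    lo, hi = lo % 24.0, hi % 24.0
    if lo < hi:
        return (ct >= lo) & (ct < hi)
    return (ct >= lo) | (ct < hi)  # interval wraps midnight


def assign_phase(clock_t, meta: RecordingMeta):
    """Label clock times as ``day``, ``night`` or ``transition``.

    The transition covers the hour before and after each day-night boundary
    (with the default schedule: 8–10 h and 22–24 h); transition overrides
    day/night.  Day is ``[lights_on, lights_off)``; everything else is night.
    Under DD and LL the same labels apply to zeitgeber time (circadian
    day/night).

    Accepts a scalar or array in ``[0, 24)``; returns a matching str or array.
    """
    scalar = np.isscalar(clock_t)
    ct = np.atleast_1d(np.asarray(clock_t, dtype=float))
    if np.any((ct < 0.0) | (ct >= 24.0)):
        raise ValueError("clock_t must lie in [0, 24)")
    on, off = meta.lights_on_clock, meta.lights_off_clock
    trans = _in_wrapped_interval(ct, on - 1.0, on + 1.0) | _in_wrapped_interval(
        ct, off - 1.0, off + 1.0
    )
    day = (ct >= on) & (ct < off)
    out = np.where(trans, TRANSITION, np.where(day, DAY, NIGHT))
    return str(out[0]) if scalar else out


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def _infer_format(path: Path, format: str | None) -> str:
    if format is not None:
        if format not in ("csv", "hdf5"):
            raise ValueError(f"unknown format {format!r}; expected 'csv' or 'hdf5'")
        return format
    if path.suffix in (".h5", ".hdf5"):
        return "hdf5"
    return "csv"


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".yaml")


def write_tracks(
    tracks: Sequence[TrackSeries],
    meta: RecordingMeta,
    path: str | Path,
    format: str | None = None,
) -> Path:
    """Write epochs + metadata to ``path`` in CSV or HDF5 form.

    Epochs are written in time order.  ``read_tracks(write_tracks(X))``
    reproduces the arrays exactly.  An empty epoch collection yields a valid
    file with zero epochs.
    """
    path = Path(path)
    fmt = _infer_format(path, format)
    meta.validate()
    for tr in tracks:
        tr.validate()
    ordered = sorted(tracks, key=lambda tr: tr.t[0] if tr.n else 0.0)

    if fmt == "csv":
        frames = [
            pd.DataFrame(
                {"epoch_id": tr.epoch_id, "t": tr.t, "x": tr.x, "z": tr.z, "pitch": tr.pitch}
            )
            for tr in ordered
        ]
        df = (
            pd.concat(frames, ignore_index=True)
            if frames
            else pd.DataFrame(columns=list(SCHEMA_COLUMNS))
        )
        df.to_csv(path, index=False, float_format="%.17g")  # exact float64 round trip
        with open(_sidecar_path(path), "w") as fh:
            yaml.safe_dump(meta.to_dict(), fh, sort_keys=False)
    else:
        with h5py.File(path, "w") as f:
            grp = f.create_group("epochs")
            for tr in ordered:
                g = grp.create_group(str(tr.epoch_id))
                for name in ("t", "x", "z", "pitch"):
                    g.create_dataset(name, data=np.asarray(getattr(tr, name), dtype=np.float64))
            f.attrs["epoch_order"] = [str(tr.epoch_id) for tr in ordered]
            for k, v in meta.to_dict().items():
                f.attrs[k] = v
    return path


def read_tracks(path: str | Path, format: str | None = None) -> TrackFile:
    """Read a track file; validate each epoch against the schema.

    Epochs violating an invariant (NaNs, non-uniform sampling, < 2 samples)
    are rejected individually with a logged reason and listed in
    ``TrackFile.rejected``.  A malformed header raises :class:`SchemaError`
    naming the offending field.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = _infer_format(path, format)

    if fmt == "csv":
        sidecar = _sidecar_path(path)
        if not sidecar.exists():
            raise SchemaError(f"missing metadata sidecar {sidecar}")
        with open(sidecar) as fh:
            meta = RecordingMeta.from_dict(yaml.safe_load(fh))
        df = pd.read_csv(path, float_precision="round_trip")
        missing = [c for c in SCHEMA_COLUMNS if c not in df.columns]
        if missing:
            raise SchemaError(f"track CSV missing column(s): {', '.join(missing)}")
        raw: list[TrackSeries] = []
        for eid, sub in df.groupby("epoch_id", sort=False):
            raw.append(
                TrackSeries(
                    epoch_id=str(eid),
                    t=sub["t"].to_numpy(dtype=np.float64),
                    x=sub["x"].to_numpy(dtype=np.float64),
                    z=sub["z"].to_numpy(dtype=np.float64),
                    pitch=sub["pitch"].to_numpy(dtype=np.float64),
                    frame_rate=meta.frame_rate,
                )
            )
    else:
        with h5py.File(path, "r") as f:
            meta = RecordingMeta.from_dict({k: f.attrs[k] for k in f.attrs if k != "epoch_order"})
            order = [
                s.decode() if isinstance(s, bytes) else str(s) for s in f.attrs["epoch_order"]
            ]
            raw = []
            for eid in order:
                g = f["epochs"][eid]
                raw.append(
                    TrackSeries(
                        epoch_id=eid,
                        t=g["t"][...],
                        x=g["x"][...],
                        z=g["z"][...],
                        pitch=g["pitch"][...],
                        frame_rate=meta.frame_rate,
                    )
                )

    tracks: list[TrackSeries] = []
    rejected: list[tuple[str, str]] = []
    for tr in raw:
        try:
            tr.validate()
        except SchemaError as e:
            logger.warning("rejected epoch %s: %s", tr.epoch_id, e)
            rejected.append((tr.epoch_id, str(e)))
            continue
        tracks.append(attach_clock(tr, meta))
    tracks.sort(key=lambda tr: tr.t[0])
    return TrackFile(tracks=tracks, meta=meta, rejected=rejected)
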