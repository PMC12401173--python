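"""Data model and text I/O for event-annotated fluorescence traces and sperm tracks.

Traces are stored as two-column tab-separated text (``time_s``,
``fluorescence_au``) with a YAML sidecar (``<file>.meta.yaml``) carrying the
sampling rate, units and the ordered reagent-addition events. Tracks are
stored as four-column tab-separated text (``track_id``, ``frame``, ``x_um``,
``y_um``) with the frame rate in the sidecar. Both round-trip at full float
precision; instruments in this domain export tabular text, so no binary
format is supported.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .errors import (
    DuplicateFrameError,
    EventRangeError,
    NonMonotonicTimeError,
    TraceFormatError,
)

EVENT_LABELS = ("valinomycin", "kcl", "p4", "ionomycin", "mncl2", "other")

#: relative tolerance on sample-spacing uniformity
_DT_RTOL = 1e-6


@dataclass(frozen=True)
class TraceEvent:
    """A time-stamped reagent addition.

    ``payload`` carries event parameters; a ``kcl`` event must carry
    ``k_final_mM``, the final bath K⁺ concentration after the addition.
    """

    time: float
    label: str
    payload: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.label not in EVENT_LABELS:
            raise TraceFormatError(
                f"unknown event label {self.label!r}; expected one of {EVENT_LABELS}"
            )
        if self.label == "kcl":
            k = self.payload.get("k_final_mM")
            if k is None or not np.isfinite(k) or k <= 0:
                raise TraceFormatError(
                    "kcl event requires a positive k_final_mM payload"
                )


@dataclass(frozen=True)
class FluorescenceTrace:
    """A uniformly sampled population-fluorescence time series with events.

    Parameters
    ----------
    time
        Sample times in seconds, strictly increasing, uniformly spaced.
    fluorescence
        Fluorescence in arbitrary units (a.u.), finite, same length as ``time``.
    events
        Ordered reagent-addition events; every event time must lie within
        ``[time[0], time[-1]]``.
    units
        Fluorescence unit string, kept through serialization.
    """

    time: np.ndarray
    fluorescence: np.ndarray
    events: tuple[TraceEvent, ...] = ()
    units: str = "a.u."

    def __post_init__(self) -> None:
        t = np.asarray(self.time, dtype=float)
        f = np.asarray(self.fluorescence, dtype=float)
        object.__setattr__(self, "time", t)
        object.__setattr__(self, "fluorescence", f)
        object.__setattr__(self, "events", tuple(self.events))
        if t.ndim != 1 or f.ndim != 1 or t.size != f.size:
            raise TraceFormatError("time and fluorescence must be equal-length 1-D")
        if t.size < 2:
            raise TraceFormatError("a trace needs at least 2 samples")
        dt = np.diff(t)
        if np.any(dt <= 0):
            raise NonMonotonicTimeError("time stamps must be strictly increasing")
        if not np.allclose(dt, dt[0], rtol=_DT_RTOL, atol=_DT_RTOL * abs(dt[0])):
            raise NonMonotonicTimeError("time stamps must be uniformly spaced")
        if not np.all(np.isfinite(f)):
            raise TraceFormatError("fluorescence values must be finite")
        times = [e.time for e in self.events]
        if any(b < a for a, b in zip(times, times[1:])):
            raise TraceFormatError("events must be time-ordered")
        for e in self.events:
            if not (t[0] <= e.time <= t[-1]):
                raise EventRangeError(
                    f"event {e.label!r} at t={e.time} s outside sampled range "
                    f"[{t[0]}, {t[-1]}] s"
                )

    @property
    def dt(self) -> float:
        return float(self.time[1] - self.time[0])

    @property
    def sampling_rate(self) -> float:
        return 1.0 / self.dt

    @property
    def duration(self) -> float:
        return float(self.time[-1] - self.time[0])

    def events_labeled(self, label: str) -> tuple[TraceEvent, ...]:
        return tuple(e for e in self.events if e.label == label)

    def first_event(self, label: str) -> TraceEvent | None:
        ev = self.events_labeled(label)
        return ev[0] if ev else None

    def with_fluorescence(self, f: np.ndarray) -> "FluorescenceTrace":
        return replace(self, fluorescence=np.asarray(f, dtype=float))

    def segment_mask(self, t0: float, t1: float) -> np.ndarray:
        """Boolean mask for samples with ``t0 <= t <= t1``."""
        return (self.time >= t0) & (self.time <= t1)


@dataclass(frozen=True)
class SpermTrack:
    """One tracked cell: per-frame positions in instrument-frame micrometres."""

    track_id: str
    frame_rate: float
    positions: np.ndarray  # shape (n_frames, 2), μm
    start_frame: int = 0

    def __post_init__(self) -> None:
        p = np.asarray(self.positions, dtype=float)
        object.__setattr__(self, "positions", p)
        if self.frame_rate <= 0:
            raise TraceFormatError("frame_rate must be positive")
        if p.ndim != 2 or p.shape[1] != 2 or p.shape[0] < 2:
            raise TraceFormatError("positions must be (n>=2, 2)")
        if not np.all(np.isfinite(p)):
            raise TraceFormatError("positions must be finite")

    @property
    def n_frames(self) -> int:
        return int(self.positions.shape[0])

    @property
    def duration(self) -> float:
        """Track duration in seconds (inter-frame intervals spanned)."""
        return (self.n_frames - 1) / self.frame_rate


# ---------------------------------------------------------------------------
# trace serialization


def _sidecar(path: Path) -> Path:
    return Path(str(path) + ".meta.yaml")


def write_trace(trace: FluorescenceTrace, path: str | Path) -> None:
    """Write a trace and its sidecar; ``read_trace`` inverts it exactly."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    data = np.column_stack([trace.time, trace.fluorescence])
    np.savetxt(
        path, data, fmt="%.17g", delimiter="\t", header="time_s\tfluorescence_au",
        comments="",
    )
    meta = {
        "units": trace.units,
        "sampling_rate_hz": trace.sampling_rate,
        "events": [
            {"time_s": float(e.time), "label": e.label,
             **{k: float(v) for k, v in e.payload.items()}}
            for e in trace.events
        ],
    }
    _sidecar(path).write_text(yaml.safe_dump(meta, sort_keys=False))


def read_trace(path: str | Path) -> FluorescenceTrace:
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    except Exception as exc:  # noqa: BLE001 - wrap any parse failure
        raise TraceFormatError(f"cannot parse trace file {path}: {exc}") from exc
    if list(df.columns) != ["time_s", "fluorescence_au"]:
        raise TraceFormatError(
            f"malformed header in {path}: expected time_s, fluorescence_au, "
            f"got {list(df.columns)}"
        )
    sidecar = _sidecar(path)
    if not sidecar.exists():
        raise TraceFormatError(f"missing sidecar metadata {sidecar}")
    meta = yaml.safe_load(sidecar.read_text()) or {}
    events = []
    for ev in meta.get("events", []):
        ev = dict(ev)
        t = ev.pop("time_s")
        label = ev.pop("label")
        events.append(TraceEvent(time=float(t), label=label, payload=ev))
    return FluorescenceTrace(
        time=df["time_s"].to_numpy(),
        fluorescence=df["fluorescence_au"].to_numpy(),
        events=tuple(events),
        units=meta.get("units", "a.u."),
    )


# ---------------------------------------------------------------------------
# track serialization


def write_tracks(tracks: Iterable[SpermTrack], path: str | Path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    tracks = list(tracks)
    if not tracks:
        raise TraceFormatError("no tracks to write")
    rates = {t.frame_rate for t in tracks}
    if len(rates) != 1:
        raise TraceFormatError("all tracks in one file must share a frame rate")
    rows = []
    for tr in tracks:
        frames = np.arange(tr.start_frame, tr.start_frame + tr.n_frames)
        rows.append(
            pd.DataFrame(
                {
                    "track_id": tr.track_id,
                    "frame": frames,
                    "x_um": tr.positions[:, 0],
                    "y_um": tr.positions[:, 1],
                }
            )
        )
    pd.concat(rows).to_csv(path, sep="\t", index=False, float_format="%.17g")
    _sidecar(path).write_text(
        yaml.safe_dump({"frame_rate_hz": float(rates.pop())}, sort_keys=False)
    )


def read_tracks(path: str | Path) -> list[SpermTrack]:
    """Read a track table; tracks with interior frame gaps are split.

    A gap (missing interior frame) splits the track into separate tracks with
    ids suffixed ``#1``, ``#2``, ...; interpolating across gaps would inflate
    straight-line velocity, so splitting is the conservative choice.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    except Exception as exc:  # noqa: BLE001
        raise TraceFormatError(f"cannot parse track file {path}: {exc}") from exc
    required = {"track_id", "frame", "x_um", "y_um"}
    if not required.issubset(df.columns):
        raise TraceFormatError(
            f"track file {path} missing columns {sorted(required - set(df.columns))}"
        )
    sidecar = _sidecar(path)
    if not sidecar.exists():
        raise TraceFormatError(f"missing sidecar metadata {sidecar}")
    meta = yaml.safe_load(sidecar.read_text()) or {}
    frame_rate = float(meta.get("frame_rate_hz", 0))
    if frame_rate <= 0:
        raise TraceFormatError("frame_rate_hz must be positive in sidecar")
    if df.duplicated(subset=["track_id", "frame"]).any():
        dup = df[df.duplicated(subset=["track_id", "frame"])].iloc[0]
        raise DuplicateFrameError(
            f"duplicate (track_id, frame) = ({dup['track_id']}, {dup['frame']})"
        )
    out: list[SpermTrack] = []
    for tid, g in df.groupby("track_id", sort=True):
        g = g.sort_values("frame")
        frames = g["frame"].to_numpy(dtype=int)
        pos = g[["x_um", "y_um"]].to_numpy(dtype=float)
        breaks = np.where(np.diff(frames) != 1)[0]
        segments = np.split(np.arange(frames.size), breaks + 1)
        for k, idx in enumerate(segments):
            if idx.size < 2:
                continue  # an isolated frame carries no kinematic information
            sid = str(tid) if len(segments) == 1 else f"{tid}#{k + 1}"
            out.append(
                SpermTrack(
                    track_id=sid,
                    frame_rate=frame_rate,
                    positions=pos[idx],
                    start_frame=int(frames[idx[0]]),
                )
            )
    return out
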