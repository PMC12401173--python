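"""CASA-style kinematics and motility classification.

Per-track velocities:

* VCL (curvilinear velocity) — total point-to-point path length / duration.
* VSL (straight-line velocity) — net first-to-last displacement / duration.
* VAP (average-path velocity) — path length of the 5-point moving-average
  smoothed trajectory / duration. The trajectory is padded by linear
  extrapolation before smoothing so a uniform straight swim has VAP = VCL
  exactly; for curved paths smoothing shortens the path, giving
  VSL ≤ VAP ≤ VCL up to a small boundary tolerance.
* STR (straightness) — 100·VSL/VAP, capped to [0, 100]; 0 when VAP = 0.

Velocity classes follow the VCL cut-offs <10 (slow), 10–35 (medium),
>35 µm·s⁻¹ (fast); the conventional ranges touch at their endpoints, so the
partition is made exact with half-open intervals ([10, 35) medium, ≥35 fast).

Motility classes: progressive (STR > 80, strict), immotile, non-progressive
otherwise. Taken literally, "immotile = STR exactly 0" would label a jittering
dead cell motile (positional noise gives STR > 0), so the default ``floor``
mode also calls a track immotile when its VCL is below a floor (default
10 µm·s⁻¹, the slow cut-off). ``strict`` mode applies the literal STR = 0 rule.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Literal, Sequence

import numpy as np

from .errors import TrackTooShortError
from .trace_io import SpermTrack

VelocityClass = Literal["slow", "medium", "fast"]
MotilityClass = Literal["progressive", "non_progressive", "immotile"]


@dataclass(frozen=True)
class CasaConfig:
    """Thresholds of the kinematic analysis (all velocities in µm·s⁻¹)."""

    slow_max: float = 10.0  # VCL below this: slow
    medium_max: float = 35.0  # VCL in [slow_max, medium_max): medium; above: fast
    progressive_str: float = 80.0  # STR strictly above this: progressive
    immotile_vcl_floor: float = 10.0  # floor mode: VCL below this: immotile
    vap_window: int = 5  # moving-average window (frames)
    immotile_mode: Literal["floor", "strict"] = "floor"


@dataclass(frozen=True)
class KinematicSummary:
    track_id: str
    vcl: float
    vsl: float
    vap: float
    str_pct: float
    velocity_class: VelocityClass
    motility_class: MotilityClass


@dataclass(frozen=True)
class MotilityProfile:
    """Per-sample motility percentages (they sum to 100 over analyzed tracks)."""

    n_tracks: int
    pct_progressive: float
    pct_non_progressive: float
    pct_immotile: float
    n_unanalyzed: int = 0  # tracks shorter than the smoothing window, disclosed


def _path_length(p: np.ndarray) -> float:
    return float(np.sum(np.linalg.norm(np.diff(p, axis=0), axis=1)))


def _smooth_path(p: np.ndarray, window: int) -> np.ndarray:
    """Moving average with linear-extrapolation padding (collinear-exact)."""
    k = window // 2
    first = p[0] + np.arange(-k, 0)[:, None] * (p[1] - p[0])
    last = p[-1] + np.arange(1, k + 1)[:, None] * (p[-1] - p[-2])
    padded = np.vstack([first, p, last])
    kernel = np.ones(window) / window
    out = np.column_stack(
        [np.convolve(padded[:, j], kernel, mode="valid") for j in range(2)]
    )
    return out


def compute_kinematics(
    track: SpermTrack, config: CasaConfig = CasaConfig()
) -> KinematicSummary:
    """Kinematic summary of one track.

    Requires at least ``vap_window`` frames. Translation/rotation invariant;
    velocities scale inversely with time rescaling.
    """
    if track.n_frames < config.vap_window:
        raise TrackTooShortError(
            f"track {track.track_id}: {track.n_frames} frames < "
            f"VAP window {config.vap_window}"
        )
    duration = track.duration
    p = track.positions
    vcl = _path_length(p) / duration
    vsl = float(np.linalg.norm(p[-1] - p[0])) / duration
    vap = _path_length(_smooth_path(p, config.vap_window)) / duration
    str_pct = 0.0 if vap == 0 else min(100.0, max(0.0, 100.0 * vsl / vap))
    if vcl < config.slow_max:
        vclass: VelocityClass = "slow"
    elif vcl < config.medium_max:
        vclass = "medium"
    else:
        vclass = "fast"
    summary = KinematicSummary(
        track_id=track.track_id, vcl=vcl, vsl=vsl, vap=vap, str_pct=str_pct,
        velocity_class=vclass, motility_class="immotile",
    )
    return KinematicSummary(
        **{**summary.__dict__, "motility_class": classify_track(summary, config)}
    )


def classify_track(
    summary: KinematicSummary, config: CasaConfig = CasaConfig()
) -> MotilityClass:
    """Motility class of one track (see module docstring for the modes).

    STR exactly at the progressive threshold is non-progressive: the
    inequality is strict.
    """
    if config.immotile_mode == "floor":
        if summary.vcl < config.immotile_vcl_floor or summary.str_pct == 0:
            return "immotile"
        if summary.str_pct > config.progressive_str:
            return "progressive"
        return "non_progressive"
    # strict-literal mode
    if summary.str_pct == 0:
        return "immotile"
    if summary.str_pct > config.progressive_str:
        return "progressive"
    return "non_progressive"


def summarize_motility(
    summaries: Sequence[KinematicSummary], n_unanalyzed: int = 0
) -> MotilityProfile:
    """Class percentages over analyzed tracks (must be non-empty)."""
    if not summaries:
        raise ValueError("no kinematic summaries to profile")
    n = len(summaries)
    counts = {"progressive": 0, "non_progressive": 0, "immotile": 0}
    for s in summaries:
        counts[s.motility_class] += 1
    return MotilityProfile(
        n_tracks=n,
        pct_progressive=100.0 * counts["progressive"] / n,
        pct_non_progressive=100.0 * counts["non_progressive"] / n,
        pct_immotile=100.0 * counts["immotile"] / n,
        n_unanalyzed=n_unanalyzed,
    )


def analyze_tracks(
    tracks: Iterable[SpermTrack], config: CasaConfig = CasaConfig()
) -> tuple[list[KinematicSummary], MotilityProfile]:
    """Per-track kinematics plus the sample profile.

    Tracks shorter than the smoothing window are counted as unanalyzed in the
    profile metadata, never silently dropped.
    """
    summaries: list[KinematicSummary] = []
    n_short = 0
    for tr in tracks:
        try:
            summaries.append(compute_kinematics(tr, config))
        except TrackTooShortError:
            n_short += 1
    return summaries, summarize_motility(summaries, n_unanalyzed=n_short)
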