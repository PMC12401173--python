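"""Synthetic study data with known ground truth.

Everything the analysis consumes can be generated here: stepped K⁺
calibration traces, single-transient progesterone responses with
ionomycin/Mn²⁺ anchoring, persistent-random-walk sperm tracks in the three
velocity classes, and paired per-subject cohorts with method-level median
shifts. All generators are deterministic under a fixed seed.

Model choices (documented in docs/methods.md):

* Dye polarity — fluorescence is an *increasing* linear function of Em
  (depolarization raises the signal), matching the upward steps after each
  KCl addition; the slope is a truth field, and the estimator never assumes
  its sign.
* Plateau settling — single exponential, time constant ``settle_samples``
  sampling intervals (default 3).
* P4 transient — raised-cosine rise reaching the peak at twice the rise
  half-time, then exponential recovery toward baseline with half-life
  ``tau_down``. Parameterized directly by half-times, so the downstream
  crossing-time estimators recover the truth exactly on noiseless traces.
* Cohorts — log-normal shifted to the target median with dispersion set via
  the (unscaled) MAD; respects positivity of counts and amplitudes.
  Negative-median variables (membrane potentials) are generated as the
  negated positive-median family.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import optimize, stats

from .em_calibration import NernstParams, nernst_em
from .errors import SpecValidationError
from .outcome_stats import PairedCohort
from .trace_io import FluorescenceTrace, SpermTrack, TraceEvent

MOTILITY_CLASSES = ("progressive", "non_progressive", "immotile")


# ---------------------------------------------------------------------------
# specs and truths


@dataclass(frozen=True)
class TraceSpec:
    """Acquisition parameters shared by the trace generators."""

    baseline_fluorescence: float  # a.u.
    noise_sd: float  # a.u., Gaussian, pointwise
    sampling_rate: float  # Hz
    duration: float  # s
    event_schedule: tuple[TraceEvent, ...] = ()
    settle_samples: int = 3  # exponential settling time, in sampling intervals

    def __post_init__(self) -> None:
        if self.sampling_rate <= 0 or self.duration <= 0:
            raise SpecValidationError("sampling_rate and duration must be positive")
        if self.noise_sd < 0:
            raise SpecValidationError("noise_sd must be >= 0")
        times = [e.time for e in self.event_schedule]
        if any(b <= a for a, b in zip(times, times[1:])):
            raise SpecValidationError("event times must be strictly increasing")
        if any(not (0 < t < self.duration) for t in times):
            raise SpecValidationError("event times must lie inside (0, duration)")


@dataclass(frozen=True)
class CalTraceTruth:
    """Ground truth of a K⁺-step calibration trace."""

    resting_em: float  # mV
    fluorescence_per_mv: float  # a.u.·mV⁻¹, slope of the true linear map
    intracellular_k: float = 120.0  # mM
    baseline_k: float = 5.0  # mM, the recording medium's K⁺
    kcl_steps: tuple[float, ...] = (7.5, 12.5, 22.5, 42.5)  # final mM
    temperature: float = 310.15  # K

    def __post_init__(self) -> None:
        if self.intracellular_k <= 0:
            raise SpecValidationError("intracellular_k must be positive")
        steps = tuple(self.kcl_steps)
        object.__setattr__(self, "kcl_steps", steps)
        if any(b <= a for a, b in zip(steps, steps[1:])):
            raise SpecValidationError("kcl_steps must be strictly increasing")
        if any(s <= self.baseline_k for s in steps):
            raise SpecValidationError("every kcl step must exceed baseline_k")

    @property
    def nernst_params(self) -> NernstParams:
        return NernstParams(
            temperature=self.temperature, intracellular_k=self.intracellular_k
        )


@dataclass(frozen=True)
class P4TraceTruth:
    """Ground truth of a progesterone-transient trace."""

    delta_p4: float  # dimensionless fold increment over basal
    tau_up: float  # s
    tau_down: float  # s
    iono_level: float  # a.u.
    mn_level: float  # a.u.
    p4_time: float  # s
    iono_time: float  # s
    mn_time: float  # s

    def __post_init__(self) -> None:
        if self.delta_p4 < 0:
            raise SpecValidationError("delta_p4 must be >= 0")
        if self.tau_up <= 0 or self.tau_down <= 0:
            raise SpecValidationError("half-times must be positive")
        if not (self.p4_time < self.iono_time < self.mn_time):
            raise SpecValidationError("need p4_time < iono_time < mn_time")


@dataclass(frozen=True)
class TrackSpec:
    """Persistent-random-walk track generator parameters."""

    n_tracks: int = 300
    class_mix: Mapping[str, float] = field(
        default_factory=lambda: {
            "progressive": 0.79, "non_progressive": 0.13, "immotile": 0.08
        }
    )
    speed_ranges: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: {
            "progressive": (40.0, 80.0),
            "non_progressive": (15.0, 35.0),
            "immotile": (0.0, 0.0),
        }
    )
    turning_noise: Mapping[str, float] = field(
        default_factory=lambda: {
            "progressive": 0.05, "non_progressive": 1.5, "immotile": 0.0
        }
    )
    frame_rate: float = 50.0  # Hz
    duration: float = 3.0  # s
    position_noise_sd: float = 0.1  # µm per frame, sub-pixel jitter

    def __post_init__(self) -> None:
        if self.n_tracks < 1:
            raise SpecValidationError("n_tracks must be >= 1")
        if self.frame_rate <= 0 or self.duration <= 0:
            raise SpecValidationError("frame_rate and duration must be positive")
        if self.position_noise_sd < 0:
            raise SpecValidationError("position_noise_sd must be >= 0")
        mix = dict(self.class_mix)
        if set(mix) - set(MOTILITY_CLASSES):
            raise SpecValidationError(f"classes must be among {MOTILITY_CLASSES}")
        if abs(sum(mix.values()) - 1.0) > 1e-9 or any(v < 0 for v in mix.values()):
            raise SpecValidationError("class_mix must be non-negative and sum to 1")
        for cls, (lo, hi) in dict(self.speed_ranges).items():
            if lo < 0 or hi < lo:
                raise SpecValidationError(f"bad speed range for {cls}: ({lo}, {hi})")

    @property
    def n_frames(self) -> int:
        return int(round(self.duration * self.frame_rate)) + 1


@dataclass(frozen=True)
class CohortSpec:
    """Paired-cohort generator parameters for one variable."""

    n_subjects: int
    sample_class: str  # Nz | Tz
    variable: str
    units: str
    dgc_median: float
    dgc_mad: float
    ca0_median: float
    ca0_mad: float
    correlation: float = 0.5  # between paired arms, on the latent normal scale
    seed: int = 0
    group: str = "other"
    calibrate_median: bool = False  # shift arms so sample medians hit targets exactly

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise SpecValidationError("n_subjects must be >= 1")
        if self.dgc_mad < 0 or self.ca0_mad < 0:
            raise SpecValidationError("dispersions must be >= 0")
        if not (0.0 <= self.correlation <= 1.0):
            raise SpecValidationError("correlation must be in [0, 1]")
        if self.dgc_median == 0 or self.ca0_median == 0:
            raise SpecValidationError("medians must be non-zero")


# ---------------------------------------------------------------------------
# trace generation


def _time_grid(spec: TraceSpec) -> np.ndarray:
    n = int(round(spec.duration * spec.sampling_rate)) + 1
    return np.arange(n) / spec.sampling_rate


def _snap(t: float, rate: float) -> float:
    """Snap an event time onto the sample grid (invariant of the format)."""
    return round(t * rate) / rate


def _piecewise_settle(
    t: np.ndarray, segments: Sequence[tuple[float, float]], f0: float, tau: float
) -> np.ndarray:
    """Exponential approach to a stepwise target level.

    ``segments`` is ``[(start_time, target_level), ...]``; before the first
    start the level is ``f0`` exactly.
    """
    f = np.full_like(t, f0)
    current = f0
    for i, (t_ev, level) in enumerate(segments):
        t_next = segments[i + 1][0] if i + 1 < len(segments) else np.inf
        mask = (t >= t_ev) & (t < t_next)
        if tau > 0:
            f[mask] = level + (current - level) * np.exp(-(t[mask] - t_ev) / tau)
        else:
            f[mask] = level
        dt_seg = (min(t_next, t[-1]) - t_ev)
        current = level + (current - level) * (math.exp(-dt_seg / tau) if tau > 0 else 0.0)
    return f


def calibration_trace_spec(
    truth: CalTraceTruth,
    baseline_fluorescence: float = 100.0,
    noise_sd: float = 0.0,
    sampling_rate: float = 5.0,
    baseline_duration: float = 30.0,
    step_interval: float = 20.0,
    settle_samples: int = 3,
) -> TraceSpec:
    """A TraceSpec with the standard calibration schedule for ``truth``.

    Valinomycin after ``baseline_duration`` seconds, then one KCl addition per
    step every ``step_interval`` seconds, with ``step_interval`` of trailing
    plateau after the last step.
    """
    events = [TraceEvent(time=_snap(baseline_duration, sampling_rate),
                         label="valinomycin")]
    t = baseline_duration
    for step in truth.kcl_steps:
        t += step_interval
        events.append(
            TraceEvent(time=_snap(t, sampling_rate), label="kcl",
                       payload={"k_final_mM": float(step)})
        )
    return TraceSpec(
        baseline_fluorescence=baseline_fluorescence,
        noise_sd=noise_sd,
        sampling_rate=sampling_rate,
        duration=t + step_interval,
        event_schedule=tuple(events),
        settle_samples=settle_samples,
    )


def make_calibration_trace(
    truth: CalTraceTruth, spec: TraceSpec, seed: int | None = None
) -> FluorescenceTrace:
    """Generate a DiSC₃(5)-style K⁺-step calibration trace.

    Before valinomycin the trace fluctuates about the baseline fluorescence,
    which corresponds to ``truth.resting_em`` under the true linear map; after
    valinomycin the potential is clamped to the Nernst potential of the
    medium's K⁺ and after each KCl addition to that step's Nernst potential,
    with exponential settling.
    """
    events = tuple(
        TraceEvent(time=_snap(e.time, spec.sampling_rate), label=e.label,
                   payload=e.payload)
        for e in spec.event_schedule
    )
    val = [e for e in events if e.label == "valinomycin"]
    kcl = [e for e in events if e.label == "kcl"]
    if len(val) != 1 or len(kcl) != len(truth.kcl_steps):
        raise SpecValidationError(
            "schedule must contain one valinomycin event and one kcl event "
            "per entry of kcl_steps"
        )
    if any(e.time <= val[0].time for e in kcl):
        raise SpecValidationError("kcl events must follow valinomycin")
    boundaries = [e.time for e in events] + [spec.duration]
    min_gap = min(b - a for a, b in zip(boundaries, boundaries[1:]))
    if min_gap * spec.sampling_rate < 5:
        raise SpecValidationError(
            "event schedule leaves < 5 samples in some plateau segment"
        )

    params = truth.nernst_params
    slope = truth.fluorescence_per_mv
    intercept = spec.baseline_fluorescence - slope * truth.resting_em
    segments = [(val[0].time, intercept + slope * float(nernst_em(truth.baseline_k, params)))]
    for e, step in zip(kcl, truth.kcl_steps):
        segments.append((e.time, intercept + slope * float(nernst_em(step, params))))

    t = _time_grid(spec)
    tau = spec.settle_samples / spec.sampling_rate
    f = _piecewise_settle(t, segments, spec.baseline_fluorescence, tau)
    if spec.noise_sd > 0:
        rng = np.random.default_rng(seed)
        f = f + rng.normal(0.0, spec.noise_sd, size=t.size)
    return FluorescenceTrace(time=t, fluorescence=f, events=events)


def p4_trace_spec(
    truth: P4TraceTruth,
    baseline_fluorescence: float = 100.0,
    noise_sd: float = 0.0,
    sampling_rate: float = 10.0,
    tail: float = 5.0,
    settle_samples: int = 3,
) -> TraceSpec:
    """A TraceSpec whose schedule mirrors the truth's event times."""
    rate = sampling_rate
    events = (
        TraceEvent(time=_snap(truth.p4_time, rate), label="p4"),
        TraceEvent(time=_snap(truth.iono_time, rate), label="ionomycin"),
        TraceEvent(time=_snap(truth.mn_time, rate), label="mncl2"),
    )
    return TraceSpec(
        baseline_fluorescence=baseline_fluorescence,
        noise_sd=noise_sd,
        sampling_rate=rate,
        duration=truth.mn_time + tail,
        event_schedule=events,
        settle_samples=settle_samples,
    )


def make_p4_trace(
    truth: P4TraceTruth, spec: TraceSpec, seed: int | None = None
) -> FluorescenceTrace:
    """Generate a Fluo-3-style progesterone-transient trace.

    The transient rises from baseline with a raised-cosine ramp whose
    half-amplitude crossing is ``tau_up`` after the P4 addition (peak at
    2·``tau_up``), then recovers toward baseline exponentially with half-life
    ``tau_down``. Ionomycin steps the trace to ``iono_level`` and MnCl₂
    quenches it to ``mn_level``; on the Mn-zeroed scale the peak's normalized
    amplitude equals ``delta_p4``.
    """
    rate = spec.sampling_rate
    dt = 1.0 / rate
    if truth.tau_up < 2 * dt or truth.tau_down < 2 * dt:
        raise SpecValidationError(
            "half-times shorter than 2 sampling intervals are not resolvable"
        )
    if truth.mn_level >= spec.baseline_fluorescence:
        raise SpecValidationError(
            "mn_level must lie below the baseline (quench invariant)"
        )
    t_p4 = _snap(truth.p4_time, rate)
    t_iono = _snap(truth.iono_time, rate)
    t_mn = _snap(truth.mn_time, rate)
    t_peak = t_p4 + 2 * truth.tau_up
    if t_peak >= t_iono:
        raise SpecValidationError("peak (p4_time + 2·tau_up) must precede ionomycin")

    f0 = spec.baseline_fluorescence
    amplitude = truth.delta_p4 * (f0 - truth.mn_level)

    t = _time_grid(spec)
    f = np.full_like(t, f0)
    rise = (t >= t_p4) & (t < t_peak)
    f[rise] = f0 + amplitude * 0.5 * (1 - np.cos(np.pi * (t[rise] - t_p4) / (2 * truth.tau_up)))
    decay = (t >= t_peak) & (t < t_iono)
    f[decay] = f0 + amplitude * np.exp2(-(t[decay] - t_peak) / truth.tau_down)

    # ionomycin and Mn²⁺ steps, with the same exponential settling as plateaus
    tau = spec.settle_samples / rate
    f_at_iono = f0 + (amplitude * math.exp2(-(t_iono - t_peak) / truth.tau_down)
                      if amplitude > 0 else 0.0)
    post = _piecewise_settle(
        t, [(t_iono, truth.iono_level), (t_mn, truth.mn_level)], f_at_iono, tau
    )
    f[t >= t_iono] = post[t >= t_iono]

    if spec.noise_sd > 0:
        rng = np.random.default_rng(seed)
        f = f + rng.normal(0.0, spec.noise_sd, size=t.size)
    events = (
        TraceEvent(time=t_p4, label="p4"),
        TraceEvent(time=t_iono, label="ionomycin"),
        TraceEvent(time=t_mn, label="mncl2"),
    )
    return FluorescenceTrace(time=t, fluorescence=f, events=events)


# ---------------------------------------------------------------------------
# tracks


def make_tracks_with_truth(
    spec: TrackSpec, seed: int | None = None
) -> tuple[list[SpermTrack], list[str]]:
    """Persistent-random-walk tracks plus their generating class labels."""
    rng = np.random.default_rng(seed)
    classes = [c for c in MOTILITY_CLASSES if spec.class_mix.get(c, 0) > 0]
    probs = np.array([spec.class_mix[c] for c in classes], dtype=float)
    probs /= probs.sum()
    labels = [classes[i] for i in rng.choice(len(classes), size=spec.n_tracks, p=probs)]

    n_steps = spec.n_frames - 1
    dt = 1.0 / spec.frame_rate
    tracks: list[SpermTrack] = []
    for i, cls in enumerate(labels):
        origin = rng.uniform(0.0, 400.0, size=2)
        lo, hi = spec.speed_ranges.get(cls, (0.0, 0.0))
        speed = rng.uniform(lo, hi) if hi > lo else lo
        if cls == "immotile" or speed == 0.0:
            steps = np.zeros((n_steps, 2))
        else:
            theta0 = rng.uniform(0.0, 2 * np.pi)
            turns = rng.normal(0.0, spec.turning_noise.get(cls, 0.0), size=n_steps)
            theta = theta0 + np.concatenate([[0.0], np.cumsum(turns[:-1])])
            steps = speed * dt * np.column_stack([np.cos(theta), np.sin(theta)])
        positions = origin + np.vstack([[0.0, 0.0], np.cumsum(steps, axis=0)])
        if spec.position_noise_sd > 0:
            positions = positions + rng.normal(
                0.0, spec.position_noise_sd, size=positions.shape
            )
        tracks.append(
            SpermTrack(
                track_id=f"t{i:04d}", frame_rate=spec.frame_rate, positions=positions
            )
        )
    return tracks, labels


def make_tracks(spec: TrackSpec, seed: int | None = None) -> list[SpermTrack]:
    return make_tracks_with_truth(spec, seed)[0]


# ---------------------------------------------------------------------------
# cohorts


def _lognormal_mad_factor(sigma: float) -> float:
    """median(|X/m − 1|) for X log-normal with median m and log-sd sigma."""
    if sigma == 0:
        return 0.0

    def cdf_at(c: float) -> float:
        # P(|X/m - 1| <= c); the lower tail vanishes once c >= 1 (X > 0)
        upper = stats.norm.cdf(math.log1p(c) / sigma)
        lower = stats.norm.cdf(math.log(1.0 - c) / sigma) if c < 1.0 else 0.0
        return upper - lower

    return float(optimize.brentq(lambda c: cdf_at(c) - 0.5, 1e-12, 10.0))


def _lognormal_sigma(median: float, mad: float) -> float:
    """Log-sd giving a log-normal (median ``median``) the target unscaled MAD."""
    if mad == 0:
        return 0.0
    ratio = mad / abs(median)
    if ratio >= 1.0:
        raise SpecValidationError(
            f"MAD {mad} >= |median| {abs(median)}: unreachable for a log-normal"
        )
    return float(
        optimize.brentq(lambda s: _lognormal_mad_factor(s) - ratio, 1e-9, 20.0)
    )


def make_cohort(spec: CohortSpec) -> PairedCohort:
    """Draw one paired cohort.

    Arms are log-normal with the target median and MAD, coupled through a
    Gaussian copula with the requested latent correlation; negative-median
    variables are the negated positive family. With ``calibrate_median`` each
    arm is rescaled so its *sample* median equals the target exactly; the
    rescaling is multiplicative, preserving positivity and sign, and the MAD
    scales by the same near-unity factor.
    """
    rng = np.random.default_rng(spec.seed)
    z1 = rng.standard_normal(spec.n_subjects)
    eps = rng.standard_normal(spec.n_subjects)
    rho = spec.correlation
    z2 = rho * z1 + math.sqrt(1.0 - rho**2) * eps

    def arm(median: float, mad: float, z: np.ndarray) -> np.ndarray:
        sigma = _lognormal_sigma(median, mad)
        v = abs(median) * np.exp(sigma * z)
        return math.copysign(1.0, median) * v

    dgc = arm(spec.dgc_median, spec.dgc_mad, z1)
    ca0 = arm(spec.ca0_median, spec.ca0_mad, z2)
    if spec.calibrate_median:
        # multiplicative: preserves positivity (a shift could cross zero)
        dgc = dgc * (spec.dgc_median / np.median(dgc))
        ca0 = ca0 * (spec.ca0_median / np.median(ca0))
    return PairedCohort(
        variable=spec.variable,
        units=spec.units,
        sample_class=spec.sample_class,  # type: ignore[arg-type]
        subject_id=tuple(f"{spec.sample_class}{i + 1:03d}" for i in range(spec.n_subjects)),
        dgc=dgc,
        ca0=ca0,
        group=spec.group,
    )
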