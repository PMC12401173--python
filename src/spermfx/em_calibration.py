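"""Resting membrane potential from a DiSC₃(5) valinomycin/K⁺-step calibration.

With valinomycin present the membrane potential is clamped to the K⁺ Nernst
potential, so each stepped external K⁺ concentration pins the population at a
known potential. The plateau fluorescence after each step, paired with the
Nernst potential of that step, gives a fluorescence↔Em calibration; the
resting potential is read off by inverting the fitted line at the
pre-valinomycin fluorescence.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .errors import (
    CalibrationInvalidError,
    MissingEventError,
    SegmentTooShortError,
)
from .trace_io import FluorescenceTrace

#: universal gas constant, J·K⁻¹·mol⁻¹
R_GAS = 8.314
#: Faraday constant, C·mol⁻¹
FARADAY = 96485.33


@dataclass(frozen=True)
class NernstParams:
    """Constants of the K⁺ Nernst potential.

    ``intracellular_k`` defaults to 120 mM (measured in bovine sperm; used
    here as the standard assumption for human sperm) and ``temperature`` to
    310.15 K (37 °C recordings).
    """

    temperature: float = 310.15  # K
    intracellular_k: float = 120.0  # mM

    def __post_init__(self) -> None:
        if self.temperature <= 0:
            raise ValueError("temperature must be positive (kelvin)")
        if self.intracellular_k <= 0:
            raise ValueError("intracellular_k must be positive (mM)")


@dataclass(frozen=True)
class EmCalibration:
    """A fitted fluorescence↔Em map and the resting Em it yields."""

    calibration_points: tuple[tuple[float, float, float], ...]
    #: (external K⁺ mM, theoretical Em mV, plateau fluorescence a.u.)
    fit_slope: float  # a.u.·mV⁻¹
    fit_intercept: float  # a.u.
    fit_r2: float
    resting_fluorescence: float  # a.u.
    resting_em: float  # mV
    extrapolated: bool


def nernst_em(external_k: float, params: NernstParams = NernstParams()) -> float:
    """K⁺ equilibrium potential in mV: (RT/F)·ln([K⁺]ₒ/[K⁺]ᵢ).

    Strictly increasing in ``external_k`` and exactly zero when the external
    concentration equals the intracellular one.
    """
    if np.any(np.asarray(external_k) <= 0):
        raise ValueError("external_k must be positive (mM)")
    rt_f_mv = 1e3 * R_GAS * params.temperature / FARADAY
    return rt_f_mv * np.log(np.asarray(external_k, dtype=float) / params.intracellular_k)


def extract_plateaus(
    trace: FluorescenceTrace, window: float = 5.0
) -> list[tuple[float, float]]:
    """Per-K⁺-step plateau fluorescence: median over the trailing ``window`` s.

    Each step's segment runs from its KCl event to the next event (or the end
    of the trace). The trailing-window median is robust to the settling
    transient at the start of the segment.

    Returns ``[(external_k_mM, plateau_fluorescence), ...]`` in event order.
    """
    if trace.first_event("valinomycin") is None:
        raise MissingEventError("calibration trace has no valinomycin event")
    kcl = trace.events_labeled("kcl")
    if len(kcl) < 2:
        raise MissingEventError(
            f"calibration needs >= 2 KCl steps, found {len(kcl)}"
        )
    all_times = [e.time for e in trace.events]
    out = []
    for ev in kcl:
        later = [t for t in all_times if t > ev.time]
        seg_end = min(later) if later else float(trace.time[-1])
        if seg_end - ev.time < window:
            raise SegmentTooShortError(
                f"KCl step at t={ev.time} s has only {seg_end - ev.time:.3g} s "
                f"before the next event; window is {window} s"
            )
        mask = trace.segment_mask(seg_end - window, seg_end)
        if mask.sum() < 2:
            raise SegmentTooShortError(
                f"fewer than 2 samples in the trailing {window} s window "
                f"of the step at t={ev.time} s"
            )
        out.append((float(ev.payload["k_final_mM"]), float(np.median(trace.fluorescence[mask]))))
    return out


def estimate_resting_em(
    trace: FluorescenceTrace,
    params: NernstParams = NernstParams(),
    window: float = 5.0,
    r2_min: float = 0.95,
    pre_event_exclusion: float = 2.0,
) -> EmCalibration:
    """Estimate resting Em by inverting a linear fluorescence-vs-Em fit.

    Fluorescence is regressed on the theoretical Nernst potentials of the K⁺
    steps (least squares); resting fluorescence is the median of the
    pre-valinomycin segment, excluding ``pre_event_exclusion`` seconds right
    before the addition (mixing artefacts); resting Em is the fitted line
    inverted at that fluorescence. ``extrapolated`` flags a resting Em outside
    the calibrated potential range — permitted, since a strongly hyperpolarized
    population can sit below the most dilute calibration point.

    The estimate is invariant to affine rescaling of the fluorescence axis:
    gain and offset move slope and intercept but cancel in the inversion.
    """
    plateaus = extract_plateaus(trace, window=window)
    ems = np.array([nernst_em(k, params) for k, _ in plateaus])
    fls = np.array([f for _, f in plateaus])
    fit = stats.linregress(ems, fls)
    slope, intercept = float(fit.slope), float(fit.intercept)
    r2 = float(fit.rvalue) ** 2 if np.isfinite(fit.rvalue) else 0.0
    scale = max(1.0, float(np.max(np.abs(fls))))
    if not math.isfinite(slope) or abs(slope) <= 1e-12 * scale:
        raise CalibrationInvalidError(
            "degenerate calibration: fluorescence does not vary with Em"
        )
    if r2 < r2_min:
        raise CalibrationInvalidError(
            f"calibration r²={r2:.4f} below acceptance floor {r2_min}"
        )
    val = trace.first_event("valinomycin")
    mask = trace.time < (val.time - pre_event_exclusion)
    if mask.sum() < 2:
        raise SegmentTooShortError(
            "no usable pre-valinomycin baseline after the "
            f"{pre_event_exclusion} s exclusion"
        )
    resting_f = float(np.median(trace.fluorescence[mask]))
    resting_em = (resting_f - intercept) / slope
    extrapolated = not (float(ems.min()) <= resting_em <= float(ems.max()))
    return EmCalibration(
        calibration_points=tuple(
            (k, float(e), f) for (k, f), e in zip(plateaus, ems)
        ),
        fit_slope=slope,
        fit_intercept=intercept,
        fit_r2=r2,
        resting_fluorescence=resting_f,
        resting_em=float(resting_em),
        extrapolated=extrapolated,
    )
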