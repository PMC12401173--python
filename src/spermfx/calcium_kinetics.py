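"""Progesterone-response descriptors from a Fluo-3 trace.

A population Ca²⁺ trace is anchored by three reagent additions: progesterone
(P4) triggers the transient under study, ionomycin drives fluorescence to its
Ca²⁺-saturated maximum, and Mn²⁺ quenches the dye to its Ca²⁺-independent
minimum. The Mn²⁺ level defines zero; on the zeroed trace the transient is
summarized by three descriptors:

* ``delta_p4`` — peak amplitude over basal, as a basal-relative fold
  increment ``(f_max − f_basal)/f_basal``. The raw definition is "maximal
  response minus basal fluorescence", but the magnitudes this analysis works
  with (≈1–2.5, unitless) only exist in normalized units, so the amplitude is
  expressed relative to the Mn-zeroed basal level. This is the one
  interpretive choice in the module; it makes the descriptor invariant to
  instrument gain and offset.
* ``tau_up`` — half-time from the P4 addition to the half-amplitude upward
  crossing.
* ``tau_down`` — half-time of recovery: from the peak to the half-amplitude
  downward crossing. If the trace has not recovered to half-amplitude before
  ionomycin, recovery is censored and ``tau_down`` is reported missing,
  never imputed.

Half-times are crossing times of the (median-smoothed) trace with linear
interpolation between samples, not fitted rate constants.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .errors import (
    EventOrderError,
    MissingEventError,
    NormalizationDegenerateError,
    SegmentTooShortError,
)
from .trace_io import FluorescenceTrace


@dataclass(frozen=True)
class CaKinetics:
    """Descriptors of one P4-response trace (on the Mn-zeroed scale)."""

    f_basal: float  # a.u., median pre-P4
    f_max: float  # a.u., smoothed maximum between P4 and ionomycin
    t_max: float  # s, time of f_max
    f_iono: float  # a.u., median of the post-ionomycin, pre-Mn segment
    f_mn: float  # a.u., median of the trailing post-Mn window
    delta_p4: float  # dimensionless fold increment over basal
    tau_up: float | None  # s; None when the response is flat
    tau_down: float | None  # s; None when flat or censored by ionomycin
    recovered: bool  # reached half-recovery before ionomycin


def normalize_trace(
    trace: FluorescenceTrace, window: float = 1.0
) -> FluorescenceTrace:
    """Zero the trace on the Mn²⁺-quenched minimum.

    The zero reference is the median over the final ``window`` seconds of the
    post-Mn²⁺ segment (the dye is fully quenched by then). Idempotent on an
    already-zeroed trace, and commutes with gain: normalize(g·F) = g·normalize(F).
    """
    mn = trace.first_event("mncl2")
    if mn is None:
        raise MissingEventError("trace has no mncl2 event; cannot normalize")
    t_end = float(trace.time[-1])
    if t_end - mn.time < window:
        raise SegmentTooShortError(
            f"only {t_end - mn.time:.3g} s after MnCl2; window is {window} s"
        )
    mask = trace.segment_mask(t_end - window, t_end)
    f_mn = float(np.median(trace.fluorescence[mask]))
    return trace.with_fluorescence(trace.fluorescence - f_mn)


def _smooth(f: np.ndarray, window: int) -> np.ndarray:
    # centered moving median: robust to single-sample spikes, level-preserving
    if window <= 1:
        return f
    return ndimage.median_filter(f, size=window, mode="nearest")


def _cross_up(t, f, level, lo, hi):
    """First time in index range [lo, hi] where f rises to >= level (interp)."""
    for i in range(lo, hi + 1):
        if f[i] >= level:
            if i == lo or f[i] == f[i - 1]:
                return float(t[i])
            frac = (level - f[i - 1]) / (f[i] - f[i - 1])
            return float(t[i - 1] + frac * (t[i] - t[i - 1]))
    return None


def _cross_down(t, f, level, lo, hi):
    """First time in index range [lo, hi] where f falls to <= level (interp)."""
    for i in range(lo, hi + 1):
        if f[i] <= level:
            if i == lo or f[i] == f[i - 1]:
                return float(t[i])
            frac = (f[i - 1] - level) / (f[i - 1] - f[i])
            return float(t[i - 1] + frac * (t[i] - t[i - 1]))
    return None


def extract_kinetics(
    trace: FluorescenceTrace,
    smooth_window: int = 5,
    min_baseline: float = 5.0,
    mn_window: float = 1.0,
) -> CaKinetics:
    """Extract ΔP4 and the two half-times from a normalized trace.

    The trace must carry ordered ``p4`` < ``ionomycin`` < ``mncl2`` events and
    at least ``min_baseline`` seconds of pre-P4 baseline. Run
    :func:`normalize_trace` first; a basal level that is not positive after
    zeroing makes the fold increment undefined and raises
    :class:`NormalizationDegenerateError`.
    """
    p4 = trace.first_event("p4")
    iono = trace.first_event("ionomycin")
    mn = trace.first_event("mncl2")
    for ev, name in ((p4, "p4"), (iono, "ionomycin"), (mn, "mncl2")):
        if ev is None:
            raise MissingEventError(f"trace has no {name} event")
    if not (p4.time < iono.time < mn.time):
        raise EventOrderError(
            f"events out of order: p4={p4.time}, ionomycin={iono.time}, "
            f"mncl2={mn.time}"
        )
    t = trace.time
    f = trace.fluorescence
    if p4.time - t[0] < min_baseline:
        raise SegmentTooShortError(
            f"only {p4.time - t[0]:.3g} s of pre-P4 baseline; need {min_baseline} s"
        )
    s = _smooth(f, smooth_window)

    f_basal = float(np.median(f[t < p4.time]))
    if f_basal <= 0:
        raise NormalizationDegenerateError(
            f"basal fluorescence {f_basal:.4g} <= 0 after normalization"
        )

    # response window: strictly between P4 and ionomycin
    idx = np.where((t > p4.time) & (t < iono.time))[0]
    if idx.size < 2:
        raise SegmentTooShortError("no samples between P4 and ionomycin")
    i_max = int(idx[np.argmax(s[idx])])
    f_max = float(s[i_max])
    t_max = float(t[i_max])

    amplitude = f_max - f_basal
    half = f_basal + amplitude / 2.0

    iono_mask = (t > iono.time) & (t < mn.time)
    f_iono = float(np.median(f[iono_mask])) if iono_mask.any() else float("nan")
    t_end = float(t[-1])
    mn_mask = trace.segment_mask(max(mn.time, t_end - mn_window), t_end)
    f_mn = float(np.median(f[mn_mask]))

    if amplitude <= 0:
        # flat (or inverted) response: no transient, half-times undefined
        return CaKinetics(
            f_basal=f_basal, f_max=f_max, t_max=t_max, f_iono=f_iono, f_mn=f_mn,
            delta_p4=0.0, tau_up=None, tau_down=None, recovered=False,
        )

    delta_p4 = amplitude / f_basal
    t_up = _cross_up(t, s, half, int(idx[0]), i_max)
    tau_up = None if t_up is None else t_up - p4.time
    t_down = _cross_down(t, s, half, i_max, int(idx[-1]))
    if t_down is None:
        return CaKinetics(
            f_basal=f_basal, f_max=f_max, t_max=t_max, f_iono=f_iono, f_mn=f_mn,
            delta_p4=delta_p4, tau_up=tau_up, tau_down=None, recovered=False,
        )
    return CaKinetics(
        f_basal=f_basal, f_max=f_max, t_max=t_max, f_iono=f_iono, f_mn=f_mn,
        delta_p4=delta_p4, tau_up=tau_up, tau_down=t_down - t_max, recovered=True,
    )
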