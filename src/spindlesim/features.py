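"""Scalar descriptors of stress and receptor-potential traces.

The features mirror the quantities stretch physiologists read off a
ramp-and-hold response: the *initial burst* (first transient peak at stretch
onset, baseline-subtracted), the *dynamic response* (line fit to the rise
during the ramp after the burst), the *dynamic index* (peak ramp response
minus the settled hold-phase response) and, for paired stretch-shorten
protocols, the *recovery time* until the signal reappears above its resting
value after a shortening.

A burst is only declared when the first interior local maximum inside the
ramp is followed by a local minimum that is still inside the ramp: a genuine
short-range-stiffness burst is a peak-then-dip transient, whereas a response
that merely climbs until the stretch turns around produces no interior dip
and is reported as burst-absent.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple, Optional

import numpy as np

__all__ = [
    "Burst",
    "DynamicResponse",
    "FeatureSet",
    "initial_burst",
    "dynamic_response",
    "dynamic_index",
    "recovery_time",
    "extract_ramp_hold_features",
]


class Burst(NamedTuple):
    """Initial-burst measurement (a.u., baseline-subtracted)."""

    value: float
    present: bool
    peak_time: Optional[float]
    baseline: float


@dataclass(frozen=True)
class DynamicResponse:
    """Line fit to the post-burst rise during the ramp.

    ``rise`` is slope * fit-interval length (the convention used to report
    the feature); ``slope`` is the raw least-squares slope in a.u. s^-1.
    """

    rise: float
    slope: float
    fit_start: float
    fit_end: float


@dataclass
class FeatureSet:
    """Bundle of ramp-and-hold features extracted from one trace."""

    initial_burst: float
    burst_present: bool
    dynamic_response: float
    dynamic_response_slope: float
    dynamic_index: float
    recovery_time: Optional[float] = None


def _index_of(time: np.ndarray, t: float) -> int:
    """Index of the first sample at or after t (t must lie inside the trace)."""
    if t < time[0] - 1e-12 or t > time[-1] + 1e-12:
        raise ValueError(f"time point {t} s lies outside the trace")
    return int(np.searchsorted(time, t - 1e-12))


def _first_local_max(x: np.ndarray, i0: int, i1: int) -> Optional[int]:
    """First index in (i0, i1) strictly greater than both neighbours."""
    for i in range(max(i0 + 1, 1), min(i1, x.shape[0] - 1)):
        if x[i] > x[i - 1] and x[i] > x[i + 1]:
            return i
    return None


def _first_local_min(x: np.ndarray, i0: int, i1: int) -> Optional[int]:
    for i in range(max(i0 + 1, 1), min(i1, x.shape[0] - 1)):
        if x[i] < x[i - 1] and x[i] < x[i + 1]:
            return i
    return None


def initial_burst(
    signal: np.ndarray,
    time: np.ndarray,
    stretch_onset: float,
    ramp_end: float,
    baseline_window: float = 0.5,
    eps: float = 0.0,
) -> Burst:
    """Baseline-subtracted magnitude of the first transient peak in the ramp.

    The baseline is the mean of the signal over ``baseline_window`` seconds
    before the onset.  The burst is the first interior local maximum within
    the ramp window, and it must be followed by an interior local minimum
    (the post-burst dip) before the ramp ends; otherwise the peak belongs to
    the ramp turnaround and no burst is reported.  ``present`` additionally
    requires the value to exceed ``eps``.
    """
    signal = np.asarray(signal, dtype=float)
    time = np.asarray(time, dtype=float)
    i_on = _index_of(time, stretch_onset)
    i_end = _index_of(time, ramp_end)
    i_base = _index_of(time, max(stretch_onset - baseline_window, time[0]))
    baseline = float(np.mean(signal[i_base : max(i_on, i_base + 1)]))
    i_peak = _first_local_max(signal, i_on, i_end)
    if i_peak is None:
        return Burst(0.0, False, None, baseline)
    i_dip = _first_local_min(signal, i_peak, i_end)
    if i_dip is None:
        return Burst(0.0, False, None, baseline)
    value = float(signal[i_peak] - baseline)
    return Burst(value, value > eps, float(time[i_peak]), baseline)


def dynamic_response(
    signal: np.ndarray,
    time: np.ndarray,
    stretch_onset: float,
    ramp_end: float,
    baseline_window: float = 0.5,
) -> DynamicResponse:
    """Least-squares line fit to the ramp response after the initial burst.

    The fit runs from the signal's lowest value after the burst peak to the
    end of the ramp; when no burst is present it runs from the ramp onset.
    Reported as the fitted rise over the fit interval (slope x interval), with
    the raw slope alongside.
    """
    signal = np.asarray(signal, dtype=float)
    time = np.asarray(time, dtype=float)
    burst = initial_burst(signal, time, stretch_onset, ramp_end, baseline_window)
    i_end = _index_of(time, ramp_end)
    if burst.present:
        i_peak = _index_of(time, burst.peak_time)
        i_fit = i_peak + int(np.argmin(signal[i_peak : i_end + 1]))
    else:
        i_fit = _index_of(time, stretch_onset)
    if i_end <= i_fit + 1:
        return DynamicResponse(0.0, 0.0, float(time[i_fit]), float(time[i_end]))
    t_fit = time[i_fit : i_end + 1]
    slope, _ = np.polyfit(t_fit, signal[i_fit : i_end + 1], 1)
    interval = float(t_fit[-1] - t_fit[0])
    return DynamicResponse(float(slope * interval), float(slope), float(t_fit[0]), float(t_fit[-1]))


def dynamic_index(
    signal: np.ndarray,
    time: np.ndarray,
    stretch_onset: float,
    ramp_end: float,
    hold_end: float,
    baseline_window: float = 0.5,
) -> float:
    """Peak dynamic response during the late ramp minus the final hold value.

    The peak is taken after the post-burst dip (when a burst is present) so
    the initial-burst transient itself is not mistaken for the dynamic
    response; the hold-phase value is read at ``hold_end``.
    """
    signal = np.asarray(signal, dtype=float)
    time = np.asarray(time, dtype=float)
    burst = initial_burst(signal, time, stretch_onset, ramp_end, baseline_window)
    i_end = _index_of(time, ramp_end)
    if burst.present:
        i_peak = _index_of(time, burst.peak_time)
        i_from = i_peak + int(np.argmin(signal[i_peak : i_end + 1]))
    else:
        i_from = _index_of(time, stretch_onset)
    peak = float(np.max(signal[i_from : i_end + 1]))
    return peak - float(signal[_index_of(time, hold_end)])


def recovery_time(
    signal: np.ndarray,
    time: np.ndarray,
    second_onset: float,
    resting_value: float,
    eps: float,
) -> Optional[float]:
    """Delay after the second stretch onset until the signal reappears.

    Returns the first time after ``second_onset`` at which the signal exceeds
    ``resting_value + eps`` (the pre-conditioning resting level plus a small
    detection threshold), measured from the onset; zero if already above at
    onset, None if the threshold is never crossed.
    """
    signal = np.asarray(signal, dtype=float)
    time = np.asarray(time, dtype=float)
    i_on = _index_of(time, second_onset)
    above = signal[i_on:] > resting_value + eps
    if above[0]:
        return 0.0
    idx = np.argmax(above)
    if idx == 0:
        return None
    return float(time[i_on + idx] - second_onset)


def extract_ramp_hold_features(
    signal: np.ndarray,
    time: np.ndarray,
    stretch_onset: float,
    ramp_end: float,
    hold_end: float,
    baseline_window: float = 0.5,
    eps_burst: float = 0.0,
) -> FeatureSet:
    """All ramp-and-hold features of one trace in a single bundle."""
    burst = initial_burst(signal, time, stretch_onset, ramp_end, baseline_window, eps_burst)
    dr = dynamic_response(signal, time, stretch_onset, ramp_end, baseline_window)
    di = dynamic_index(signal, time, stretch_onset, ramp_end, hold_end, baseline_window)
    return FeatureSet(
        initial_burst=burst.value,
        burst_present=burst.present,
        dynamic_response=dr.rise,
        dynamic_response_slope=dr.slope,
        dynamic_index=di,
    )
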