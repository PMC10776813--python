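"""Stretch and activation protocols for the half-sarcomere engine.

Length protocols are expressed the way stretch physiology reports them:
amplitudes in % of the resting half-sarcomere length L0 and velocities in
% L0 per second.  Every shipped protocol starts with a 2 s isometric pre-hold
at the protocol pCa so that thin-filament activation and the bound cross-bridge
population reach steady state before any length change.

All protocols are sampled on a uniform 10 kHz grid and are piecewise linear
(ramps, triangles) or sinusoidal; they can be resampled onto an arbitrary
engine time step and serialized to a delimited table (time_s, length_nm, pCa).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "SAMPLE_RATE",
    "DEFAULT_PCA",
    "LengthProtocol",
    "ActivationProtocol",
    "ramp_hold",
    "triangle_pair",
    "sinusoid",
]

SAMPLE_RATE = 10_000.0  # Hz; equal to the default engine rate (dt = 0.1 ms)
DEFAULT_PCA = 6.4  # near-passive activation used across all shipped protocols
DEFAULT_L0 = 1300.0  # nm


@dataclass
class LengthProtocol:
    """Uniformly sampled half-sarcomere length time series (nm).

    ``events`` holds the named time points (stretch onsets, ramp ends, hold
    end) that the feature-extraction stage needs; ``metadata`` carries the
    generating parameters so any run can be reproduced from its record.
    """

    time: np.ndarray
    hs_length: np.ndarray
    metadata: dict = field(default_factory=dict)
    events: dict = field(default_factory=dict)

    @property
    def dt(self) -> float:
        return float(self.time[1] - self.time[0])

    @property
    def duration(self) -> float:
        return float(self.time[-1])

    def resample(self, dt: float) -> "LengthProtocol":
        """Linear-interpolate the protocol onto a uniform grid of step dt."""
        if dt <= 0:
            raise ValueError("dt must be > 0")
        n = int(round(self.duration / dt)) + 1
        t = dt * np.arange(n)
        return LengthProtocol(
            time=t,
            hs_length=np.interp(t, self.time, self.hs_length),
            metadata=dict(self.metadata),
            events=dict(self.events),
        )

    def to_frame(self, pca: float = DEFAULT_PCA) -> pd.DataFrame:
        return pd.DataFrame(
            {"time_s": self.time, "length_nm": self.hs_length, "pCa": pca}
        )


@dataclass
class ActivationProtocol:
    """Uniformly sampled activation series in pCa units."""

    time: np.ndarray
    pca: np.ndarray

    @staticmethod
    def constant(protocol: LengthProtocol, pca: float = DEFAULT_PCA) -> "ActivationProtocol":
        return ActivationProtocol(
            time=protocol.time, pca=np.full_like(protocol.time, pca)
        )


def _from_breakpoints(
    knots_t: list[float], knots_l: list[float], sample_rate: float
) -> tuple[np.ndarray, np.ndarray]:
    """Sample a piecewise-linear length profile exactly on a uniform grid."""
    duration = knots_t[-1]
    n = int(round(duration * sample_rate)) + 1
    t = np.arange(n) / sample_rate
    return t, np.interp(t, np.asarray(knots_t), np.asarray(knots_l))


def ramp_hold(
    velocity: float,
    amplitude: float,
    pre_hold: float = 2.0,
    total: float = 3.0,
    L0: float = DEFAULT_L0,
    sample_rate: float = SAMPLE_RATE,
) -> LengthProtocol:
    """Ramp-and-hold stretch: pre-hold at L0, linear ramp, hold at the new length.

    ``velocity`` is in % L0 s^-1 and ``amplitude`` in % L0; ``total`` is the
    duration of the stretch-and-hold portion measured from stretch onset, so
    the full protocol lasts ``pre_hold + total`` seconds.
    """
    if velocity <= 0:
        raise ValueError("velocity must be > 0")
    if amplitude < 0:
        raise ValueError("amplitude must be >= 0")
    ramp_dur = amplitude / velocity
    if ramp_dur > total:
        raise ValueError("ramp duration exceeds the protocol duration")
    peak = L0 * (1.0 + amplitude / 100.0)
    if amplitude > 0:
        knots_t = [0.0, pre_hold, pre_hold + ramp_dur, pre_hold + total]
        knots_l = [L0, L0, peak, peak]
    else:
        knots_t, knots_l = [0.0, pre_hold + total], [L0, L0]
    t, length = _from_breakpoints(knots_t, knots_l, sample_rate)
    return LengthProtocol(
        time=t,
        hs_length=length,
        metadata={
            "kind": "ramp_hold",
            "velocity": velocity,
            "amplitude": amplitude,
            "pre_hold": pre_hold,
            "total": total,
            "L0": L0,
        },
        events={
            "onset": pre_hold,
            "ramp_end": pre_hold + ramp_dur,
            "hold_end": pre_hold + total,
        },
    )


def triangle_pair(
    velocity: float,
    cond_amplitude: float,
    test_amplitude: float,
    isi: float,
    pre_hold: float = 2.0,
    trailing_hold: float = 1.0,
    L0: float = DEFAULT_L0,
    sample_rate: float = SAMPLE_RATE,
) -> LengthProtocol:
    """Conditioning and test symmetric stretch-shorten triangles.

    A triangle ramps from L0 up to the given amplitude and straight back down
    at the same velocity.  The two triangles are separated by an isometric
    inter-stretch interval (ISI) at L0; a zero-amplitude conditioning triangle
    degenerates to nothing, yielding an unconditioned test stretch.
    """
    if velocity <= 0:
        raise ValueError("velocity must be > 0")
    if cond_amplitude < 0 or test_amplitude < 0:
        raise ValueError("amplitudes must be >= 0")
    if isi < 0:
        raise ValueError("isi must be >= 0")
    cond_ramp = cond_amplitude / velocity
    test_ramp = test_amplitude / velocity
    cond_peak = L0 * (1.0 + cond_amplitude / 100.0)
    test_peak = L0 * (1.0 + test_amplitude / 100.0)

    knots_t: list[float] = [0.0, pre_hold]
    knots_l: list[float] = [L0, L0]
    t_cursor = pre_hold
    if cond_amplitude > 0:
        knots_t += [t_cursor + cond_ramp, t_cursor + 2 * cond_ramp]
        knots_l += [cond_peak, L0]
        t_cursor += 2 * cond_ramp
    test_onset = t_cursor + isi
    if isi > 0:
        knots_t.append(test_onset)
        knots_l.append(L0)
    if test_amplitude > 0:
        knots_t += [test_onset + test_ramp, test_onset + 2 * test_ramp]
        knots_l += [test_peak, L0]
    end = test_onset + 2 * test_ramp + trailing_hold
    knots_t.append(end)
    knots_l.append(L0)
    t, length = _from_breakpoints(knots_t, knots_l, sample_rate)
    return LengthProtocol(
        time=t,
        hs_length=length,
        metadata={
            "kind": "triangle_pair",
            "velocity": velocity,
            "cond_amplitude": cond_amplitude,
            "test_amplitude": test_amplitude,
            "isi": isi,
            "pre_hold": pre_hold,
            "trailing_hold": trailing_hold,
            "L0": L0,
        },
        events={
            "cond_onset": pre_hold,
            "cond_ramp_end": pre_hold + cond_ramp,
            "cond_end": pre_hold + 2 * cond_ramp,
            "test_onset": test_onset,
            "test_ramp_end": test_onset + test_ramp,
            "test_end": test_onset + 2 * test_ramp,
            "end": end,
        },
    )


def sinusoid(
    amplitude: float,
    frequency: float = 1.0,
    n_cycles: int = 3,
    pre_hold: float = 2.0,
    L0: float = DEFAULT_L0,
    sample_rate: float = SAMPLE_RATE,
) -> LengthProtocol:
    """Raised-cosine sinusoidal stretch-shorten cycles.

    The length starts at L0 moving into stretch and the peak-to-baseline
    excursion equals ``amplitude`` (% L0):
    L(t) = L0 * (1 + a * (1 - cos(2 pi f t)) / 2) after the pre-hold.
    """
    if amplitude < 0:
        raise ValueError("amplitude must be >= 0")
    if frequency <= 0 or n_cycles < 1:
        raise ValueError("frequency must be > 0 and n_cycles >= 1")
    duration = pre_hold + n_cycles / frequency
    n = int(round(duration * sample_rate)) + 1
    t = np.arange(n) / sample_rate
    phase = np.clip(t - pre_hold, 0.0, None)
    a = amplitude / 100.0
    length = L0 * (1.0 + 0.5 * a * (1.0 - np.cos(2.0 * np.pi * frequency * phase)))
    cycle_starts = [pre_hold + k / frequency for k in range(n_cycles)]
    return LengthProtocol(
        time=t,
        hs_length=length,
        metadata={
            "kind": "sinusoid",
            "amplitude": amplitude,
            "frequency": frequency,
            "n_cycles": n_cycles,
            "pre_hold": pre_hold,
            "L0": L0,
        },
        events={
            "onset": pre_hold,
            "cycle_starts": cycle_starts,
            "end": duration,
        },
    )
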