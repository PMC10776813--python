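"""Ia-afferent receptor potential from bag and chain fibre forces.

The receptor potential at the spike-initiating region is phenomenological:
a scaled, weighted sum of the chain fibre force, the bag fibre force, and the
half-wave-rectified yank (time derivative of force) of the bag fibre,

    r_total(t) = scale * (k_fc * F_c(t) + k_fb * F_b(t) + k_yb * [dF_b/dt]_+)

All receptor-potential quantities are in arbitrary units; no conversion to
membrane potential is attempted.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["ReceptorWeights", "SpindleTrace", "yank", "receptor_potential", "write_trace"]


@dataclass(frozen=True)
class ReceptorWeights:
    """Weights of the receptor-potential model (a.u.), fixed across protocols."""

    k_fb: float = 0.4
    k_fc: float = 0.5
    k_yb: float = 0.005
    scale: float = 2.0e5

    def __post_init__(self) -> None:
        if min(self.k_fb, self.k_fc, self.k_yb, self.scale) < 0:
            raise ValueError("receptor weights must be >= 0")


@dataclass
class SpindleTrace:
    """Receptor-potential time series and its per-fibre components (a.u.)."""

    time: np.ndarray
    bag_component: np.ndarray
    chain_component: np.ndarray

    @property
    def r_total(self) -> np.ndarray:
        return self.bag_component + self.chain_component

    @property
    def dt(self) -> float:
        return float(self.time[1] - self.time[0])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time_s": self.time,
                "bag_au": self.bag_component,
                "chain_au": self.chain_component,
                "rtotal_au": self.r_total,
            }
        )


def yank(force: np.ndarray, dt: float, time: np.ndarray | None = None) -> np.ndarray:
    """Half-wave-rectified time derivative of a uniformly sampled force trace.

    First-order backward difference; the first sample has no predecessor and
    its yank is defined as zero.  Negative rates are rectified to zero.
    """
    force = np.asarray(force, dtype=float)
    if force.ndim != 1 or force.shape[0] < 2:
        raise ValueError("force trace must be 1-d with at least 2 samples")
    if dt <= 0:
        raise ValueError("dt must be > 0")
    if time is not None:
        steps = np.diff(np.asarray(time, dtype=float))
        if not np.allclose(steps, dt, rtol=1e-9, atol=1e-12 * max(dt, 1.0)):
            raise ValueError("trace is not uniformly sampled at dt")
    dy = np.empty_like(force)
    dy[0] = 0.0
    dy[1:] = np.diff(force) / dt
    return np.maximum(dy, 0.0)


def receptor_potential(
    bag_force: np.ndarray,
    chain_force: np.ndarray,
    weights: ReceptorWeights,
    dt: float,
    t0: float = 0.0,
) -> SpindleTrace:
    """Combine time-aligned bag and chain force traces into a receptor potential.

    bag component  = scale * (k_fb * F_b + k_yb * rectified yank(F_b))
    chain component = scale * k_fc * F_c
    """
    bag_force = np.asarray(bag_force, dtype=float)
    chain_force = np.asarray(chain_force, dtype=float)
    if bag_force.shape != chain_force.shape:
        raise ValueError("bag and chain traces must have equal length")
    bag = weights.scale * (weights.k_fb * bag_force + weights.k_yb * yank(bag_force, dt))
    chain = weights.scale * weights.k_fc * chain_force
    time = t0 + dt * np.arange(bag_force.shape[0])
    return SpindleTrace(time=time, bag_component=bag, chain_component=chain)


def write_trace(path, trace: SpindleTrace) -> None:
    """Write a spindle trace as a delimited table."""
    trace.to_frame().to_csv(path, index=False)
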