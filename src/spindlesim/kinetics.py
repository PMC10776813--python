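"""Half-sarcomere cross-bridge engine for intrafusal muscle fibres.

Each intrafusal fibre (dynamic *bag* or static *chain*) is modelled as a single
half-sarcomere: a thin (actin) filament whose sites are activated by calcium
with inter-filament cooperativity, and a thick (myosin) filament whose heads
cycle between a detached state and an attached, strained state.  Attached
heads (cross-bridges) are linear springs; the population is tracked as a
distribution over a uniform strain grid and is advected along that grid when
the imposed half-sarcomere length changes.  Total stress is the cross-bridge
spring force scaled by the areal head density plus a linear parallel-elastic
passive term.

All fractions (activated actin, bound myosin) are per total available sites;
attached + detached myosin always sums to one.  Lengths are in nanometres,
times in seconds, calcium in molar, stress in N m^-2.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

try:  # pragma: no cover - exercised implicitly wherever numba is installed
    from numba import njit as _njit

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    _HAVE_NUMBA = False

    def _njit(*a, **k):
        def deco(fn):
            return fn

        return deco if not a else a[0]


__all__ = [
    "FilamentGeometry",
    "ThinFilamentParams",
    "CrossBridgeParams",
    "PassiveParams",
    "FibreParams",
    "StrainGrid",
    "FibreState",
    "FibreTrace",
    "InvalidParameterError",
    "StateCorruptionError",
    "GridOverflowError",
    "pca_to_molar",
    "filament_overlap",
    "attachment_rate",
    "detachment_rate",
    "actin_derivative",
    "myosin_derivatives",
    "stress",
    "advance",
    "simulate",
    "save_trace",
    "load_trace",
]

# nm -> m conversion applied to cross-bridge strain inside the stress sum; with
# the head density (m^-2) and spring constant below this yields N m^-2.
_STRAIN_NM_TO_M = 1e-9


class InvalidParameterError(ValueError):
    """A parameter set violates its structural constraints."""


class StateCorruptionError(RuntimeError):
    """A fibre state violates the ordering invariant cb_attached <= actin."""


class GridOverflowError(RuntimeError):
    """Bound-myosin mass reached the edge of the strain grid above tolerance."""


# ---------------------------------------------------------------------------
# parameter bundles
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class FilamentGeometry:
    """Filament lengths (nm) setting the thick/thin overlap function."""

    length_thin_filament: float = 1120.0
    length_thick_filament: float = 815.0
    length_bare_zone: float = 80.0
    resting_length_L0: float = 1300.0

    def __post_init__(self) -> None:
        for name in (
            "length_thin_filament",
            "length_thick_filament",
            "length_bare_zone",
            "resting_length_L0",
        ):
            if getattr(self, name) <= 0:
                raise InvalidParameterError(f"{name} must be > 0")
        if self.length_bare_zone >= self.length_thick_filament:
            raise InvalidParameterError(
                "length_bare_zone must be smaller than length_thick_filament"
            )


@dataclass(frozen=True)
class ThinFilamentParams:
    """Calcium-driven actin site kinetics.

    k_on (M^-1 s^-1) and k_off (s^-1) are the site activation/deactivation
    rate constants; k_coop (dimensionless) scales the myosin-dependent
    cooperative enhancement of activation and suppression of deactivation.
    """

    k_on: float = 8.0e7
    k_off: float = 200.0
    k_coop: float = 1.0

    def __post_init__(self) -> None:
        if self.k_on < 0 or self.k_off < 0 or self.k_coop < 0:
            raise InvalidParameterError("thin filament rates must be >= 0")


@dataclass(frozen=True)
class CrossBridgeParams:
    """Two-state myosin cycling rates and cross-bridge mechanics.

    The attachment rate is Gaussian in strain,
    ``f(dx) = attach_slope * exp(-cb_stiffness * dx^2 / const_f)`` (1/e
    half-width sqrt(const_f / cb_stiffness) ~ 8.5 nm with the defaults), so
    heads attach over a window of several nm around zero strain.

    The detachment rate is U-shaped: a piecewise cubic around
    ``detach_breakpoint`` with coefficient ``detach_coeff_below`` on the
    compressed side and ``detach_coeff_above`` on the stretched side, plus the
    fibre-specific ``detach_extra_offset``; its minimum,
    ``detach_offset + detach_extra_offset`` at the breakpoint, sets the
    lifetime of the resting bound pool and thereby the fibre's memory
    timescale.
    """

    attach_slope: float = 600.0  # s^-1 (b_f bag / c_f chain)
    detach_offset: float = 7.0  # s^-1 (b_g bag / c_g chain)
    detach_extra_offset: float = 0.5  # s^-1 (offset_bag / offset_chain)
    detach_coeff_below: float = 0.2  # s^-1 nm^-3
    detach_coeff_above: float = 0.3  # s^-1 nm^-3
    detach_breakpoint: float = -5.0  # nm
    cb_density: float = 6.9e16  # heads m^-2
    cb_stiffness: float = 0.001  # pN nm^-1, exactly as tabulated (see docs/methods.md)
    const_f: float = 7.2e-2  # pN nm

    def __post_init__(self) -> None:
        for name in (
            "attach_slope",
            "detach_offset",
            "detach_extra_offset",
            "detach_coeff_below",
            "detach_coeff_above",
            "cb_density",
            "cb_stiffness",
            "const_f",
        ):
            if getattr(self, name) < 0:
                raise InvalidParameterError(f"{name} must be >= 0")


@dataclass(frozen=True)
class PassiveParams:
    """Linear parallel-elastic element: stress = k * (L - length_slack)."""

    passive_stiffness: float = 90.0  # N m^-2 nm^-1
    length_slack: float = 1050.0  # nm

    def __post_init__(self) -> None:
        if self.passive_stiffness < 0:
            raise InvalidParameterError("passive_stiffness must be >= 0")


@dataclass(frozen=True)
class FibreParams:
    """Complete parameter bundle for one intrafusal fibre."""

    label: str
    geometry: FilamentGeometry = field(default_factory=FilamentGeometry)
    thin: ThinFilamentParams = field(default_factory=ThinFilamentParams)
    xb: CrossBridgeParams = field(default_factory=CrossBridgeParams)
    passive: PassiveParams = field(default_factory=PassiveParams)

    @staticmethod
    def bag(
        b_f: float = 600.0,
        b_g: float = 7.0,
        k_coop: float = 1.0,
        k_off: float = 200.0,
    ) -> "FibreParams":
        """Dynamic bag1 fibre with the tuned final rate set."""
        return FibreParams(
            label="bag",
            thin=ThinFilamentParams(k_off=k_off, k_coop=k_coop),
            xb=CrossBridgeParams(
                attach_slope=b_f, detach_offset=b_g, detach_extra_offset=0.5
            ),
            passive=PassiveParams(passive_stiffness=90.0, length_slack=1050.0),
        )

    @staticmethod
    def chain(
        c_f: float = 400.0,
        c_g: float = 300.0,
        k_coop: float = 1.0,
        k_off: float = 200.0,
    ) -> "FibreParams":
        """Static bag2/chain fibre with the tuned final rate set."""
        return FibreParams(
            label="chain",
            thin=ThinFilamentParams(k_off=k_off, k_coop=k_coop),
            xb=CrossBridgeParams(
                attach_slope=c_f, detach_offset=c_g, detach_extra_offset=10.0
            ),
            passive=PassiveParams(passive_stiffness=250.0, length_slack=1200.0),
        )

    def with_variant(self, k_off: Optional[float] = None, k_coop: Optional[float] = None) -> "FibreParams":
        thin = self.thin
        if k_off is not None:
            thin = replace(thin, k_off=k_off)
        if k_coop is not None:
            thin = replace(thin, k_coop=k_coop)
        return replace(self, thin=thin)


@dataclass(frozen=True)
class StrainGrid:
    """Uniform strain grid (nm) over which bound myosin is distributed.

    The default span is asymmetric: shortening drags surviving bridges below
    the detachment minimum at the breakpoint, where the cubic rise of g is
    slower than on the stretch side, so the negative side needs more headroom.
    Both edges sit where attachment-tail deposition balanced against
    detachment leaves well under 1e-6 occupancy in all shipped protocols.
    """

    lower_bound: float = -40.0
    upper_bound: float = 25.0
    bin_width: float = 0.5

    def __post_init__(self) -> None:
        if not (self.lower_bound < 0.0 < self.upper_bound):
            raise InvalidParameterError("grid must straddle zero strain")
        if self.bin_width <= 0:
            raise InvalidParameterError("bin_width must be > 0")

    @property
    def bin_centres(self) -> np.ndarray:
        n = int(round((self.upper_bound - self.lower_bound) / self.bin_width)) + 1
        return self.lower_bound + self.bin_width * np.arange(n)

    @property
    def n_bins(self) -> int:
        return len(self.bin_centres)

    def refined(self, factor: int = 2) -> "StrainGrid":
        return StrainGrid(self.lower_bound, self.upper_bound, self.bin_width / factor)


@dataclass
class FibreState:
    """Instantaneous half-sarcomere state.

    bound_myosin[i] is the fraction of all myosin heads bound with strain in
    grid bin i; the detached fraction is 1 - sum(bound_myosin).
    ``strain_offset`` is the sub-bin residue of the exact advection scheme:
    the true strain of bin i is ``bin_centres[i] + strain_offset``, with
    |strain_offset| <= bin_width / 2.
    """

    time: float
    hs_length: float
    actin_activated: float
    bound_myosin: np.ndarray
    strain_offset: float = 0.0

    @property
    def cb_attached(self) -> float:
        return float(np.sum(self.bound_myosin))

    @property
    def detached(self) -> float:
        return 1.0 - self.cb_attached

    @staticmethod
    def resting(params: FibreParams, grid: StrainGrid) -> "FibreState":
        """Zero activation, zero bound myosin, at resting length."""
        return FibreState(
            time=0.0,
            hs_length=params.geometry.resting_length_L0,
            actin_activated=0.0,
            bound_myosin=np.zeros(grid.n_bins),
        )


# ---------------------------------------------------------------------------
# elementary rate laws
# ---------------------------------------------------------------------------


def pca_to_molar(pca) -> float:
    """Convert pCa (= -log10 [Ca2+]) to molar concentration."""
    pca = np.asarray(pca, dtype=float)
    if np.any(pca <= 0):
        raise InvalidParameterError("pCa must be > 0")
    out = 10.0 ** (-pca)
    return float(out) if out.ndim == 0 else out


def filament_overlap(hs_length, geometry: FilamentGeometry):
    """Fraction of actin sites within reach of the thick filament.

    Linear in half-sarcomere length, clamped to [0, 1]: with default geometry
    the overlap is 1 below 1200 nm and reaches 0 at 1935 nm.
    """
    denom = geometry.length_thick_filament - geometry.length_bare_zone
    if denom <= 0:
        raise InvalidParameterError("thick filament shorter than bare zone")
    hs_length = np.asarray(hs_length, dtype=float)
    if np.any(hs_length <= 0):
        raise InvalidParameterError("hs_length must be > 0")
    frac = (
        geometry.length_thin_filament
        - (hs_length - geometry.length_thick_filament)
    ) / denom
    out = np.clip(frac, 0.0, 1.0)
    return float(out) if out.ndim == 0 else out


def attachment_rate(strain, xb: CrossBridgeParams):
    """Myosin attachment rate f(dx): Gaussian peak at zero strain.

    The exponent is the cross-bridge spring energy over the thermal constant
    const_f; with the default constants the 1/e half-width is
    sqrt(const_f / cb_stiffness) ~ 8.5 nm.
    """
    strain = np.asarray(strain, dtype=float)
    out = xb.attach_slope * np.exp(-xb.cb_stiffness * strain**2 / xb.const_f)
    return float(out) if out.ndim == 0 else out


def detachment_rate(strain, xb: CrossBridgeParams):
    """Myosin detachment rate g(dx): U-shaped cubic around the breakpoint.

    Below the breakpoint the cubic grows with |dx - breakpoint| (coefficient
    detach_coeff_below); above it with coefficient detach_coeff_above.  The
    fibre-specific extra offset applies to both branches, so the minimum is
    detach_offset + detach_extra_offset at the breakpoint.  Bridges are
    longest-lived near the breakpoint; detachment rises steeply on both
    sides, so stretch or shortening strips the bound pool.
    """
    strain = np.asarray(strain, dtype=float)
    d = strain - xb.detach_breakpoint
    cubic = np.where(
        d >= 0,
        xb.detach_coeff_above * d**3,
        xb.detach_coeff_below * np.abs(d) ** 3,
    )
    out = xb.detach_offset + xb.detach_extra_offset + cubic
    return float(out) if out.ndim == 0 else out


def actin_derivative(
    state: FibreState,
    thin: ThinFilamentParams,
    ca: float,
    geometry: FilamentGeometry,
) -> float:
    """Rate of change of the activated-actin fraction.

    Activation pulls free overlapped sites on at k_on*[Ca]; deactivation turns
    off activated sites that carry no bound myosin at k_off.  Cooperativity
    (k_coop) boosts activation in proportion to existing activation and
    suppresses deactivation near full activation.  At zero overlap the
    cooperativity ratios (and the activation term) are defined as zero.
    """
    n_ov = filament_overlap(state.hs_length, geometry)
    a = state.actin_activated
    cb = state.cb_attached
    if cb > a + 1e-12:
        raise StateCorruptionError("cb_attached exceeds actin_activated")
    if n_ov <= 0.0:
        return -thin.k_off * (a - cb)
    act = thin.k_on * ca * (n_ov - a) * (1.0 + thin.k_coop * a / n_ov)
    deact = thin.k_off * (a - cb) * (1.0 + thin.k_coop * (n_ov - a) / n_ov)
    return act - deact


def _attach_weights(f: np.ndarray) -> np.ndarray:
    """Per-bin attachment kernel f_i * w_i with w = f / sum(f).

    New attachments are distributed over strain bins by the normalized f
    profile; weighting f by w keeps the bin-summed flux invariant under grid
    refinement (it converges to int f^2 / int f) and collapses to the plain
    two-state attachment rate when the grid has a single bin.
    """
    total = f.sum()
    if total <= 0:
        return np.zeros_like(f)
    return f * f / total


def myosin_derivatives(
    state: FibreState, xb: CrossBridgeParams, grid: StrainGrid
) -> tuple[np.ndarray, float]:
    """Time derivatives of the bound distribution and the detached pool.

    Attachment draws on the detached pool in proportion to the free activated
    actin (actin_activated - cb_attached), distributed over strain bins by the
    normalised attachment profile; detachment empties each bin at g(dx).
    Returns (d bound/dt per bin, d detached/dt); the pair sums to zero.
    """
    a = state.actin_activated
    cb = state.cb_attached
    if cb > a + 1e-12:
        raise StateCorruptionError("cb_attached exceeds actin_activated")
    avail = max(a - cb, 0.0)
    x = grid.bin_centres
    fw = _attach_weights(attachment_rate(x, xb))
    g = detachment_rate(x, xb)
    dbound = fw * (state.detached * avail) - g * state.bound_myosin
    return dbound, -float(dbound.sum())


def stress(state: FibreState, params: FibreParams, grid: StrainGrid) -> float:
    """Half-sarcomere stress (N m^-2): cross-bridge springs + passive element.

    The passive term is signed linear in length and may be negative below the
    slack length; no clipping is applied.
    """
    xb = params.xb
    cb_term = (
        _STRAIN_NM_TO_M
        * xb.cb_density
        * xb.cb_stiffness
        * float(
            np.dot(grid.bin_centres, state.bound_myosin)
            + state.strain_offset * state.cb_attached
        )
    )
    passive = params.passive.passive_stiffness * (
        state.hs_length - params.passive.length_slack
    )
    return cb_term + passive


# ---------------------------------------------------------------------------
# time stepping
# ---------------------------------------------------------------------------


def _advect_exact(
    b: np.ndarray, delta: float, shift: float, bin_width: float
) -> tuple[np.ndarray, float]:
    """Translate the bound distribution by ``shift`` nm without diffusion.

    The sub-bin part of the displacement is accumulated in ``delta`` (the
    strain offset of the whole grid); whenever it exceeds half a bin the
    distribution is rolled by whole bins.  Mass rolled past either grid edge
    is dropped from the bound pool (those bridges are treated as forcibly
    detached); translation is otherwise exact.
    """
    delta += shift
    k = int(np.floor(delta / bin_width + 0.5))
    delta -= k * bin_width
    if k == 0:
        return b, delta
    n = b.shape[0]
    out = np.zeros_like(b)
    if k > 0:
        if k < n:
            out[k:] = b[: n - k]
    else:
        if -k < n:
            out[: n + k] = b[-k:]
    return out, delta


def advance(
    state: FibreState,
    dt: float,
    next_length: float,
    ca: float,
    params: FibreParams,
    grid: StrainGrid,
    overflow_tol: float = 1e-6,
) -> FibreState:
    """One operator-split step of the half-sarcomere engine.

    Sub-step 1 (kinetics, at the current length): explicit Euler for the actin
    fraction, then exact exponential relaxation of each strain bin towards its
    attachment/detachment balance.  Sub-step 2 (advection): every attached
    bridge's strain increases by the imposed length change
    ``next_length - hs_length``, applied as an exact lazy-rolled translation
    of the distribution.
    """
    if dt <= 0:
        raise ValueError("dt must be > 0")
    x = grid.bin_centres + state.strain_offset  # true strains of the bins
    f = attachment_rate(x, params.xb)
    g = detachment_rate(x, params.xb)
    fw = _attach_weights(f)
    decay = np.exp(-g * dt)
    gain = np.where(g > 0, (1.0 - decay) / np.where(g > 0, g, 1.0), dt)

    a = state.actin_activated
    cb = state.cb_attached
    a = a + dt * actin_derivative(state, params.thin, ca, params.geometry)
    avail = max(a - cb, 0.0)
    b = state.bound_myosin * decay + fw * ((1.0 - cb) * avail) * gain
    b, delta = _advect_exact(
        b, state.strain_offset, next_length - state.hs_length, grid.bin_width
    )
    if max(b[0], b[-1]) > overflow_tol:
        raise GridOverflowError(
            f"edge-bin occupancy {max(b[0], b[-1]):.3e} exceeds {overflow_tol:.1e}"
        )
    return FibreState(
        time=state.time + dt,
        hs_length=next_length,
        actin_activated=a,
        bound_myosin=b,
        strain_offset=delta,
    )


def _run_loop(
    lengths,
    ca,
    dt,
    x,
    bw,
    f_slope,
    f_decay,
    g_offset,
    g_below,
    g_above,
    g_break,
    k_on,
    k_off,
    k_coop,
    l_thin,
    l_thick,
    l_bare,
    cb_scale,
    k_pass,
    l_slack,
    a0,
    b0,
    delta0,
    snap_stride,
):
    """Batch version of `advance` over a whole protocol (numba-friendly).

    Must stay arithmetic-identical to `advance`; the equivalence is enforced
    by a regression test.
    """
    n = lengths.shape[0]
    nb = b0.shape[0]
    a = a0
    b = b0.copy()
    delta = delta0
    a_out = np.empty(n)
    cb_out = np.empty(n)
    stress_out = np.empty(n)
    edge_max = 0.0
    denom = l_thick - l_bare
    n_snaps = (n - 1) // snap_stride + 1 if snap_stride > 0 else 0
    snaps = np.zeros((n_snaps, nb))
    # rate tables at the true bin strains x + delta; rebuilt when delta moves
    rate_delta = np.inf
    fw = np.zeros(nb)
    decay = np.zeros(nb)
    gain = np.zeros(nb)
    for i in range(n):
        if delta != rate_delta:
            xs = x + delta
            f = f_slope * np.exp(-f_decay * xs * xs)
            sf = f.sum()
            if sf > 0.0:
                fw = f * f / sf
            else:
                fw = f * 0.0
            dd = xs - g_break
            g = g_offset + np.where(
                dd >= 0.0, g_above * dd**3, g_below * np.abs(dd) ** 3
            )
            decay = np.exp(-g * dt)
            gain = np.where(g > 0.0, (1.0 - decay) / np.where(g > 0.0, g, 1.0), dt)
            rate_delta = delta
        length = lengths[i]
        cb = b.sum()
        a_out[i] = a
        cb_out[i] = cb
        stress_out[i] = cb_scale * (np.dot(x, b) + delta * cb) + k_pass * (
            length - l_slack
        )
        if snap_stride > 0 and i % snap_stride == 0:
            snaps[i // snap_stride] = b
        if i == n - 1:
            break
        # --- kinetics sub-step at the current length
        n_ov = (l_thin - (length - l_thick)) / denom
        if n_ov < 0.0:
            n_ov = 0.0
        elif n_ov > 1.0:
            n_ov = 1.0
        if n_ov <= 0.0:
            da = -k_off * (a - cb)
        else:
            da = k_on * ca[i] * (n_ov - a) * (1.0 + k_coop * a / n_ov) - k_off * (
                a - cb
            ) * (1.0 + k_coop * (n_ov - a) / n_ov)
        a = a + dt * da
        avail = a - cb
        if avail < 0.0:
            avail = 0.0
        b = b * decay + fw * ((1.0 - cb) * avail) * gain
        # --- advection sub-step to the next imposed length (exact roll)
        delta += lengths[i + 1] - length
        kk = int(np.floor(delta / bw + 0.5))
        delta -= kk * bw
        if kk != 0:
            nb_arr = np.zeros(nb)
            if kk > 0:
                if kk < nb:
                    nb_arr[kk:] = b[: nb - kk]
            else:
                if -kk < nb:
                    nb_arr[: nb + kk] = b[-kk:]
            b = nb_arr
        e = b[0] if b[0] > b[nb - 1] else b[nb - 1]
        if e > edge_max:
            edge_max = e
    return a_out, cb_out, stress_out, b, delta, edge_max, snaps


if _HAVE_NUMBA:
    _run_loop_jit = _njit(cache=False)(_run_loop)
else:  # pragma: no cover
    _run_loop_jit = _run_loop


@dataclass
class FibreTrace:
    """Recorded time course of one fibre simulation."""

    time: np.ndarray
    hs_length: np.ndarray
    ca: np.ndarray
    actin_activated: np.ndarray
    cb_attached: np.ndarray
    stress: np.ndarray
    n_overlap: np.ndarray
    bound_final: np.ndarray
    strain_offset_final: float
    edge_max: float
    params: FibreParams
    grid: StrainGrid
    snapshot_times: Optional[np.ndarray] = None
    bound_snapshots: Optional[np.ndarray] = None

    @property
    def dt(self) -> float:
        return float(self.time[1] - self.time[0])

    @property
    def final_state(self) -> FibreState:
        return FibreState(
            time=float(self.time[-1]),
            hs_length=float(self.hs_length[-1]),
            actin_activated=float(self.actin_activated[-1]),
            bound_myosin=self.bound_final.copy(),
            strain_offset=self.strain_offset_final,
        )


def simulate(
    lengths: np.ndarray,
    ca,
    dt: float,
    params: FibreParams,
    grid: Optional[StrainGrid] = None,
    initial_state: Optional[FibreState] = None,
    overflow_tol: float = 1e-6,
    snapshot_stride: int = 0,
    t0: float = 0.0,
) -> FibreTrace:
    """Run the half-sarcomere engine over a uniformly sampled length series.

    Parameters
    ----------
    lengths
        Imposed half-sarcomere length (nm) at each sample, spacing ``dt``.
    ca
        Calcium concentration (molar), scalar or per-sample array.
    params, grid
        Fibre parameters and strain grid (defaults to the shipped grid).
    initial_state
        Continuation state; defaults to rest (zero activation, zero bound).
    overflow_tol
        Maximum tolerated occupancy of the outermost strain bins; exceeding it
        raises :class:`GridOverflowError` (the grid was too narrow).
    snapshot_stride
        If > 0, store the full bound distribution every that many samples.
    """
    if dt <= 0:
        raise ValueError("dt must be > 0")
    grid = grid or StrainGrid()
    if not (grid.lower_bound < params.xb.detach_breakpoint < grid.upper_bound):
        raise InvalidParameterError(
            "the detachment breakpoint must lie inside the strain grid"
        )
    lengths = np.ascontiguousarray(lengths, dtype=float)
    n = lengths.shape[0]
    ca_arr = np.broadcast_to(np.asarray(ca, dtype=float), (n,))
    ca_arr = np.ascontiguousarray(ca_arr)
    if initial_state is None:
        initial_state = FibreState(
            t0, lengths[0], 0.0, np.zeros(grid.n_bins)
        )
    if initial_state.bound_myosin.shape[0] != grid.n_bins:
        raise InvalidParameterError("initial state does not match the grid")

    xb = params.xb
    a_out, cb_out, stress_out, b_final, delta_final, edge_max, snaps = _run_loop_jit(
        lengths,
        ca_arr,
        dt,
        grid.bin_centres,
        grid.bin_width,
        xb.attach_slope,
        xb.cb_stiffness / xb.const_f,
        xb.detach_offset + xb.detach_extra_offset,
        xb.detach_coeff_below,
        xb.detach_coeff_above,
        xb.detach_breakpoint,
        params.thin.k_on,
        params.thin.k_off,
        params.thin.k_coop,
        params.geometry.length_thin_filament,
        params.geometry.length_thick_filament,
        params.geometry.length_bare_zone,
        _STRAIN_NM_TO_M * params.xb.cb_density * params.xb.cb_stiffness,
        params.passive.passive_stiffness,
        params.passive.length_slack,
        float(initial_state.actin_activated),
        np.ascontiguousarray(initial_state.bound_myosin, dtype=float),
        float(initial_state.strain_offset),
        snapshot_stride,
    )
    if edge_max > overflow_tol:
        raise GridOverflowError(
            f"edge-bin occupancy {edge_max:.3e} exceeds {overflow_tol:.1e}; "
            "widen the strain grid"
        )
    time = t0 + dt * np.arange(n)
    trace = FibreTrace(
        time=time,
        hs_length=lengths,
        ca=ca_arr,
        actin_activated=a_out,
        cb_attached=cb_out,
        stress=stress_out,
        n_overlap=filament_overlap(lengths, params.geometry),
        bound_final=b_final,
        strain_offset_final=float(delta_final),
        edge_max=float(edge_max),
        params=params,
        grid=grid,
    )
    if snapshot_stride > 0:
        trace.snapshot_times = time[::snapshot_stride]
        trace.bound_snapshots = snaps
    return trace


# ---------------------------------------------------------------------------
# trace container i/o
# ---------------------------------------------------------------------------


def save_trace(path, trace: FibreTrace) -> None:
    """Write a fibre trace to an HDF5 container."""
    import h5py

    with h5py.File(path, "w") as h5:
        h5.attrs["label"] = trace.params.label
        h5.attrs["dt"] = trace.dt
        h5.attrs["edge_max"] = trace.edge_max
        for name in ("time", "hs_length", "ca", "actin_activated", "cb_attached", "stress", "n_overlap"):
            h5.create_dataset(name, data=getattr(trace, name))
        h5.create_dataset("bound_final", data=trace.bound_final)
        h5.create_dataset("strain_bins", data=trace.grid.bin_centres)
        if trace.bound_snapshots is not None:
            h5.create_dataset("snapshot_times", data=trace.snapshot_times)
            h5.create_dataset("bound_snapshots", data=trace.bound_snapshots)


def load_trace(path) -> dict:
    """Read back the arrays written by :func:`save_trace` as a dict."""
    import h5py

    out = {}
    with h5py.File(path, "r") as h5:
        for key in h5.keys():
            out[key] = np.asarray(h5[key])
        out.update({k: h5.attrs[k] for k in h5.attrs})
    return out
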