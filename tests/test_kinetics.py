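"""Half-sarcomere engine: rate laws, oracles, conservation, stepping."""

from __future__ import annotations

from dataclasses import replace

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.integrate import solve_ivp

import spindlesim as ss
from spindlesim import kinetics as kin


GEO = kin.FilamentGeometry()


class TestPcaToMolar:
    @pytest.mark.parametrize(
        "pca, molar",
        [(6.4, 10**-6.4), (9.0, 1e-9), (4.5, 10**-4.5)],
    )
    def test_definition(self, pca, molar):
        assert kin.pca_to_molar(pca) == pytest.approx(molar, rel=1e-12)

    def test_rejects_nonpositive(self):
        with pytest.raises(kin.InvalidParameterError):
            kin.pca_to_molar(0.0)


class TestFilamentOverlap:
    @pytest.mark.parametrize(
        "length, expected",
        [
            (1300.0, 635.0 / 735.0),  # resting length with default geometry
            (1200.0, 1.0),  # numerator equals denominator
            (1935.0, 0.0),  # thin filament fully cleared
            (1100.0, 1.0),  # clamped above
            (2200.0, 0.0),  # clamped below
        ],
    )
    def test_values(self, length, expected):
        assert kin.filament_overlap(length, GEO) == pytest.approx(expected, abs=1e-12)

    def test_bad_geometry_rejected(self):
        with pytest.raises(kin.InvalidParameterError):
            kin.FilamentGeometry(length_bare_zone=900.0)

    def test_nonpositive_length_rejected(self):
        with pytest.raises(kin.InvalidParameterError):
            kin.filament_overlap(-1.0, GEO)


class TestRateFunctions:
    def test_attachment_peak_is_slope(self, bag_params):
        assert kin.attachment_rate(0.0, bag_params.xb) == pytest.approx(600.0)

    def test_attachment_is_even(self, bag_params):
        x = np.linspace(0.1, 20.0, 40)
        np.testing.assert_allclose(
            kin.attachment_rate(x, bag_params.xb),
            kin.attachment_rate(-x, bag_params.xb),
            rtol=1e-12,
        )

    def test_attachment_efold_width(self, bag_params):
        # 1/e point at sqrt(const_f / cb_stiffness) = sqrt(72) nm
        x = np.sqrt(bag_params.xb.const_f / bag_params.xb.cb_stiffness)
        assert x == pytest.approx(8.4853, abs=1e-3)
        assert kin.attachment_rate(x, bag_params.xb) == pytest.approx(600.0 / np.e)

    def test_detachment_minimum_at_breakpoint(self, bag_params, chain_params):
        assert kin.detachment_rate(-5.0, bag_params.xb) == pytest.approx(7.0 + 0.5)
        assert kin.detachment_rate(-5.0, chain_params.xb) == pytest.approx(300.0 + 10.0)

    def test_detachment_above_branch_value(self, bag_params):
        # 0.3 * 5^3 above the breakpoint evaluated at zero strain
        assert kin.detachment_rate(0.0, bag_params.xb) == pytest.approx(7.0 + 37.5 + 0.5)

    def test_detachment_nondecreasing_above_breakpoint(self, bag_params):
        x = np.linspace(-5.0, 25.0, 200)
        g = kin.detachment_rate(x, bag_params.xb)
        assert np.all(np.diff(g) >= 0)

    def test_detachment_u_shaped_below_breakpoint(self, bag_params):
        x = np.linspace(-40.0, -5.0, 200)
        g = kin.detachment_rate(x, bag_params.xb)
        assert np.all(np.diff(g) <= 0)
        assert np.all(g >= 0)


class TestActinDerivative:
    thin0 = kin.ThinFilamentParams(k_coop=0.0)

    def _state(self, a, cb_bin=0.0):
        grid = kin.StrainGrid()
        b = np.zeros(grid.n_bins)
        b[grid.n_bins // 2] = cb_bin
        return kin.FibreState(0.0, 1300.0, a, b)

    def test_pure_deactivation(self):
        n_ov = kin.filament_overlap(1300.0, GEO)
        state = self._state(n_ov)
        d = kin.actin_derivative(state, self.thin0, 0.0, GEO)
        assert d == pytest.approx(-self.thin0.k_off * n_ov, rel=1e-12)

    def test_steady_state_matches_closed_form(self):
        # dA/dt = 0 at A* = n * kon Ca / (kon Ca + koff) without cooperativity
        ca = kin.pca_to_molar(6.4)
        n_ov = kin.filament_overlap(1300.0, GEO)
        a_star = n_ov * self.thin0.k_on * ca / (self.thin0.k_on * ca + self.thin0.k_off)
        assert a_star == pytest.approx(0.1187, abs=2e-4)
        d = kin.actin_derivative(self._state(a_star), self.thin0, ca, GEO)
        assert d == pytest.approx(0.0, abs=1e-9)

    def test_bound_myosin_blocks_deactivation(self):
        n_ov = kin.filament_overlap(1300.0, GEO)
        state = self._state(n_ov, cb_bin=n_ov)  # A = cb = n_overlap
        for k_off in (0.0, 200.0, 5000.0):
            thin = kin.ThinFilamentParams(k_off=k_off, k_coop=0.0)
            assert kin.actin_derivative(state, thin, 0.0, GEO) == pytest.approx(0.0)

    def test_corrupt_state_rejected(self):
        state = self._state(0.1, cb_bin=0.5)
        with pytest.raises(kin.StateCorruptionError):
            kin.actin_derivative(state, self.thin0, 0.0, GEO)


class TestMyosinDerivatives:
    def test_empty_state_is_static(self, bag_params):
        grid = kin.StrainGrid()
        state = kin.FibreState(0.0, 1300.0, 0.0, np.zeros(grid.n_bins))
        dbound, ddet = kin.myosin_derivatives(state, bag_params.xb, grid)
        assert np.all(dbound == 0.0)
        assert ddet == 0.0

    def test_conservation_by_construction(self, bag_params):
        grid = kin.StrainGrid()
        rng = np.random.default_rng(0)
        b = rng.uniform(0, 0.002, grid.n_bins)
        state = kin.FibreState(0.0, 1300.0, 0.6, b)
        dbound, ddet = kin.myosin_derivatives(state, bag_params.xb, grid)
        assert dbound.sum() + ddet == pytest.approx(0.0, abs=1e-12)


def _flat_rates(f0: float, g0: float) -> kin.CrossBridgeParams:
    """Near-delta attachment window at zero strain, constant detachment g0."""
    return kin.CrossBridgeParams(
        attach_slope=f0,
        detach_offset=g0,
        detach_extra_offset=0.0,
        detach_coeff_below=0.0,
        detach_coeff_above=0.0,
        detach_breakpoint=-0.5,
        cb_stiffness=100.0,  # exponent ~ -347 one bin away: single-bin window
    )


class TestSingleBinOracle:
    """Engine vs the scalar two-state model on an effectively single-bin grid."""

    f0, g0, a_level = 50.0, 30.0, 0.6

    def _params(self):
        return kin.FibreParams(
            label="toy",
            thin=kin.ThinFilamentParams(k_on=0.0, k_off=0.0, k_coop=0.0),
            xb=_flat_rates(self.f0, self.g0),
            passive=kin.PassiveParams(passive_stiffness=0.0, length_slack=1300.0),
        )

    def _run(self, t_end, dt=1e-4):
        grid = kin.StrainGrid(-1.0, 1.0, 0.5)
        params = self._params()
        n = int(round(t_end / dt)) + 1
        init = kin.FibreState(0.0, 1300.0, self.a_level, np.zeros(grid.n_bins))
        return kin.simulate(
            np.full(n, 1300.0), 0.0, dt, params, grid=grid, initial_state=init
        )

    def test_steady_state_matches_closed_form(self):
        """Fixed point f0*(1-b)*(A-b) = g0*b, i.e. b = f0*a/(f0*a + g0) with
        a = A - b the available actin, solved analytically as a quadratic."""
        f0, g0, A = self.f0, self.g0, self.a_level
        p = f0 * (1 + A) + g0
        b_star = (p - np.sqrt(p * p - 4 * f0 * f0 * A)) / (2 * f0)
        a = A - b_star
        assert b_star == pytest.approx(f0 * a / (f0 * a + g0), rel=1e-12)
        trace = self._run(2.0)
        assert trace.cb_attached[-1] == pytest.approx(b_star, rel=1e-6)

    def test_transient_matches_ode_solution(self):
        """Trajectory against a high-accuracy integration of the scalar ODE
        db/dt = f0*(1-b)*(A-b) - g0*b (agreement at the splitting-error level)."""
        f0, g0, A = self.f0, self.g0, self.a_level
        sol = solve_ivp(
            lambda t, b: f0 * (1 - b) * (A - b) - g0 * b,
            (0.0, 0.1),
            [0.0],
            t_eval=np.linspace(0, 0.1, 11),
            rtol=1e-11,
            atol=1e-13,
        )
        trace = self._run(0.1)
        engine = np.interp(sol.t, trace.time, trace.cb_attached)
        np.testing.assert_allclose(engine, sol.y[0], rtol=3e-3, atol=1e-9)


class TestAdvance:
    def test_isometric_steady_state_is_fixed_point(self, bag_params, config):
        n = int(3.0 / config.dt) + 1
        trace = kin.simulate(
            np.full(n, 1300.0), kin.pca_to_molar(6.4), config.dt, bag_params,
            grid=config.grid,
        )
        state = trace.final_state
        nxt = kin.advance(state, config.dt, 1300.0, kin.pca_to_molar(6.4),
                          bag_params, config.grid)
        assert nxt.actin_activated == pytest.approx(state.actin_activated, abs=1e-8)
        s0 = kin.stress(state, bag_params, config.grid)
        s1 = kin.stress(nxt, bag_params, config.grid)
        assert s1 == pytest.approx(s0, rel=1e-6)

    def test_single_cohort_advection_oracle(self):
        """A lone bound cohort shifted +2 nm with all rates off: the stress
        changes by exactly the cross-bridge term at strain +2 nm."""
        grid = kin.StrainGrid()
        params = kin.FibreParams(
            label="toy",
            thin=kin.ThinFilamentParams(k_on=0.0, k_off=0.0, k_coop=0.0),
            xb=kin.CrossBridgeParams(
                attach_slope=0.0, detach_offset=0.0, detach_extra_offset=0.0,
                detach_coeff_below=0.0, detach_coeff_above=0.0,
            ),
            passive=kin.PassiveParams(passive_stiffness=0.0, length_slack=1300.0),
        )
        b = np.zeros(grid.n_bins)
        i0 = int(round(-grid.lower_bound / grid.bin_width))
        assert grid.bin_centres[i0] == 0.0
        b[i0] = 0.1
        state = kin.FibreState(0.0, 1300.0, 0.5, b)
        nxt = kin.advance(state, 1e-4, 1302.0, 0.0, params, grid)
        assert nxt.cb_attached == pytest.approx(0.1, abs=1e-15)
        assert nxt.bound_myosin[i0 + 4] == pytest.approx(0.1)
        expected = 1e-9 * params.xb.cb_density * params.xb.cb_stiffness * 2.0 * 0.1
        assert kin.stress(nxt, params, grid) == pytest.approx(expected, rel=1e-12)

    def test_mass_conserved_up_to_edge_loss(self, bag_params, config):
        ca = kin.pca_to_molar(6.4)
        state = kin.FibreState(0.0, 1300.0, 0.0, np.zeros(config.grid.n_bins))
        for i in range(200):
            state = kin.advance(state, 1e-4, 1300.0 + 0.05 * i, ca, bag_params,
                                config.grid)
            assert state.cb_attached <= 1.0 + 1e-12
            assert np.all(state.bound_myosin >= 0.0)
            # attached + detached is one by construction of the state
            assert state.cb_attached + state.detached == pytest.approx(1.0, abs=1e-12)

    def test_simulate_equals_repeated_advance(self, bag_params, config):
        protocol = ss.ramp_hold(36.0, 5.6).resample(config.dt)
        lengths = protocol.hs_length[19900:20200]
        ca = kin.pca_to_molar(6.4)
        trace = kin.simulate(lengths, ca, config.dt, bag_params, grid=config.grid)
        state = kin.FibreState(0.0, lengths[0], 0.0, np.zeros(config.grid.n_bins))
        for i in range(len(lengths) - 1):
            state = kin.advance(state, config.dt, lengths[i + 1], ca, bag_params,
                                config.grid)
        assert state.actin_activated == pytest.approx(
            trace.actin_activated[-1], abs=1e-12
        )
        np.testing.assert_allclose(
            state.bound_myosin, trace.bound_final, atol=1e-14
        )

    def test_grid_overflow_raises(self, bag_params):
        tiny = kin.StrainGrid(-6.0, 3.0, 0.5)
        protocol = ss.ramp_hold(36.0, 5.6).resample(1e-4)
        with pytest.raises(kin.GridOverflowError):
            kin.simulate(protocol.hs_length, kin.pca_to_molar(6.4), 1e-4,
                         bag_params, grid=tiny)


class TestStress:
    def test_zero_at_slack_with_no_bridges(self, bag_params):
        grid = kin.StrainGrid()
        state = kin.FibreState(0.0, 1050.0, 0.0, np.zeros(grid.n_bins))
        assert kin.stress(state, bag_params, grid) == 0.0

    @pytest.mark.parametrize(
        "fibre, expected", [("bag", 90.0 * 250.0), ("chain", 250.0 * 100.0)]
    )
    def test_passive_term_at_resting_length(self, fibre, expected):
        params = getattr(kin.FibreParams, fibre)()
        grid = kin.StrainGrid()
        state = kin.FibreState(0.0, 1300.0, 0.0, np.zeros(grid.n_bins))
        assert kin.stress(state, params, grid) == pytest.approx(expected)

    def test_signed_below_slack(self, bag_params):
        grid = kin.StrainGrid()
        state = kin.FibreState(0.0, 1000.0, 0.0, np.zeros(grid.n_bins))
        assert kin.stress(state, bag_params, grid) == pytest.approx(90.0 * -50.0)


class TestOrderingInvariant:
    def test_cb_le_actin_le_overlap_through_paired_triangles(self, paired_result):
        _, res = paired_result
        for trace in (res.bag, res.chain):
            assert np.all(trace.cb_attached <= trace.actin_activated + 1e-9)
            assert np.all(trace.actin_activated <= trace.n_overlap + 1e-9)
            assert np.all(trace.cb_attached >= -1e-15)


@settings(max_examples=30, deadline=None, derandomize=True)
@given(
    shift=st.floats(-3.0, 3.0, allow_nan=False),
    delta=st.floats(-0.24, 0.24),
    seed=st.integers(0, 2**16),
)
def test_exact_advection_conserves_interior_mass(shift, delta, seed):
    """Translation conserves total bound mass whenever no mass is rolled past
    a grid edge, and never produces negative occupancies."""
    rng = np.random.default_rng(seed)
    b = np.zeros(41)
    b[12:29] = rng.uniform(0, 0.01, 17)  # keep well clear of the edges
    out, new_delta = kin._advect_exact(b, delta, shift, 0.5)
    assert out.sum() == pytest.approx(b.sum(), abs=1e-15)
    assert np.all(out >= 0.0)
    assert abs(new_delta) <= 0.25 + 1e-12


class TestTraceIO:
    def test_hdf5_round_trip(self, bag_params, config, tmp_path):
        n = 2001
        trace = kin.simulate(
            np.full(n, 1300.0), kin.pca_to_molar(6.4), config.dt, bag_params,
            grid=config.grid, snapshot_stride=1000,
        )
        path = tmp_path / "trace.h5"
        kin.save_trace(path, trace)
        back = kin.load_trace(path)
        np.testing.assert_allclose(back["stress"], trace.stress)
        np.testing.assert_allclose(back["bound_final"], trace.bound_final)
        assert back["label"] == "bag"
        assert back["bound_snapshots"].shape[0] == 3
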