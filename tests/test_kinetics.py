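"""Well-mixed kinetics: stoichiometry, conservation, steady states, phases."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from actocap.kinetics import (SPECIES, _IDX, ConvergenceError, GrowthPhases,
                              Trajectory, build_network, detect_phases,
                              integrate_wellmixed, steady_state)
from actocap.params import Concentrations, Geometry, ParameterError, RateParams


class TestNetworkConstruction:
    def test_negative_rate_rejected(self):
        with pytest.raises(ParameterError):
            RateParams(k_cap=-1.0)

    def test_regeneration_slower_than_activation(self):
        with pytest.raises(ParameterError):
            RateParams(k_regen=0.1, k_act=0.01)

    def test_unknown_reservoir_mode(self, rates, geometry):
        with pytest.raises(ValueError):
            build_network(rates, geometry, "bogus")

    def test_infinite_mode_clamps_bulk_reservoirs(self, rates, geometry):
        """Reservoir species must have zero net stoichiometry in every
        reaction when the pools are infinite."""
        net = build_network(rates, geometry, "infinite")
        for sp in ("G", "CP_free", "Arp_inactive"):
            assert np.all(net.S[_IDX[sp], :] == 0.0)

    def test_finite_mode_conserves_actin_symbolically(self, rates, geometry):
        """Column sums of the actin-carrying rows vanish: monomers moved
        out of G always land in P or VCA·G (symbolic stoichiometry check)."""
        net = build_network(rates, geometry, "finite")
        actin_rows = (net.S[_IDX["G"]] + net.S[_IDX["P"]]
                      + net.conv * net.S[_IDX["VCA_G"]])
        assert np.allclose(actin_rows, 0.0, atol=1e-15)
        cp_rows = net.S[_IDX["CP_free"]] + net.conv * net.S[_IDX["B_capped"]]
        assert np.allclose(cp_rows, 0.0, atol=1e-15)

    def test_no_branching_gives_linear_growth_before_capping(self, geometry):
        """With k_branch=0 and CP=0 the barbed-end count grows without
        autocatalysis: dB/dt = eta*k_seed*Arp*, so B is linear in time once
        Arp* has plateaued."""
        p = RateParams(k_branch=0.0, k_seed=1e-3, eta_seed_membrane=1.0,
                       k_act=5.0, k_bind_VG=10.0)
        net = build_network(p, geometry, "infinite")
        conc = Concentrations(cp_nM=0.0)
        t = np.linspace(0.0, 400.0, 201)
        traj = integrate_wellmixed(net, net.initial_state(conc), t)
        # after the activation transient Arp* is quasi-steady
        late = t >= 200.0
        dBdt = np.gradient(traj.B, t)[late]
        assert dBdt.std() / dBdt.mean() < 0.05


class TestIntegration:
    def test_no_capping_consumes_monomers_to_critical(self, rates, geometry):
        """CP=0: B never decreases and the pool polymerizes down to the
        critical concentration (P = A_tot − c_crit − monomers held by VCA)."""
        net = build_network(rates, geometry, "finite")
        conc = Concentrations(cp_nM=0.0)
        t = np.linspace(0.0, 4000.0, 801)
        traj = integrate_wellmixed(net, net.initial_state(conc), t)
        assert np.all(np.diff(traj.B) >= -1e-8 * traj.B.max())
        expected_P = (conc.actin_uM - rates.c_crit
                      - net.conv * traj["VCA_G"][-1])
        assert traj["P"][-1] == pytest.approx(expected_P, rel=1e-3)

    def test_no_actin_no_barbed_ends(self, rates, geometry):
        net = build_network(rates, geometry, "finite")
        conc = Concentrations(actin_uM=0.0)
        t = np.linspace(0.0, 100.0, 101)
        traj = integrate_wellmixed(net, net.initial_state(conc), t)
        assert np.all(traj.B == 0.0)
        assert np.all(traj["P"] == 0.0)

    def test_conservation_and_nonnegativity(self, rates, geometry,
                                            t_grid_5min):
        """Finite-pool runs close all four conservation laws to 1e-6
        relative and keep every species non-negative."""
        for cp in (40.0, 120.0):
            net = build_network(rates, geometry, "finite")
            traj = integrate_wellmixed(
                net, net.initial_state(Concentrations(cp_nM=cp)), t_grid_5min)
            assert np.all(traj.states >= 0.0)
            for law, resid in traj.conservation_residuals().items():
                assert resid < 1e-6, law

    def test_steady_B_ordering_under_cp(self, rates, geometry):
        """Infinite pools: more CP means a lower barbed-end plateau."""
        finals = []
        t = np.linspace(0.0, 2000.0, 401)
        for cp in (40.0, 80.0, 120.0):
            net = build_network(rates, geometry, "infinite")
            traj = integrate_wellmixed(
                net, net.initial_state(Concentrations(cp_nM=cp)), t)
            finals.append(traj.B[-1])
        assert finals[0] > finals[1] > finals[2]

    def test_trajectory_requires_increasing_times(self, rates, geometry):
        net = build_network(rates, geometry, "finite")
        with pytest.raises(ValueError):
            Trajectory(np.array([0.0, 1.0, 1.0]), np.zeros((3, 10)), net)


class TestSteadyState:
    def test_absorbing_state_without_seeding(self, geometry):
        # k_regen=0 so the activation flux also dies out: with no seeding
        # and B(0)=0 the barbed-end state is absorbing at zero
        p = RateParams(k_seed=0.0, k_regen=0.0)
        net = build_network(p, geometry, "infinite")
        ss = steady_state(net, net.initial_state(Concentrations(cp_nM=80.0)))
        assert ss.B == pytest.approx(0.0, abs=1e-9)

    def test_requires_infinite_mode(self, rates, geometry, paper_mix):
        net = build_network(rates, geometry, "finite")
        with pytest.raises(ValueError):
            steady_state(net, net.initial_state(paper_mix))

    def test_monotone_in_cp(self, rates, geometry):
        """Steady-state barbed ends strictly decrease and Arp* strictly
        increases over a five-point CP sweep."""
        B, A = [], []
        for cp in (40.0, 60.0, 80.0, 100.0, 120.0):
            net = build_network(rates, geometry, "infinite")
            ss = steady_state(net, net.initial_state(Concentrations(cp_nM=cp)))
            B.append(ss.B)
            A.append(ss.Arp_star)
        assert all(b1 > b2 for b1, b2 in zip(B, B[1:]))
        assert all(a1 < a2 for a1, a2 in zip(A, A[1:]))

    def test_agrees_with_long_time_integration(self, rates, geometry):
        """Fixed point equals the long-time limit of the integrator to
        1e-4 relative on the cycling species."""
        net = build_network(rates, geometry, "infinite")
        init = net.initial_state(Concentrations(cp_nM=80.0))
        ss = steady_state(net, init)
        t_long = 20.0 / rates.k_regen
        t = np.linspace(0.0, t_long, 200)
        traj = integrate_wellmixed(net, init, t, rtol=1e-10, atol=1e-12)
        for sp in ("B", "Arp_star", "VCA_free", "VCA_G", "VCA_spent"):
            ref = getattr(ss, sp)
            if abs(ref) < 1e-8:
                continue
            assert traj[sp][-1] == pytest.approx(ref, rel=1e-4), sp


class TestPhases:
    def test_saturating_curve_orders_phases(self, rates, geometry):
        """B(t) = Bmax(1 − e^{−t/τ}) has its fastest growth at t=0, so the
        initial-growth boundary collapses onto the seeding boundary and the
        ordering invariant still holds."""
        net = build_network(rates, geometry, "finite")
        t = np.linspace(0.0, 100.0, 2001)
        B = 50.0 * (1.0 - np.exp(-t / 5.0))
        states = np.zeros((len(t), len(SPECIES)))
        states[:, _IDX["B"]] = B
        ph = detect_phases(Trajectory(t, states, net))
        assert 0.0 <= ph.t_seed_end <= ph.t_initial_end <= ph.t_transient_end
        assert ph.steady_reached
        assert ph.t_initial_end < 1.0

    def test_piecewise_linear_breakpoints_recovered(self, rates, geometry):
        """Synthetic seed/rise/plateau curve: recovered boundaries within
        one grid step of the construction breakpoints."""
        net = build_network(rates, geometry, "finite")
        dt = 0.25
        t = np.arange(0.0, 100.0 + dt, dt)
        t1, t2 = 20.0, 60.0          # rise starts / plateau starts
        B = np.piecewise(
            t, [t < t1, (t >= t1) & (t < t2), t >= t2],
            [lambda x: 0.01 * x / t1,
             lambda x: 0.01 + (x - t1) * (100.0 - 0.01) / (t2 - t1),
             100.0])
        ph = detect_phases(Trajectory(t, states_with_B(B), net))
        assert ph.t_seed_end == pytest.approx(t1, abs=5 * dt + t1 * 0.01)
        assert t1 <= ph.t_initial_end <= t2
        assert ph.t_transient_end == pytest.approx(t2, abs=1.0)

    def test_finite_pool_overshoot_at_80nM(self, rates, geometry,
                                           t_grid_5min):
        """At 80 nM CP the finite-pool barbed-end maximum lies above the
        final (steady) level: the transient overshoot of the growth."""
        net = build_network(rates, geometry, "finite")
        traj = integrate_wellmixed(
            net, net.initial_state(Concentrations(cp_nM=80.0)), t_grid_5min)
        i_pk = int(np.argmax(traj.B))
        assert 0 < i_pk < len(traj.times) - 1
        assert traj.B[i_pk] > 1.5 * traj.B[-1]

    def test_seeding_later_at_higher_cp(self, rates, geometry):
        """Time to 5% of the barbed-end maximum increases with CP."""
        lags = []
        t = np.linspace(0.0, 300.0, 1201)
        for cp in (40.0, 60.0, 80.0, 100.0, 120.0):
            net = build_network(rates, geometry, "infinite")
            traj = integrate_wellmixed(
                net, net.initial_state(Concentrations(cp_nM=cp)), t)
            lags.append(t[np.argmax(traj.B > 0.05 * traj.B.max())])
        assert all(a < b for a, b in zip(lags, lags[1:]))

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(tau=st.floats(1.0, 30.0), bmax=st.floats(0.1, 500.0),
           power=st.integers(1, 4))
    def test_ordering_invariant_on_sigmoids(self, rates, tau, bmax, power):
        """Phase boundaries are ordered for any smooth sigmoidal input."""
        net = build_network(rates, Geometry(), "finite")
        t = np.linspace(0.0, 40.0 * tau, 800)
        B = bmax * (1.0 - np.exp(-((t / (3 * tau)) ** power)))
        ph = detect_phases(Trajectory(t, states_with_B(B), net))
        assert ph.t_seed_end <= ph.t_initial_end
        if ph.steady_reached:
            assert ph.t_initial_end <= ph.t_transient_end


def states_with_B(B):
    states = np.zeros((len(B), len(SPECIES)))
    states[:, _IDX["B"]] = B
    return states
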