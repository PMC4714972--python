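"""Rate laws, Jacobian, and equilibrium structure of the repression ring."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import ringosc as ro
from ringosc.network import rhs_flat, jacobian_flat


class TestDilutionConversion:
    def test_definition_identity(self):
        assert ro.dilution_rate_from_time(math.log(2)) == pytest.approx(1.0)

    def test_device_range_endpoints(self):
        # 0.5/hr corresponds to ~83.2 min, inside the device's 15-85 min span
        assert ro.dilution_time_from_rate(0.5 / 60) == pytest.approx(83.18, abs=0.01)
        assert ro.dilution_rate_from_time(85.0) == pytest.approx(8.155e-3, rel=1e-3)

    def test_inverse_pair(self):
        for t_d in (5.0, 40.0, 85.0):
            assert ro.dilution_time_from_rate(ro.dilution_rate_from_time(t_d)) == pytest.approx(t_d)

    @pytest.mark.parametrize("bad", [0.0, -3.0])
    def test_nonpositive_rejected(self, bad):
        with pytest.raises(ValueError):
            ro.dilution_rate_from_time(bad)
        with pytest.raises(ValueError):
            ro.dilution_time_from_rate(bad)


class TestRingNetworkValidation:
    def test_scalar_broadcast(self, repressilator):
        assert repressilator.a.shape == (3,)
        assert repressilator.is_symmetric

    @pytest.mark.parametrize("kwargs", [
        dict(n=1), dict(a=-1.0), dict(K=0.0), dict(nu=0.5), dict(g=-1.0),
    ])
    def test_invalid_parameters_rejected(self, kwargs):
        base = dict(n=3, a=0.1, b=0.01, c=0.5, beta=0.4, K=5.0, nu=2.0)
        base.update(kwargs)
        with pytest.raises(ValueError):
            ro.RingNetwork(**base)

    def test_vector_length_must_match_n(self):
        with pytest.raises(ValueError):
            ro.RingNetwork.symmetric(3).replace(K=np.array([5.0, 5.0]))

    def test_untagged_b_zero_allowed(self):
        net = ro.RingNetwork.symmetric(3, b=0.0)
        assert np.all(net.b == 0.0)


class TestOdeRhs:
    def test_zero_state_full_transcription(self, repressilator, mu40):
        d = ro.ode_rhs(repressilator, ro.RingState.zeros(3), mu40)
        # beta * g = 0.4 * 5.0 with no repressor present
        np.testing.assert_allclose(d.r, 2.0)
        np.testing.assert_allclose(d.p, 0.0)

    @pytest.mark.parametrize("nu", [1.0, 2.0, 3.7])
    def test_half_maximal_at_K(self, nu, mu40):
        net = ro.RingNetwork.symmetric(3, nu=nu)
        state = ro.RingState(r=np.zeros(3), p=np.full(3, net.K[0]))
        d = ro.ode_rhs(net, state, mu40)
        np.testing.assert_allclose(d.r, net.beta * net.g / 2.0)

    def test_dimension_mismatch(self, repressilator, mu40):
        with pytest.raises(ValueError):
            ro.ode_rhs(repressilator, ro.RingState.zeros(4), mu40)

    def test_cyclic_wiring(self, mu40):
        # saturating only p_3 should shut off transcription of gene 1 alone
        net = ro.RingNetwork.symmetric(3)
        p = np.array([0.0, 0.0, 1e9])
        d = ro.ode_rhs(net, ro.RingState(r=np.zeros(3), p=p), mu40)
        assert d.r[0] == pytest.approx(0.0, abs=1e-6)
        assert d.r[1] == pytest.approx(2.0)
        assert d.r[2] == pytest.approx(2.0)

    @given(st.integers(0, 2 ** 31 - 1))
    @settings(max_examples=25, deadline=None)
    def test_positive_orthant_forward_invariant(self, seed):
        """Any coordinate at zero has a nonnegative time derivative."""
        rng = np.random.default_rng(seed)
        n = int(rng.integers(2, 6))
        net = ro.RingNetwork(n=n, a=rng.uniform(0.01, 0.2, n), b=rng.uniform(0.0, 0.05, n),
                             c=rng.uniform(0.1, 1.0, n), beta=rng.uniform(0.1, 1.0, n),
                             K=rng.uniform(1.0, 20.0, n), nu=rng.uniform(1.0, 4.0, n),
                             g=rng.uniform(0.0, 10.0))
        y = rng.uniform(0.0, 50.0, 2 * n)
        zero_idx = rng.integers(0, 2 * n)
        y[zero_idx] = 0.0
        dy = rhs_flat(net, y, rng.uniform(0.005, 0.15))
        assert dy[zero_idx] >= 0.0


class TestJacobian:
    def test_matches_finite_differences(self, repressilator, mu40):
        rng = np.random.default_rng(7)
        y = rng.uniform(0.5, 30.0, 6)
        J = jacobian_flat(repressilator, y, mu40)
        eps = 1e-6
        for j in range(6):
            yp, ym = y.copy(), y.copy()
            yp[j] += eps
            ym[j] -= eps
            col = (rhs_flat(repressilator, yp, mu40) - rhs_flat(repressilator, ym, mu40)) / (2 * eps)
            np.testing.assert_allclose(J[:, j], col, rtol=1e-6, atol=1e-8)

    def test_repression_coupling_zero_at_origin(self, mu40):
        net = ro.RingNetwork.symmetric(3, nu=2.0)
        J = ro.jacobian(net, ro.RingState.zeros(3), mu40)
        # dr_i/dp_{i-1} entries live at rows 0..2, columns 3..5
        assert np.all(J[:3, 3:] == 0.0)

    def test_decoupled_eigenvalues_exact(self, mu40):
        # g = 0 removes the repression coupling; the block-triangular Jacobian
        # has exactly the decay rates as eigenvalues
        net = ro.RingNetwork.symmetric(3, g=0.0)
        eig = np.linalg.eigvals(ro.jacobian(net, ro.RingState.zeros(3), mu40))
        expected = np.concatenate([-(net.a + mu40), -(net.b + mu40)])
        np.testing.assert_allclose(np.sort(eig.real), np.sort(expected), rtol=1e-12)
        np.testing.assert_allclose(eig.imag, 0.0, atol=1e-12)


class TestEquilibrium:
    def test_no_production_equilibrium_at_origin(self, mu40):
        net = ro.RingNetwork.symmetric(3, g=0.0)
        eq = ro.find_equilibrium(net, mu40)
        np.testing.assert_allclose(eq.state.to_flat(), 0.0)
        assert eq.stable

    def test_residual_below_tolerance(self, repressilator, mu40):
        eq = ro.find_equilibrium(repressilator, mu40)
        assert eq.residual < 1e-9

    def test_symmetric_ring_symmetric_equilibrium(self, repressilator, mu40):
        eq = ro.find_equilibrium(repressilator, mu40)
        assert np.ptp(eq.state.r) < 1e-9
        assert np.ptp(eq.state.p) < 1e-9

    def test_scalar_reduction_matches_vector_rootfind(self, repressilator, mu40):
        """The symmetric fixed point solves p = (c beta g)/((a+mu)(b+mu)) * K^nu/(K^nu+p^nu)."""
        from scipy.optimize import brentq
        net = repressilator
        a, b, c, beta = net.a[0], net.b[0], net.c[0], net.beta[0]
        K, nu, g = net.K[0], net.nu[0], net.g
        top = c * beta * g / ((a + mu40) * (b + mu40))
        p_scalar = brentq(lambda p: top * K ** nu / (K ** nu + p ** nu) - p, 0, top)
        eq = ro.find_equilibrium(net, mu40)
        assert eq.state.p[0] == pytest.approx(p_scalar, abs=1e-8)

    def test_odd_ring_equilibrium_unique_multistart(self):
        """Multi-start Newton from random states lands on one equilibrium (odd n)."""
        from scipy.optimize import root
        rng = np.random.default_rng(42)
        for _ in range(50):
            n = int(rng.choice([3, 5]))
            net = ro.RingNetwork(n=n, a=rng.uniform(0.02, 0.2, n), b=rng.uniform(0.001, 0.05, n),
                                 c=rng.uniform(0.1, 1.0, n), beta=rng.uniform(0.1, 1.0, n),
                                 K=rng.uniform(1.0, 20.0, n), nu=rng.uniform(1.0, 4.0, n),
                                 g=rng.uniform(0.5, 10.0))
            mu = rng.uniform(0.008, 0.05)
            found = []
            for _ in range(20):
                y0 = rng.uniform(0.0, 100.0, 2 * n)
                sol = root(lambda y: rhs_flat(net, y, mu), y0, method="hybr")
                if sol.success and np.all(sol.x > -1e-9):
                    y = sol.x
                    for _ in range(3):   # Newton polish to tighten fsolve's xtol
                        y = y - np.linalg.solve(jacobian_flat(net, y, mu),
                                                rhs_flat(net, y, mu))
                    found.append(y)
            assert found, "no converged equilibria"
            spread = np.max(np.ptp(np.array(found), axis=0))
            assert spread < 1e-6

    def test_four_node_ring_has_two_stable_equilibria(self):
        net = ro.builtin_network("4n")
        eqs = ro.find_all_equilibria(net, ro.dilution_rate_from_time(44.5))
        stable = [e for e in eqs if e.stable]
        assert len(eqs) == 3
        assert len(stable) == 2
        # the two stable states mirror each other across the ring
        p0, p1 = stable[0].state.p, stable[1].state.p
        np.testing.assert_allclose(np.sort(p0), np.sort(p1), rtol=1e-6)
        assert not np.allclose(p0, p1)
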