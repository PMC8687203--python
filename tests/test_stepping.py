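"""Partial-equilibrium detection, critical partitioning and step-size
candidates."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from citsens import (
    LeapControls,
    classify_critical,
    g_exponent,
    partial_equilibrium_flags,
    select_critical_reaction,
    tau_critical,
    tau_noncritical,
    build_fixture,
)
from citsens.stepping import equilibrium_reaction_mask


class TestPartialEquilibrium:
    @pytest.mark.parametrize(
        "ap, am, expected",
        [
            (1000.0, 1001.0, True),   # |1| <= 0.05 * 1000
            (0.0, 0.0, True),         # equality edge
            (10.0, 1.0, False),       # 9 > 0.05
        ],
    )
    def test_balance_condition(self, iso_net, ap, am, expected):
        net, _ = iso_net
        flags = partial_equilibrium_flags(net, np.array([ap, am]), 0.05)
        assert flags[0] == expected

    def test_irreversible_never_flagged(self, dd_fixture):
        a = dd_fixture.net.propensities(np.array([400, 800, 0]))
        flags = partial_equilibrium_flags(dd_fixture.net, a, 0.05)
        mask = equilibrium_reaction_mask(dd_fixture.net, flags)
        assert not mask[0] and not mask[3]  # R1, R4 are irreversible


class TestCriticalPartition:
    def test_large_populations_noncritical(self, dd_fixture):
        net = dd_fixture.net
        x = np.array([400, 800, 0])
        a = net.propensities(x)
        part = classify_critical(net, x, x, a, a, n_c=10)
        assert part.L[1] == 200  # floor(400 / 2)
        assert not part.crit.any()

    def test_near_exhaustion_is_critical(self, dd_fixture):
        net = dd_fixture.net
        x = np.array([5, 800, 0])
        a = net.propensities(x)
        part = classify_critical(net, x, x, a, a, n_c=10)
        assert part.crit[0] and part.crit[1]  # both consumers of S1
        assert part.L[0] == 5 and part.L[1] == 2

    def test_pure_production_never_critical(self):
        fx = build_fixture("toggle_switch", k=1.0)
        x = np.array([1, 1, 1, 1])
        a = fx.net.propensities(x)
        part = classify_critical(fx.net, x, x, a, a, n_c=10)
        assert math.isinf(part.L[0]) and math.isinf(part.L[4])
        assert not part.crit[0] and not part.crit[4]

    def test_criticality_uses_worst_path(self, dd_fixture):
        net = dd_fixture.net
        x_c = np.array([400, 800, 0])
        x_ch = np.array([5, 800, 0])
        a_c = net.propensities(x_c)
        a_ch = net.propensities(x_ch)
        part = classify_critical(net, x_c, x_ch, a_c, a_ch, n_c=10)
        assert part.crit[0]  # critical on the perturbed path only

    def test_equilibrium_pair_excluded_from_criticality(self, iso_net):
        net, _ = iso_net
        x = np.array([2, 2])  # L = 2 < n_c
        a = net.propensities(x)
        eq = equilibrium_reaction_mask(
            net, partial_equilibrium_flags(net, a, 0.05)
        )
        assert eq.all()
        part = classify_critical(net, x, x, a, a, n_c=10, eq_mask=eq)
        assert not part.crit.any()
        assert part.ncr.all() and not part.necr.any()

    def test_partition_exhaustive_and_disjoint(self, dd_fixture):
        net = dd_fixture.net
        rng = np.random.default_rng(7)
        for _ in range(50):
            x = rng.integers(0, 40, size=3)
            a = net.propensities(x)
            part = classify_critical(net, x, x, a, a, n_c=5)
            active = a > 0
            assert not (part.crit & part.ncr).any()
            assert np.array_equal(part.crit | part.ncr & active, active)


class TestLeapExponent:
    def test_first_order(self):
        assert g_exponent(1, 1, 100.0) == 1.0

    def test_homo_dimerisation(self):
        assert g_exponent(2, 2, 400.0) == pytest.approx(2 + 1 / 399)

    def test_hetero_second_order(self):
        assert g_exponent(2, 1, 400.0) == 2.0

    def test_third_order_forms(self):
        x = 10.0
        assert g_exponent(3, 1, x) == 3.0
        assert g_exponent(3, 2, x) == pytest.approx(1.5 * (2 + 1 / 9))
        assert g_exponent(3, 3, x) == pytest.approx(3 + 1 / 9 + 2 / 8)

    def test_degenerate_population_falls_back(self):
        assert g_exponent(2, 2, 1.0) == 2.0
        assert g_exponent(3, 3, 2.0) == 3.0


class TestTauCandidates:
    def test_single_decay_worked_value(self, decay_net):
        # c = 1, x = 100: bound = max(0.05*100, 1) = 5, mu = sigma^2 = 100
        net, _ = decay_net
        net = net.with_perturbed_rate(0, 0.9)  # c: 0.1 -> 1.0
        x = np.array([100])
        a = net.propensities(x)
        part = classify_critical(net, x, x, a, a, n_c=10)
        tau1 = tau_noncritical(net, x, a, part, 0.05)
        assert tau1 == pytest.approx(0.05)  # min(5/100, 25/100)

    def test_empty_noncritical_set_gives_infinity(self, decay_net):
        net, _ = decay_net
        x = np.array([3])  # L = 3 < n_c: the only channel is critical
        a = net.propensities(x)
        part = classify_critical(net, x, x, a, a, n_c=10)
        assert math.isinf(tau_noncritical(net, x, a, part, 0.05))

    def test_small_population_clamps_bound_at_one(self, decay_net):
        net, _ = decay_net
        x = np.array([15])  # eps * x = 0.75 < 1 with n_c below
        a = net.propensities(x)
        part = classify_critical(net, x, x, a, a, n_c=2)
        tau1 = tau_noncritical(net, x, a, part, 0.05)
        assert tau1 == pytest.approx(1.0 / a[0])  # min(1/|mu|, 1/sig2)

    def test_exponential_critical_waiting_time(self, decay_net):
        net, _ = decay_net
        x = np.array([5])
        a = net.propensities(x)  # a0^cr = 0.5
        part = classify_critical(net, x, x, a, a, n_c=10)
        assert part.crit[0]
        tau2 = tau_critical(a, part, math.exp(-1.0))
        assert tau2 == pytest.approx(1.0 / 0.5)

    def test_no_critical_reactions_infinite_tau2(self, decay_net):
        net, _ = decay_net
        x = np.array([100])
        a = net.propensities(x)
        part = classify_critical(net, x, x, a, a, n_c=10)
        assert math.isinf(tau_critical(a, part, 0.5))

    def test_xi_near_one_gives_vanishing_tau2(self, decay_net):
        net, _ = decay_net
        x = np.array([5])
        a = net.propensities(x)
        part = classify_critical(net, x, x, a, a, n_c=10)
        assert tau_critical(a, part, 1 - 1e-12) < 1e-11

    @given(lam=st.floats(min_value=1e-3, max_value=1e3))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_tau1_scale_covariance(self, lam):
        fx = build_fixture("decay_dimer")
        net = fx.net
        x = np.array([50, 30, 2])
        a = net.propensities(x)
        part = classify_critical(net, x, x, a, a, n_c=5)
        tau1 = tau_noncritical(net, x, a, part, 0.05)
        tau1_scaled = tau_noncritical(net, x, lam * a, part, 0.05)
        assert tau1_scaled == pytest.approx(tau1 / lam)

    @given(
        x1=st.integers(min_value=0, max_value=500),
        x2=st.integers(min_value=0, max_value=500),
    )
    @settings(max_examples=40, deadline=None, derandomize=True)
    def test_leap_bound_invariant(self, x1, x2):
        """The chosen tau1 respects the mean and variance bounds for every
        reactant of the non-critical, non-equilibrium channels."""
        from citsens.stepping import g_exponent as g

        fx = build_fixture("decay_dimer")
        net = fx.net
        x = np.array([x1, x2, 0])
        a = net.propensities(x)
        part = classify_critical(net, x, x, a, a, n_c=10)
        tau1 = tau_noncritical(net, x, a, part, 0.05)
        if math.isinf(tau1):
            return
        necr = part.necr
        nu = net.nu[:, necr].astype(float)
        mu = nu @ a[necr]
        sig2 = (nu ** 2) @ a[necr]
        for i, (psi, mult) in net.species_reaction_orders(necr).items():
            bound = max(0.05 * x[i] / g(psi, mult, float(x[i])), 1.0)
            assert abs(mu[i]) * tau1 <= bound * (1 + 1e-12)
            assert sig2[i] * tau1 <= bound ** 2 * (1 + 1e-12)


class TestCriticalSelection:
    def test_cumulative_search(self, dd_fixture):
        net = dd_fixture.net
        x = np.array([2, 1, 0])
        a = net.propensities(x)
        part = classify_critical(net, x, x, a, a, n_c=10)
        idx = part.J_cr
        av = np.zeros(net.M)
        av[idx[0]], av[idx[1]] = 3.0, 1.0
        assert select_critical_reaction(part, av, 0.8) == idx[1]
        assert select_critical_reaction(part, av, 0.5) == idx[0]

    def test_single_critical_always_selected(self, decay_net):
        net, _ = decay_net
        x = np.array([4])
        a = net.propensities(x)
        part = classify_critical(net, x, x, a, a, n_c=10)
        for xi2 in (1e-9, 0.5, 1 - 1e-9):
            assert select_critical_reaction(part, a, xi2) == 0

    def test_all_zero_critical_propensities_rejected(self, decay_net):
        net, _ = decay_net
        x = np.array([4])
        a = net.propensities(x)
        part = classify_critical(net, x, x, a, a, n_c=10)
        with pytest.raises(ValueError):
            select_critical_reaction(part, np.zeros(1), 0.5)


class TestControls:
    def test_defaults_follow_published_settings(self):
        c = LeapControls()
        assert (c.epsilon, c.delta, c.newton_tol, c.n_c) == (
            0.05, 0.05, 0.01, 10
        )

    @pytest.mark.parametrize(
        "kw", [{"epsilon": 0.0}, {"epsilon": 1.0}, {"delta": 0.0},
               {"newton_tol": 0.0}, {"n_c": 0}]
    )
    def test_invalid_controls_rejected(self, kw):
        with pytest.raises(ValueError):
            LeapControls(**kw)
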