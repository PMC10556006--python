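"""Engine tests: growth rate, integration, fixed points and summaries."""

import math

import numpy as np
import pytest

from mgm.comparators import vb_closed_form, vb_time_to_mass
from mgm.engine import (
    PiecewisePhi,
    energy_budget_series,
    food_restriction_sweep,
    growth_rate,
    integrate_growth,
    summarize_rate,
    summarize_trajectory,
    ultimate_mass,
)
from mgm.exceptions import (
    DomainError,
    IncompleteTrajectoryError,
    NoUltimateMassError,
)
from mgm.presets import cricket_params, reduced_params


class TestGrowthRate:
    def test_supply_only(self):
        p = reduced_params(a=1.0, beta=2.0 / 3.0, c=0.0)
        assert growth_rate(8.0, 1.0, p) == pytest.approx(4.0, rel=1e-12)

    def test_reduced_arithmetic(self):
        p = reduced_params(a=1.0, beta=0.75, c=0.5, a_N=0.1, b_N=1.0)
        expected = 1.0 - 0.5 / 0.9
        assert growth_rate(1.0, 1.0, p) == pytest.approx(expected, rel=1e-12)

    def test_zero_at_ultimate_mass(self, cricket):
        W_U = ultimate_mass(cricket, 1.0)
        assert abs(growth_rate(W_U, 1.0, cricket)) < 1e-10


class TestUltimateMass:
    def test_von_bertalanffy_closed_form(self):
        # dW/dt = 2 W^{2/3} - W  ->  W_U = (a/b)^3 = 8
        p = reduced_params(a=2.0, beta=2.0 / 3.0, c=1.0)
        assert ultimate_mass(p, 1.0) == pytest.approx(8.0, rel=1e-10)

    def test_agrees_with_long_integration(self):
        p = reduced_params(a=1.0, beta=0.75, c=0.25, a_N=0.05, b_N=1.0)
        W_U = ultimate_mass(p, 1.0)
        traj = integrate_growth(0.5, 4000.0, p, 1.0)
        assert traj.masses[-1] == pytest.approx(W_U, rel=1e-6)

    def test_immediate_decline_raises(self):
        p = reduced_params(a=0.1, beta=0.75, c=50.0)
        with pytest.raises(NoUltimateMassError):
            ultimate_mass(p, 1.0)

    def test_indefinite_growth_raises(self):
        # supply exponent 1 with weaker linear expenditure: no fixed point
        p = reduced_params(a=1.0, beta=1.0, c=0.5)
        with pytest.raises(NoUltimateMassError):
            ultimate_mass(p, 1.0)

    def test_fixed_point_consistency(self, cricket):
        for phi in (1.0, 0.8, 0.6):
            W_U = ultimate_mass(cricket, phi)
            assert abs(growth_rate(W_U, phi, cricket)) < 1e-10


class TestIntegration:
    def test_constant_rate_growth(self):
        # beta = 0, no maintenance: dW/dt = a, linear in time
        p = reduced_params(a=1.0, beta=0.0, c=0.0)
        traj = integrate_growth(1.0, 5.0, p, 1.0, ages=[0, 1, 2, 3, 4, 5])
        assert traj.masses[-1] == pytest.approx(6.0, rel=1e-9)
        assert np.allclose(traj.masses, 1.0 + traj.ages, rtol=1e-9)

    @pytest.mark.parametrize(
        "a,b,beta,W0",
        [
            (1.0, 1.0, 2.0 / 3.0, 0.125),
            (2.0, 1.0, 2.0 / 3.0, 1.0),
            (1.0, 0.5, 0.75, 0.67),
            (0.5, 0.25, 0.6, 0.1),
            (3.0, 2.0, 0.9, 0.5),
        ],
    )
    def test_von_bertalanffy_oracle(self, a, b, beta, W0):
        """b_N = 0 trajectories must match the closed-form Bernoulli solution."""
        p = reduced_params(a=a, beta=beta, c=b, a_N=0.0, b_N=0.0)
        ages = np.linspace(0.0, 10.0, 41)
        traj = integrate_growth(W0, 10.0, p, 1.0, ages=ages)
        exact = vb_closed_form(ages, a, b, beta, W0)
        assert np.max(np.abs(traj.masses - exact) / exact) < 1e-6

    def test_monotone_and_bounded(self, cricket, W0):
        traj = integrate_growth(W0, 300.0, cricket, 1.0)
        W_U = ultimate_mass(cricket, 1.0)
        assert np.all(np.diff(traj.masses) >= -1e-12)
        assert np.all(traj.masses <= W_U * (1.0 + 1e-9))

    def test_determinism(self, cricket, W0):
        ages = np.linspace(0, 150, 51)
        t1 = integrate_growth(W0, 150.0, cricket, 1.0, ages=ages)
        t2 = integrate_growth(W0, 150.0, cricket, 1.0, ages=ages)
        assert np.array_equal(t1.masses, t2.masses)
        assert np.array_equal(t1.ages, t2.ages)

    def test_domain_errors(self, cricket):
        with pytest.raises(DomainError):
            integrate_growth(-1.0, 10.0, cricket, 1.0)
        with pytest.raises(DomainError):
            integrate_growth(1.0, -10.0, cricket, 1.0)

    def test_declining_start_rejected_by_default(self):
        p = reduced_params(a=0.1, beta=0.75, c=50.0)
        with pytest.raises(NoUltimateMassError):
            integrate_growth(1.0, 10.0, p, 1.0)
        traj = integrate_growth(1.0, 1.0, p, 1.0, allow_shrinkage=True)
        assert traj.masses[-1] < 1.0

    def test_piecewise_phi_schedule(self, cricket, W0):
        sched = PiecewisePhi([30.0], [1.0, 0.6])
        traj = integrate_growth(W0, 90.0, cricket, sched, ages=np.linspace(0, 90, 91))
        full = integrate_growth(W0, 90.0, cricket, 1.0, ages=np.linspace(0, 90, 91))
        # identical up to the switch, strictly below afterwards
        assert traj.mass_at(30.0) == pytest.approx(full.mass_at(30.0), rel=1e-8)
        assert traj.mass_at(90.0) < full.mass_at(90.0)


class TestSummary:
    def test_von_bertalanffy_hump_position(self):
        """For dW/dt = a W^{2/3} - b W the hump sits at omega* = 8/27."""
        p = reduced_params(a=1.0, beta=2.0 / 3.0, c=1.0, a_N=0.0, b_N=0.0)
        traj = integrate_growth(0.125, 40.0, p, 1.0)
        s = summarize_trajectory(traj, p)
        assert s.omega_star == pytest.approx(8.0 / 27.0, rel=1e-8)
        assert s.W_U == pytest.approx(1.0, rel=1e-10)

    def test_t95_against_closed_form(self):
        a, b, beta, W0 = 1.0, 1.0, 2.0 / 3.0, 0.125
        p = reduced_params(a=a, beta=beta, c=b, a_N=0.0, b_N=0.0)
        traj = integrate_growth(W0, 40.0, p, 1.0)
        s = summarize_trajectory(traj, p)
        t95_exact = vb_time_to_mass(0.95, a, b, beta, W0)
        assert s.t95 == pytest.approx(t95_exact, rel=1e-6)

    def test_t_at_fraction_monotone(self, cricket, W0):
        traj = integrate_growth(W0, 300.0, cricket, 1.0)
        s = summarize_trajectory(traj, cricket)
        fracs = [0.25, 0.5, 0.75, 0.9, 0.95]
        ages = [s.t_at_fraction(f) for f in fracs]
        assert all(b > a for a, b in zip(ages, ages[1:]))
        assert s.t95 > s.t_at_fraction(0.9)
        assert 0.0 < s.omega_star < 1.0
        assert 0.0 < s.W_star < s.W_U

    def test_incomplete_trajectory_raises(self, cricket, W0):
        traj = integrate_growth(W0, 20.0, cricket, 1.0)
        with pytest.raises(IncompleteTrajectoryError):
            summarize_trajectory(traj, cricket)

    def test_logistic_hump_is_symmetric(self):
        from mgm.comparators import logistic_rate

        s = summarize_rate(lambda W: logistic_rate(W, 1.0, 4.0), 0.1)
        assert s.W_star == pytest.approx(2.0, rel=1e-9)
        assert s.omega_star == pytest.approx(0.5, rel=1e-9)
        # analytic logistic time to reach 95% of K from W0
        t95_exact = math.log((3.8 / 0.2) * (3.9 / 0.1))
        assert s.t95 == pytest.approx(t95_exact, rel=1e-7)


class TestEnergyBudget:
    def test_closure_along_trajectory(self, cricket, W0):
        traj = integrate_growth(W0, 150.0, cricket, 1.0, ages=np.linspace(0, 150, 76))
        budgets, max_rel = energy_budget_series(traj, cricket)
        assert max_rel < 1e-10
        assert len(budgets) == 76
        assert all(b.S >= 0 and b.R_M >= 0 and b.R_F >= 0 for b in budgets)

    def test_zero_maintenance_series(self):
        p = reduced_params(a=1.0, beta=0.5, c=0.0)
        traj = integrate_growth(1.0, 5.0, p, 1.0, ages=np.linspace(0, 5, 11))
        budgets, _ = energy_budget_series(traj, p)
        assert all(b.R_M == 0.0 for b in budgets)

    def test_starvation_budget_flags_negative_growth(self, cricket):
        p = reduced_params(a=1.0, beta=0.75, c=0.5, a_N=0.0)
        traj = integrate_growth(4.0, 1.0, p, 0.0, allow_shrinkage=True)
        budgets, _ = energy_budget_series(traj, p)
        assert all(b.S == 0.0 and b.R_F == 0.0 and b.G <= 0.0 for b in budgets)


class TestRestrictionSweep:
    def test_phi_one_column_independent_of_delta(self, cricket, W0):
        sweep = food_restriction_sweep(cricket, [1.0], [0.3, 1.0, 2.0], W0=W0)
        assert sweep["W_U"].nunique() == 1
        assert sweep["t95"].round(9).nunique() == 1

    def test_monotone_response_to_restriction(self, cricket, W0):
        """For delta <= 1, restriction shrinks W95 and delays t95."""
        phis = [1.0, 0.9, 0.8, 0.7, 0.6, 0.5]
        sweep = food_restriction_sweep(cricket, phis, [0.5, 1.0], W0=W0)
        for _, grp in sweep.groupby("delta"):
            grp = grp.sort_values("phi")
            assert grp["W95"].is_monotonic_increasing
            assert grp["t95"].is_monotonic_decreasing
            assert grp["status"].eq("ok").all()

    def test_failures_recorded_not_raised(self, W0):
        p = reduced_params(a=0.25, beta=0.75, c=0.2, a_N=0.001, b_N=1.0)
        # phi = 0.01 starves the model; the cell must fail gracefully
        sweep = food_restriction_sweep(p, [1.0, 0.01], [1.0], W0=1.0)
        assert set(sweep["status"]) == {"ok", "failed"}
        failed = sweep[sweep["status"] == "failed"]
        assert failed["message"].str.len().gt(0).all()
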