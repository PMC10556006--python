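"""Unit and property tests for the energy-budget component functions."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mgm.components import (
    CompositionParams,
    FeedingParams,
    IngestionParams,
    MaintenanceParams,
    defence_fraction,
    energy_density_EM,
    feeding_cost,
    growth_overhead_ES,
    ingestion_rate,
    maintenance_cost,
)
from mgm.exceptions import (
    ConfigurationError,
    DomainError,
    InvalidCompositionError,
    SingularMaintenanceError,
)


class TestIngestion:
    @pytest.mark.parametrize(
        "phi,W,alpha,beta,expected",
        [
            (1.0, 16.0, 1.0, 0.75, 8.0),
            (0.0, 123.0, 1.0, 0.75, 0.0),
            (0.5, 16.0, 1.0, 0.75, 4.0),
        ],
    )
    def test_proportional_allometry(self, phi, W, alpha, beta, expected):
        p = IngestionParams(alpha=alpha, beta=beta)
        assert ingestion_rate(phi, W, p) == pytest.approx(expected, rel=1e-12)

    def test_post_break_policies(self):
        hold = IngestionParams(alpha=2.0, beta=0.5, W_break=100.0)
        cap = IngestionParams(
            alpha=2.0, beta=0.5, W_break=100.0, post_break_policy="cap-at-break-value"
        )
        assert ingestion_rate(1.0, 400.0, hold) == pytest.approx(2.0 * 20.0)
        assert ingestion_rate(1.0, 400.0, cap) == pytest.approx(2.0 * 10.0)
        # below the break both agree
        assert ingestion_rate(1.0, 50.0, hold) == ingestion_rate(1.0, 50.0, cap)

    @pytest.mark.parametrize("bad", [-0.1, 1.1])
    def test_phi_domain(self, bad):
        p = IngestionParams(alpha=1.0)
        with pytest.raises(DomainError):
            ingestion_rate(bad, 1.0, p)

    def test_mass_domain(self):
        with pytest.raises(DomainError):
            ingestion_rate(0.5, -1.0, IngestionParams(alpha=1.0))

    def test_invalid_params(self):
        with pytest.raises(DomainError):
            IngestionParams(alpha=-1.0)
        with pytest.raises(DomainError):
            IngestionParams(alpha=1.0, beta=2.0)

    @given(st.floats(0.1, 100.0))
    @settings(derandomize=True, max_examples=25)
    def test_homogeneous_in_alpha(self, W):
        """Doubling alpha doubles S (and hence proportional R_F)."""
        p1 = IngestionParams(alpha=1.3, beta=0.75)
        p2 = IngestionParams(alpha=2.6, beta=0.75)
        s1 = ingestion_rate(0.8, W, p1)
        s2 = ingestion_rate(0.8, W, p2)
        assert s2 == pytest.approx(2.0 * s1, rel=1e-12)
        f = FeedingParams(k_F=0.1)
        assert feeding_cost(s2, f) == pytest.approx(2.0 * feeding_cost(s1, f), rel=1e-12)


class TestComposition:
    def test_pure_carbohydrate_protein_tissue(self):
        c = CompositionParams(f_CP=1.0, f_L=0.0, f_R=0.0)
        assert energy_density_EM(1.0, c) == pytest.approx(17.0)

    def test_pure_lipid_tissue(self):
        c = CompositionParams(f_CP=0.0, f_L=1.0, f_R=0.0)
        assert energy_density_EM(1.0, c) == pytest.approx(34.0)

    def test_pure_reproductive_growth(self):
        c = CompositionParams(E_MR=20.0, f_R=1.0)
        assert energy_density_EM(1.0, c) == pytest.approx(20.0)

    def test_default_fresh_tissue_density(self):
        # f_CP = 0.29, f_L = 0.06 give the ~7 J/mg of fresh animal tissue
        assert energy_density_EM(1.0, CompositionParams()) == pytest.approx(6.97)

    @pytest.mark.parametrize(
        "kwargs,expected",
        [
            (dict(f_R=0.0, f_G=1.0, E_SSG=5.0, E_SSD=99.0), 5.0),
            (dict(f_R=1.0, E_SR=8.0), 8.0),
            (dict(f_R=0.5, f_G=0.0, E_SSD=4.0, E_SR=8.0), 6.0),
        ],
    )
    def test_growth_overhead(self, kwargs, expected):
        c = CompositionParams(**kwargs)
        assert growth_overhead_ES(1.0, c) == pytest.approx(expected)

    def test_invalid_composition(self):
        c = CompositionParams(f_CP=0.7, f_L=0.5)
        with pytest.raises(InvalidCompositionError):
            energy_density_EM(1.0, c)

    def test_mass_dependent_fraction_hook(self):
        c = CompositionParams(f_R=lambda W: min(1.0, 0.001 * W))
        low = energy_density_EM(1.0, c)
        high = energy_density_EM(900.0, c)
        assert low == pytest.approx(6.97 * 0.999 + 6.97 * 0.001)
        assert high == pytest.approx(c.E_MR * 0.9 + 6.97 * 0.1)


class TestFeedingCost:
    def test_proportional(self):
        assert feeding_cost(100.0, FeedingParams(k_F=0.1)) == pytest.approx(10.0)
        assert feeding_cost(0.0, FeedingParams(k_F=0.1)) == 0.0

    def test_custom_function(self):
        p = FeedingParams(custom_fn=lambda S: 0.05 * S + 0.001 * S**2)
        assert feeding_cost(10.0, p) == pytest.approx(0.6)
        assert feeding_cost(0.0, p) == 0.0

    def test_custom_function_must_be_monotone(self):
        with pytest.raises(ConfigurationError):
            FeedingParams(custom_fn=lambda S: -S)

    def test_custom_function_must_vanish_at_zero(self):
        with pytest.raises(ConfigurationError):
            FeedingParams(custom_fn=lambda S: 1.0 + 0.1 * S)

    def test_kF_bounds(self):
        with pytest.raises(DomainError):
            FeedingParams(k_F=1.0)


class TestDefenceFraction:
    @pytest.mark.parametrize(
        "phi,W,a_N,b_N,delta,expected",
        [
            (1.0, 4.0, 0.1, 1.0, 1.0, 0.4),
            (0.0, 77.0, 0.1, 1.0, 1.0, 0.0),
            (1.0, 123.0, 0.3, 0.0, 1.0, 0.3),
        ],
    )
    def test_values(self, phi, W, a_N, b_N, delta, expected):
        assert defence_fraction(phi, W, a_N, b_N, delta) == pytest.approx(expected)

    def test_singularity_names_the_mass(self):
        with pytest.raises(SingularMaintenanceError, match="20"):
            defence_fraction(1.0, 20.0, 0.1, 1.0, 1.0)


class TestMaintenance:
    def test_basal_only(self):
        m = MaintenanceParams.simple(gamma_B=0.5, a_N=0.0)
        assert maintenance_cost(1.0, 10.0, m) == pytest.approx(5.0)

    def test_phi_zero_downregulates_fully(self):
        m = MaintenanceParams.simple(gamma_B=0.5, a_N=0.2, b_N=0.0, delta=1.0)
        assert maintenance_cost(0.0, 10.0, m) == pytest.approx(5.0)

    def test_negotiable_inflation(self):
        m = MaintenanceParams.simple(gamma_B=1.0, a_N=0.5, b_N=1.0, delta=1.0)
        assert maintenance_cost(1.0, 1.0, m) == pytest.approx(2.0)

    def test_two_tissue_sum(self):
        m = MaintenanceParams(gamma_BS=1.0, gamma_BR=2.0, a_NS=0.0, a_NR=0.0)
        # p_R = 0.5 at W = 2: each tissue has mass 1
        assert maintenance_cost(1.0, 2.0, m, p_R=0.5) == pytest.approx(3.0)

    def test_singular_denominator(self):
        m = MaintenanceParams.simple(gamma_B=1.0, a_N=0.1, b_N=1.0)
        with pytest.raises(SingularMaintenanceError):
            maintenance_cost(1.0, 10.0, m)

    @given(
        st.floats(0.0, 1.0),
        st.floats(0.0, 1.0),
        st.floats(0.1, 300.0),
    )
    @settings(derandomize=True, max_examples=50)
    def test_monotone_in_phi(self, phi_lo, phi_hi, W):
        """Larger phi means a larger negotiable allocation, never smaller."""
        phi_lo, phi_hi = sorted((phi_lo, phi_hi))
        m = MaintenanceParams.simple(gamma_B=0.44, a_N=0.001125, b_N=1.0, delta=1.0)
        if 0.001125 * W >= 1.0:
            return
        assert maintenance_cost(phi_hi, W, m) >= maintenance_cost(phi_lo, W, m) - 1e-12

    @given(st.floats(0.01, 1.0), st.floats(0.1, 500.0))
    @settings(derandomize=True, max_examples=50)
    def test_two_tissue_collapses_to_lumped(self, phi, W):
        """Identical tissue parameters make the two-tissue sum equal the
        lumped single-tissue expression, for any reproductive share."""
        m = MaintenanceParams.simple(gamma_B=0.7, a_N=0.0005, b_N=1.0, delta=0.8)
        lumped = maintenance_cost(phi, W, m, p_R=0.0)
        # with b_N = 1 the split is exactly additive only at p_R in {0, 1};
        # check both degenerate splits and the b_N = 0 case for interior p_R
        assert maintenance_cost(phi, W, m, p_R=1.0) == pytest.approx(lumped, rel=1e-12)
        m0 = MaintenanceParams.simple(gamma_B=0.7, a_N=0.2, b_N=0.0, delta=0.8)
        full = maintenance_cost(phi, W, m0, p_R=0.35)
        assert full == pytest.approx(maintenance_cost(phi, W, m0, p_R=0.0), rel=1e-12)

    def test_linear_scaling_when_bN_zero(self):
        """b_N = 0 makes maintenance exactly proportional to mass."""
        m = MaintenanceParams.simple(gamma_B=0.44, a_N=0.15, b_N=0.0, delta=1.0)
        base = maintenance_cost(0.7, 1.0, m)
        for W in (2.0, 10.0, 400.0):
            assert maintenance_cost(0.7, W, m) == pytest.approx(W * base, rel=1e-12)
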