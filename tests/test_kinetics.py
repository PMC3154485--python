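"""Closed-form model: eigenstructure, conservation, limits, oracle agreement."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from relkin import (
    DegenerateParameterError,
    RateParameters,
    ThermoParameters,
    TimeUnit,
    convert_rate,
    convert_times,
    cumulative_release,
    cumulative_release_case1,
    cumulative_release_case2,
    delta_g_from_rates,
    eigenvalues,
    equilibrium_fractions,
    ode_reference_solution,
    rates_from_delta_g,
    release_prefactors,
    state_fractions,
    thermal_energy,
)

RATES = st.floats(min_value=1e-4, max_value=1e3)
TIMES_GRID = np.array([0.0, 0.1, 0.5, 1.0, 3.0, 10.0, 40.0])


def rate_params(draw_tuple) -> RateParameters:
    k_s, k_on, k_off = draw_tuple
    return RateParameters(k_s=k_s, k_on=k_on, k_off=k_off, time_unit=TimeUnit.DAY)


valid_rates = st.tuples(RATES, st.one_of(st.just(0.0), RATES), RATES)


class TestEigenvalues:
    @pytest.mark.parametrize(
        "k_s,k_on,k_off,lam1,lam2",
        [
            (2.0, 0.0, 0.5, 2.0, 0.5),
            (1.0, 1.0, 1.0, (3 + math.sqrt(5)) / 2, (3 - math.sqrt(5)) / 2),
        ],
    )
    def test_known_roots(self, k_s, k_on, k_off, lam1, lam2):
        eig = eigenvalues(RateParameters(k_s, k_on, k_off))
        assert eig.lambda1 == pytest.approx(lam1, rel=1e-12)
        assert eig.lambda2 == pytest.approx(lam2, rel=1e-12)

    def test_published_liposome_rates_satisfy_symmetric_functions(self):
        # 1 mol% PEG thermosensitive-liposome parameter set (per minute)
        p = RateParameters(0.4941, 0.0172, 0.0136, TimeUnit.MINUTE)
        eig = eigenvalues(p)
        assert eig.lambda1 + eig.lambda2 == pytest.approx(0.4941 + 0.0172 + 0.0136, rel=1e-10)
        assert eig.lambda1 * eig.lambda2 == pytest.approx(0.4941 * 0.0136, rel=1e-10)

    @settings(derandomize=True, max_examples=60, deadline=None)
    @given(valid_rates)
    def test_symmetric_function_invariants(self, rates):
        p = rate_params(rates)
        eig = eigenvalues(p)
        assert eig.lambda1 >= eig.lambda2 >= 0
        s = p.k_s + p.k_on + p.k_off
        assert eig.lambda1 + eig.lambda2 == pytest.approx(s, rel=1e-10)
        assert eig.lambda1 * eig.lambda2 == pytest.approx(p.k_s * p.k_off, rel=1e-10)

    def test_repeated_root_flagged(self):
        eig = eigenvalues(RateParameters(k_s=0.3, k_on=0.0, k_off=0.3))
        assert eig.repeated
        assert eig.lambda1 == pytest.approx(0.3)


class TestThermoMapping:
    def test_equal_rates_give_zero_free_energy(self):
        assert delta_g_from_rates(0.05, 0.05) == 0.0

    @pytest.mark.parametrize(
        "k_on,k_off,printed",
        [
            (0.0172, 0.0136, -0.9676),  # liposome, 1 mol% PEG (per minute)
            (0.0176, 0.0068, -3.9408),  # PLGA 85:15 nanoparticle (per day)
        ],
    )
    def test_published_delta_g_reproduced(self, k_on, k_off, printed):
        # printed rate constants are rounded, so agreement is ~1% not exact
        assert delta_g_from_rates(k_on, k_off) == pytest.approx(printed, rel=0.02)

    @settings(derandomize=True, max_examples=40, deadline=None)
    @given(st.floats(-25.0, 25.0), RATES, st.floats(200.0, 400.0))
    def test_round_trip_delta_g(self, dg, k_off, temp):
        k_on = rates_from_delta_g(dg, k_off, temp)
        assert delta_g_from_rates(k_on, k_off, temp) == pytest.approx(dg, abs=1e-9)

    def test_thermo_rate_round_trip_preserves_values(self):
        p = ThermoParameters(delta_g=-6.65, k_s=0.041, k_off=0.0004, time_unit="minute")
        back = p.to_rates().to_thermo()
        assert back.delta_g == pytest.approx(p.delta_g, rel=1e-12)
        assert back.k_s == pytest.approx(p.k_s, rel=1e-12)
        assert back.k_off == pytest.approx(p.k_off, rel=1e-12)

    def test_zero_k_on_rejected_with_case1_message(self):
        with pytest.raises(ValueError, match="single-exponential"):
            delta_g_from_rates(0.0, 0.1)
        with pytest.raises(ValueError, match="k_off"):
            delta_g_from_rates(0.1, 0.0)

    def test_thermal_energy_at_300k(self):
        assert thermal_energy(300.0) == pytest.approx(4.14, abs=0.005)


class TestEquilibrium:
    def test_no_association_means_all_free(self):
        assert equilibrium_fractions(0.0, 0.3) == (1.0, 0.0)

    def test_plga_50_50_published_rates(self):
        free0, bound0 = equilibrium_fractions(0.03, 0.0199)
        assert free0 == pytest.approx(0.0199 / 0.0499, rel=1e-12)
        assert free0 + bound0 == 1.0

    def test_burst_exceeds_70pct_when_delta_g_equals_thermal_energy(self):
        p = ThermoParameters(delta_g=thermal_energy(), k_s=1.0, k_off=0.01)
        assert p.burst_fraction == pytest.approx(1 / (1 + math.exp(-1)), rel=1e-12)
        assert p.burst_fraction > 0.70

    def test_burst_fraction_increases_with_delta_g(self):
        bursts = [
            ThermoParameters(delta_g=dg, k_s=1.0, k_off=0.01).burst_fraction
            for dg in np.linspace(-10, 10, 21)
        ]
        assert np.all(np.diff(bursts) > 0)


class TestStateFractions:
    def test_initial_condition_is_binding_equilibrium(self):
        p = RateParameters(k_s=0.7, k_on=0.03, k_off=0.0199)
        traj = state_fractions(p, [0.0])
        assert traj.free_fraction[0] == pytest.approx(0.0199 / 0.0499, rel=1e-12)
        assert traj.bound_fraction[0] == pytest.approx(0.03 / 0.0499, rel=1e-12)

    def test_no_binding_reduces_to_single_compartment_decay(self):
        traj = state_fractions(RateParameters(0.3, 0.0, 0.0), TIMES_GRID)
        assert traj.bound_fraction == pytest.approx(np.zeros_like(TIMES_GRID), abs=1e-15)
        assert traj.free_fraction == pytest.approx(np.exp(-0.3 * TIMES_GRID), rel=1e-12)

    def test_matches_ode_oracle_at_reference_parameters(self):
        p = ThermoParameters(delta_g=-2.0, k_s=0.15, k_off=0.005, time_unit="day")
        t = np.array([1.0, 5.0, 20.0])
        closed = state_fractions(p, t)
        ode = ode_reference_solution(p, t)
        for attr in ("free_fraction", "bound_fraction", "released_fraction"):
            assert getattr(closed, attr) == pytest.approx(getattr(ode, attr), abs=1e-8)

    def test_degenerate_parameters_rejected(self):
        with pytest.raises(DegenerateParameterError):
            RateParameters(k_s=1.0, k_on=0.5, k_off=0.0)

    @settings(derandomize=True, max_examples=60, deadline=None)
    @given(valid_rates)
    def test_conservation_and_monotonicity(self, rates):
        p = rate_params(rates)
        t = np.geomspace(1e-3, 10.0 / max(p.k_s, p.k_off, 1e-3), 40)
        traj = state_fractions(p, t)
        total = traj.free_fraction + traj.bound_fraction + traj.released_fraction
        assert total == pytest.approx(np.ones_like(t), abs=1e-10)
        assert np.all(traj.free_fraction >= -1e-12)
        assert np.all(traj.bound_fraction >= -1e-12)
        assert np.all(np.diff(traj.released_fraction) >= -1e-12)

    def test_repeated_eigenvalue_continuous_with_neighbours(self):
        # k_on -> 0 with k_s = k_off sits exactly on the degenerate root
        t = np.linspace(0.0, 20.0, 50)
        exact = state_fractions(RateParameters(0.25, 0.0, 0.25), t)
        near = state_fractions(RateParameters(0.25 * (1 + 1e-7), 0.0, 0.25), t)
        assert exact.released_fraction == pytest.approx(near.released_fraction, abs=1e-6)
        ode = ode_reference_solution(RateParameters(0.25, 0.0, 0.25), t)
        assert exact.released_fraction == pytest.approx(ode.released_fraction, abs=1e-8)


class TestCumulativeRelease:
    def test_nothing_released_at_time_zero(self):
        p = ThermoParameters(delta_g=1.0, k_s=0.5, k_off=0.05)
        assert cumulative_release(p, [0.0])[0] == 0.0

    def test_complete_release_in_the_long_time_limit(self):
        p = RateParameters(k_s=0.5, k_on=0.02, k_off=0.05)
        lam2 = eigenvalues(p).lambda2
        assert cumulative_release(p, [60.0 / lam2])[0] == pytest.approx(1.0, abs=1e-12)

    def test_case1_identity_without_binding(self):
        got = cumulative_release(RateParameters(0.1, 0.0, 0.0), [10.0])[0]
        assert got == pytest.approx(1 - math.exp(-1), rel=1e-12)

    def test_case1_half_release_time(self):
        assert cumulative_release_case1(0.2, [math.log(2) / 0.2])[0] == pytest.approx(0.5)

    def test_case1_telmisartan_complete_release_within_80_minutes(self):
        # largest-pore mesoporous-silica fit: k_S = 0.192/min, no binding term
        assert cumulative_release_case1(0.192, [80.0])[0] > 0.999

    @settings(derandomize=True, max_examples=60, deadline=None)
    @given(valid_rates)
    def test_prefactors_sum_to_one(self, rates):
        p = rate_params(rates)
        eig = eigenvalues(p)
        if eig.repeated:
            return
        a1, a2 = release_prefactors(p)
        assert a1 + a2 == pytest.approx(1.0, abs=1e-12)

    def test_case2_agrees_when_transport_dominates(self):
        k_on, k_off = 0.004, 0.006
        p = RateParameters(k_s=1000 * (k_on + k_off), k_on=k_on, k_off=k_off)
        t = np.geomspace(1e-4, 1000.0, 200)
        assert cumulative_release_case2(p, t) == pytest.approx(
            cumulative_release(p, t), abs=1e-3
        )

    def test_case2_overpredicts_when_separation_is_poor(self):
        p = RateParameters(k_s=0.1, k_on=0.02, k_off=0.05)  # k_s only 2x k_off
        t = np.geomspace(0.01, 200.0, 100)
        assert np.all(cumulative_release_case2(p, t) - cumulative_release(p, t) >= -1e-12)

    def test_case1_limit_as_binding_vanishes(self):
        t = np.linspace(0.0, 30.0, 40)
        p = ThermoParameters(delta_g=28.0, k_s=0.2, k_off=0.01)  # k_on/k_off ~ 1e-3
        assert cumulative_release(p, t) == pytest.approx(
            cumulative_release_case1(0.2, t), abs=2e-3
        )


class TestOdeOracle:
    @settings(derandomize=True, max_examples=50, deadline=None)
    @given(valid_rates)
    def test_closed_form_matches_integration(self, rates):
        p = rate_params(rates)
        scale = max(p.k_s, p.k_off, p.k_on, 1e-3)
        t = np.linspace(0.0, 5.0 / scale, 12)
        closed = state_fractions(p, t)
        ode = ode_reference_solution(p, t)
        assert closed.released_fraction == pytest.approx(ode.released_fraction, abs=1e-8)


class TestUnits:
    def test_rate_and_time_conversions_are_inverse(self):
        assert convert_rate(0.192, TimeUnit.MINUTE, TimeUnit.HOUR) == pytest.approx(11.52)
        assert convert_times(120.0, TimeUnit.MINUTE, TimeUnit.HOUR) == pytest.approx(2.0)

    def test_parameter_conversion_preserves_dimensionless_shape(self):
        p = ThermoParameters(delta_g=-6.65, k_s=0.041, k_off=0.0004, time_unit="minute")
        q = p.convert_to(TimeUnit.HOUR)
        t_min = np.array([50.0, 500.0, 2000.0])
        assert cumulative_release(q, t_min / 60.0) == pytest.approx(
            cumulative_release(p, t_min), rel=1e-12
        )
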