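"""Unit and property tests of the two-state dimerization model."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from acdimer.dimer_model import (
    R_KCAL,
    GasComposition,
    ShiftPair,
    ThermoState,
    celsius_to_kelvin,
    equilibrium_constant,
    gibbs_energy,
    monomer_pressure,
    observed_shift,
    predict_shift,
)


class TestEquilibriumConstant:
    def test_zero_gibbs_energy_gives_unit_constant(self):
        # dH = T*dS*1e-3 forces dG = 0 hence K = 1
        T = 310.0
        thermo = ThermoState(dH=T * (-30.0) * 1e-3, dS=-30.0)
        assert equilibrium_constant(thermo, T) == pytest.approx(1.0, rel=1e-12)

    @pytest.mark.parametrize(
        "dH, dS, T, expected_K, expected_dG",
        [
            (-15.38, -36.6, 298.15, 1.883e3, -4.4677),
            (-15.4, -36.6, 373.15, 1.049e1, -1.7427),
        ],
    )
    def test_vant_hoff_values(self, dH, dS, T, expected_K, expected_dG):
        thermo = ThermoState(dH, dS)
        assert gibbs_energy(thermo, T) == pytest.approx(expected_dG, abs=1e-3)
        assert equilibrium_constant(thermo, T) == pytest.approx(expected_K, rel=1e-3)

    def test_nonpositive_temperature_rejected(self):
        with pytest.raises(ValueError):
            equilibrium_constant(ThermoState(-15.0, -36.0), 0.0)
        with pytest.raises(ValueError):
            gibbs_energy(ThermoState(-15.0, -36.0), -5.0)

    @given(
        dH=st.floats(-40, 5),
        dS=st.floats(-80, 5),
        T=st.floats(200, 500),
    )
    @settings(derandomize=True, max_examples=50)
    def test_consistency_with_gibbs_energy(self, dH, dS, T):
        thermo = ThermoState(dH, dS)
        K = equilibrium_constant(thermo, T)
        dG = gibbs_energy(thermo, T)
        assert K == pytest.approx(np.exp(-dG / (R_KCAL * T)), rel=1e-12)


class TestMonomerPressure:
    def test_no_dimerization_limit(self):
        comp = monomer_pressure(0.0, 0.3)
        assert comp.p_M == pytest.approx(0.3)
        assert comp.p_D == pytest.approx(0.0)

    def test_exact_arithmetic_case(self):
        comp = monomer_pressure(1.0, 1.0)  # sqrt(9) = 3
        assert comp.p_M == pytest.approx(0.5, rel=1e-14)
        assert comp.p_D == pytest.approx(0.25, rel=1e-14)

    def test_against_quadratic_root(self):
        comp = monomer_pressure(10.49, 0.2)
        assert comp.p_M == pytest.approx(0.0767, abs=2e-4)

    def test_negative_inputs_rejected(self):
        with pytest.raises(ValueError):
            monomer_pressure(-1.0, 0.1)
        with pytest.raises(ValueError):
            monomer_pressure(1.0, -0.1)

    @given(
        K=st.floats(0, 1e6),
        p_tot=st.floats(0, 10),
    )
    @settings(derandomize=True, max_examples=200)
    def test_dalton_closure(self, K, p_tot):
        comp = monomer_pressure(K, p_tot)
        assert comp.p_M + 2 * comp.p_D == pytest.approx(p_tot, rel=1e-12, abs=1e-12)

    def test_equilibrium_round_trip_random_instances(self, rng):
        """p_D / p_M**2 recovers K on 1000 random instances."""
        Ks = 10.0 ** rng.uniform(-6, 6, size=1000)
        ps = 10.0 ** rng.uniform(-6, 1, size=1000)
        for K, p in zip(Ks, ps):
            comp = monomer_pressure(K, p)
            if comp.p_M > 1e-30:
                assert comp.p_D / comp.p_M**2 == pytest.approx(K, rel=1e-9)

    def test_agrees_with_bisection(self, rng):
        """Independent bisection root of 2K p^2 + p - p_tot on random inputs."""

        def bisect_root(K, p_tot):
            f = lambda p: 2 * K * p * p + p - p_tot
            lo, hi = 0.0, p_tot
            for _ in range(200):
                mid = 0.5 * (lo + hi)
                if f(mid) < 0:
                    lo = mid
                else:
                    hi = mid
            return 0.5 * (lo + hi)

        for _ in range(200):
            K = 10.0 ** rng.uniform(-4, 5)
            p_tot = 10.0 ** rng.uniform(-4, 1)
            expected = bisect_root(K, p_tot)
            assert monomer_pressure(K, p_tot).p_M == pytest.approx(expected, rel=1e-10, abs=1e-12)


class TestObservedShift:
    def test_pure_monomer_and_pure_dimer_limits(self):
        shifts = ShiftPair(3.76, 10.55)
        assert observed_shift(GasComposition(0.2, 0.0, 0.2), shifts) == pytest.approx(3.76)
        assert observed_shift(GasComposition(0.0, 0.1, 0.2), shifts) == pytest.approx(10.55)

    def test_weighted_average_value(self):
        shifts = ShiftPair(3.76, 10.55)
        comp = GasComposition(0.383, (1 - 0.383) / 2, 1.0)
        assert observed_shift(comp, shifts) == pytest.approx(7.949, abs=1e-3)

    def test_zero_pressure_is_undefined(self):
        with pytest.raises(ValueError):
            observed_shift(GasComposition(0.0, 0.0, 0.0), ShiftPair(3.76, 10.55))

    @given(
        K=st.floats(0, 1e5),
        p_tot=st.floats(1e-9, 10),
    )
    @settings(derandomize=True, max_examples=100)
    def test_shift_bounded_by_limiting_shifts(self, K, p_tot):
        shifts = ShiftPair(3.76, 10.55)
        delta = observed_shift(monomer_pressure(K, p_tot), shifts)
        assert 3.76 - 1e-9 <= delta <= 10.55 + 1e-9


class TestPredictShift:
    def test_zero_pressure_limit_is_monomer_shift(self):
        thermo, shifts = ThermoState(-15.4, -36.6), ShiftPair(3.76, 10.55)
        assert predict_shift(thermo, shifts, 350.0, 0.0) == pytest.approx(3.76)
        assert predict_shift(thermo, shifts, 350.0, 1e-12) == pytest.approx(3.76, abs=1e-4)

    def test_dimer_limit_at_high_pressure(self):
        thermo, shifts = ThermoState(-15.4, -36.6), ShiftPair(3.76, 10.55)
        assert predict_shift(thermo, shifts, 298.15, 1e6) == pytest.approx(10.55, abs=1e-2)

    def test_chained_value_at_100C(self):
        thermo, shifts = ThermoState(-15.4, -36.6), ShiftPair(3.76, 10.55)
        assert predict_shift(thermo, shifts, 373.15, 0.2) == pytest.approx(7.95, abs=0.02)

    def test_monotone_nonincreasing_in_temperature(self):
        """Cooling shifts the equilibrium toward dimer (higher dd)."""
        thermo, shifts = ThermoState(-15.4, -36.6), ShiftPair(3.76, 10.55)
        temps = np.linspace(280.0, 450.0, 40)
        dd = [predict_shift(thermo, shifts, T, 0.2) for T in temps]
        assert np.all(np.diff(dd) <= 1e-12)

    def test_matches_composed_operations(self):
        thermo, shifts = ThermoState(-14.0, -35.0), ShiftPair(3.5, 11.0)
        T, p = 330.0, 0.15
        composed = observed_shift(monomer_pressure(equilibrium_constant(thermo, T), p), shifts)
        assert predict_shift(thermo, shifts, T, p) == pytest.approx(composed, rel=1e-12)


def test_celsius_conversion():
    assert celsius_to_kelvin(25.0) == pytest.approx(298.15)


def test_degenerate_shift_pair_rejected():
    with pytest.raises(ValueError):
        ShiftPair(5.0, 5.0)


def test_gas_composition_closure_enforced():
    with pytest.raises(ValueError):
        GasComposition(0.1, 0.1, 0.5)
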