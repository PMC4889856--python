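"""Mobility conversions: Mason-Schamp, drift times, O2/air transfer."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import constants as si

from iontraj.mobility import (
    AIR_COMPOSITION,
    Conditions,
    GasProperties,
    InstrumentGeometry,
    MeasuredPeak,
    MobilityValue,
    air_from_n2,
    blanc_mix,
    gas_properties,
    langevin_ratio,
    mason_schamp,
    mobility_from_drift,
    o2_from_n2,
    standard_number_density,
)


def mason_schamp_oracle(omega_A2, m_da, M_da, q, T, N_cm3):
    """Independent SI evaluation using scipy.constants only."""
    mu = (m_da * M_da / (m_da + M_da)) * si.atomic_mass
    k = (
        (3.0 / 16.0)
        * (q * si.elementary_charge / (N_cm3 * 1e6))
        * np.sqrt(2.0 * np.pi / (mu * si.Boltzmann * T))
        / (omega_A2 * 1e-20)
    )
    return k * 1e4  # cm^2 / (V s)


class TestMasonSchamp:
    def test_matches_dimensional_analysis_oracle(self):
        N = standard_number_density()  # Loschmidt
        mv = mason_schamp(omega=100.0, m=91.0, M=28.0, q=1, T=298.0, N=N)
        expected = mason_schamp_oracle(100.0, 91.0, 28.0, 1, 298.0, N)
        assert mv.K == pytest.approx(expected, rel=1e-6)

    def test_inverse_in_omega_linear_in_charge(self):
        base = mason_schamp(100.0, 91.0, 28.0, 1, 298.0)
        assert mason_schamp(200.0, 91.0, 28.0, 1, 298.0).K == pytest.approx(
            base.K / 2, rel=1e-12
        )
        assert mason_schamp(100.0, 91.0, 28.0, 2, 298.0).K == pytest.approx(
            base.K * 2, rel=1e-12
        )

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(
        omega=st.floats(20.0, 500.0),
        m=st.floats(15.0, 600.0),
        c=st.floats(0.5, 2.0),
    )
    def test_homogeneity(self, omega, m, c):
        k1 = mason_schamp(omega, m, 28.0134, 1, 300.0).K
        k2 = mason_schamp(c * omega, m, 28.0134, 1, 300.0).K
        assert k2 == pytest.approx(k1 / c, rel=1e-9)

    def test_k0_invariant_across_density(self):
        """K0 removes the density dependence: K scales as 1/N at fixed T,
        so reducing from any N gives the same K0.  (The residual sqrt(T)
        dependence of the Mason-Schamp K is physical and is not removed by
        the standard K0 reduction.)"""
        omega, m, T = 120.0, 91.0, 298.0
        mvs = [
            mason_schamp(omega, m, 28.0134, 1, T, N)
            for N in (1.1e19, 2.46e19, 5.0e19)
        ]
        k0 = [mv.K0 for mv in mvs]
        assert max(k0) - min(k0) < 1e-9 * k0[0]

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            mason_schamp(-1.0, 91.0, 28.0, 1, 298.0)


class TestDriftTime:
    def test_compact_drift_tube_arithmetic(self):
        geom = InstrumentGeometry(length=5.5, voltage=1925.0)
        mv = mobility_from_drift(geom, MeasuredPeak(drift_time=6.0))
        assert mv.K == pytest.approx(30.25 / 11.55, rel=1e-12)

    def test_round_trip_exact(self):
        geom = InstrumentGeometry(5.5, 1925.0)
        K = 2.07
        t_ms = geom.length**2 / (K * geom.voltage) * 1e3
        back = mobility_from_drift(geom, MeasuredPeak(t_ms))
        assert back.K == pytest.approx(K, rel=1e-14)

    def test_voltage_scaling(self):
        k1 = mobility_from_drift(InstrumentGeometry(5.5, 1000.0), MeasuredPeak(6.0)).K
        k2 = mobility_from_drift(InstrumentGeometry(5.5, 2000.0), MeasuredPeak(6.0)).K
        assert k2 == pytest.approx(k1 / 2, rel=1e-12)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            InstrumentGeometry(0.0, 100.0)
        with pytest.raises(ValueError):
            MeasuredPeak(-1.0)


def _mv(K: float) -> MobilityValue:
    cond = Conditions(298.0, standard_number_density(298.0))
    return MobilityValue(K, K, cond)


class TestLangevinTransfer:
    def test_degenerate_gases_identity(self):
        props = (
            GasProperties("N2", 28.0, 1.0005),
            GasProperties("O2", 28.0, 1.0005),
        )
        out = o2_from_n2(_mv(2.0), 91.0, props)
        assert out.K == pytest.approx(2.0, rel=1e-14)

    def test_heavy_analyte_limit(self):
        n2, o2 = gas_properties("N2"), gas_properties("O2")
        ratio = langevin_ratio(1e6, n2, o2)
        expected = np.sqrt(
            (n2.dielectric - 1) * n2.mass / ((o2.dielectric - 1) * o2.mass)
        )
        assert ratio == pytest.approx(expected, rel=1e-4)

    def test_hand_evaluated_ratio_for_91_da(self):
        n2, o2 = gas_properties("N2"), gas_properties("O2")
        m = 91.0
        by_hand = np.sqrt(
            ((n2.dielectric - 1.0) * n2.mass * (m + o2.mass))
            / ((o2.dielectric - 1.0) * o2.mass * (m + n2.mass))
        )
        assert langevin_ratio(m, n2, o2) == pytest.approx(by_hand, rel=1e-9)

    def test_bad_dielectric_rejected(self):
        with pytest.raises(ValueError):
            GasProperties("X", 28.0, 0.99)


class TestBlanc:
    def test_single_component_identity(self):
        out = blanc_mix([(_mv(2.0), 1.0)])
        assert out.K == pytest.approx(2.0, rel=1e-14)

    def test_equal_mobilities_degenerate(self):
        out = blanc_mix([(_mv(1.5), 0.3), (_mv(1.5), 0.7)])
        assert out.K == pytest.approx(1.5, rel=1e-14)

    def test_harmonic_mean_arithmetic(self):
        out = blanc_mix([(_mv(2.000), 0.79), (_mv(1.900), 0.21)])
        assert out.K == pytest.approx(1.0 / (0.79 / 2.0 + 0.21 / 1.9), rel=1e-12)
        assert out.K == pytest.approx(1.9781, abs=5e-4)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(
        k1=st.floats(0.5, 4.0),
        k2=st.floats(0.5, 4.0),
        x=st.floats(0.01, 0.99),
    )
    def test_betweenness(self, k1, k2, x):
        out = blanc_mix([(_mv(k1), x), (_mv(k2), 1.0 - x)])
        assert min(k1, k2) - 1e-12 <= out.K <= max(k1, k2) + 1e-12

    def test_bad_fractions_rejected(self):
        with pytest.raises(ValueError):
            blanc_mix([])
        with pytest.raises(ValueError):
            blanc_mix([(_mv(2.0), 0.5)])


class TestAirTransfer:
    @pytest.mark.parametrize("m", [19.0, 78.0, 91.0, 142.0])
    def test_air_within_three_percent_of_n2(self, m):
        out = air_from_n2(_mv(2.0), m)
        assert abs(out.K - 2.0) / 2.0 < 0.03

    def test_air_between_n2_and_o2(self):
        m = 91.0
        k_n2 = _mv(2.0)
        k_o2 = o2_from_n2(k_n2, m)
        k_air = air_from_n2(k_n2, m)
        lo, hi = sorted([k_n2.K, k_o2.K])
        assert lo <= k_air.K <= hi

    def test_pure_n2_composition_identity(self):
        out = air_from_n2(_mv(2.0), 91.0, composition=(("N2", 1.0),))
        assert out.K == pytest.approx(2.0, rel=1e-14)

    def test_default_composition(self):
        assert dict(AIR_COMPOSITION) == {"N2": 0.79, "O2": 0.21}
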