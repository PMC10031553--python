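"""Penetration depth, Sauerbrey relation and coupled-resonator physics."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from qcmd_adhesion import (
    CoupledResonatorParams,
    FluidProperties,
    SensorParams,
    coupled_resonator_load,
    penetration_depth,
    sauerbrey_areal_mass,
    small_load_shifts,
)
from qcmd_adhesion.errors import SingularLoadError


class TestPenetrationDepth:
    @pytest.mark.parametrize("n,expected_nm", [(3, 144), (5, 112), (11, 75)])
    def test_depths_in_buffered_saline(self, n, expected_nm, sensor, fluid):
        # the depths a 5 MHz sensor reaches in PBS at the overtones used to
        # bracket the bacterial cell body
        assert round(penetration_depth(n, sensor, fluid)) == expected_nm

    def test_quarter_frequency_doubles_depth(self, sensor):
        fluid = FluidProperties(eta=3.3e-3, rho=870.0)
        assert penetration_depth(1, sensor, fluid) == pytest.approx(
            2.0 * penetration_depth(4, sensor, fluid), rel=1e-12
        )

    def test_strictly_decreasing_in_overtone(self, sensor, fluid):
        depths = [penetration_depth(n, sensor, fluid) for n in range(1, 30, 2)]
        assert all(a > b for a, b in zip(depths, depths[1:]))

    def test_invalid_inputs_rejected(self, sensor):
        with pytest.raises(ValueError):
            penetration_depth(0, sensor)
        with pytest.raises(ValueError):
            FluidProperties(eta=-1.0, rho=1000.0)


class TestSauerbrey:
    def test_zero_shift_zero_mass(self, sensor):
        assert sauerbrey_areal_mass(0.0, 3, sensor) == 0.0

    def test_hand_evaluated_closed_form(self, sensor):
        # -Zq * df / (2 n f0^2): 8.8e6 * 35 / (2*3*(5e6)^2) kg/m^2
        # = 2.0533e-6 kg/m^2 = 205.33 ng/cm^2
        assert sauerbrey_areal_mass(-35.0, 3, sensor) == pytest.approx(
            205.33, abs=0.01
        )
        # equivalently 17.6 ng cm^-2 Hz^-1 of normalized shift, x 35/3
        assert sauerbrey_areal_mass(-35.0, 3, sensor) == pytest.approx(
            17.6 * 35.0 / 3.0, rel=1e-3
        )

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(df=st.floats(min_value=-500, max_value=500, allow_nan=False))
    def test_linearity(self, df):
        sensor = SensorParams()
        assert sauerbrey_areal_mass(2 * df, 3, sensor) == pytest.approx(
            2 * sauerbrey_areal_mass(df, 3, sensor), rel=1e-12, abs=1e-12
        )


def _params(f_p_hz=2.0e7, gamma=0.0, m_p=1e-15, n_s=1e10):
    omega_p = 2 * np.pi * f_p_hz
    return CoupledResonatorParams(
        m_p=m_p, k=m_p * omega_p**2, gamma=gamma, N_s=n_s
    )


def _oracle_load(omega, params):
    """Independent evaluation: mass and complex spring as series mechanical
    impedances, combined per particle and scaled by the areal density."""
    z_mass = 1j * omega * params.m_p
    z_spring = params.k * (1.0 + 1j * params.gamma) / (1j * omega)
    z_particle = z_mass * z_spring / (z_mass + z_spring)
    return params.N_s * z_particle


class TestCoupledResonatorLoad:
    def test_low_frequency_is_inertial(self):
        p = _params(gamma=0.0)
        omega = p.omega_p / 1000
        z = coupled_resonator_load(omega, p)
        expected = 1j * omega * p.N_s * p.m_p
        assert abs(z - expected) / abs(expected) < 1e-5

    def test_high_frequency_is_elastic(self):
        p = _params(gamma=0.0)
        omega = 1000 * p.omega_p
        z = coupled_resonator_load(omega, p)
        expected = -1j * p.N_s * p.k / omega
        assert abs(z - expected) / abs(expected) < 1e-5

    def test_against_series_impedance_oracle(self):
        p = _params(f_p_hz=2.0e7, gamma=0.1, m_p=1e-15, n_s=1e10)
        omega = 2 * np.pi * 1.5e7
        z = coupled_resonator_load(omega, p)
        oracle = _oracle_load(omega, p)
        assert z == pytest.approx(oracle, rel=1e-12)

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(
        f_ratio=st.floats(min_value=0.05, max_value=20.0),
        gamma=st.floats(min_value=0.01, max_value=1.0),
    )
    def test_oracle_agreement_over_parameter_space(self, f_ratio, gamma):
        p = _params(gamma=gamma)
        omega = f_ratio * p.omega_p
        assert coupled_resonator_load(omega, p) == pytest.approx(
            _oracle_load(omega, p), rel=1e-10
        )

    def test_lossless_pole_raises(self):
        p = _params(gamma=0.0)
        with pytest.raises(SingularLoadError):
            coupled_resonator_load(p.omega_p, p)

    def test_zero_density_zero_load(self, sensor):
        p = _params(n_s=0.0, gamma=0.1)
        for n in sensor.overtones:
            resp = small_load_shifts(
                coupled_resonator_load(sensor.angular_frequency(n), p), n, sensor
            )
            assert resp.df == 0.0 and resp.dd == 0.0


class TestSmallLoadShifts:
    def test_inertial_load_reproduces_sauerbrey_with_zero_dissipation(
        self, sensor
    ):
        m_a = 2.053e-6  # kg/m^2
        n = 3
        omega = sensor.angular_frequency(n)
        resp = small_load_shifts(1j * omega * m_a, n, sensor)
        assert resp.df == pytest.approx(-35.0, abs=0.01)
        assert resp.dd == pytest.approx(0.0, abs=1e-12)
        # exact closed form
        assert resp.df == pytest.approx(
            -2 * n * sensor.f0**2 * m_a / sensor.Zq, rel=1e-12
        )

    @pytest.mark.parametrize("gamma", [0.0, 0.05, 0.3, 1.0])
    def test_dissipation_nonnegative_for_passive_bond(self, gamma, sensor):
        p = _params(f_p_hz=2.0e7, gamma=gamma)
        for n in sensor.overtones:
            omega = sensor.angular_frequency(n)
            if gamma == 0.0 and abs(omega - p.omega_p) < 1e-6 * p.omega_p:
                continue
            resp = small_load_shifts(
                coupled_resonator_load(omega, p), n, sensor
            )
            assert resp.dd >= -1e-15

    def test_sign_pattern_straddles_bond_resonance(self, sensor):
        # bond resonance at 20 MHz: inertial (negative) at n=3 (15 MHz),
        # elastic (positive) at n=13 (65 MHz)
        p = _params(f_p_hz=2.0e7, gamma=0.1)
        low = small_load_shifts(
            coupled_resonator_load(sensor.angular_frequency(3), p), 3, sensor
        )
        high = small_load_shifts(
            coupled_resonator_load(sensor.angular_frequency(13), p), 13, sensor
        )
        assert low.df < 0 < high.df


class TestModelInvariants:
    def test_sauerbrey_equivalence_in_deep_inertial_regime(self, sensor):
        p = _params(f_p_hz=1.0e10, gamma=0.0)  # omega_p >> all overtones
        for n in sensor.overtones:
            omega = sensor.angular_frequency(n)
            assert omega <= p.omega_p / 100
            resp = small_load_shifts(coupled_resonator_load(omega, p), n, sensor)
            sauerbrey = -2 * n * sensor.f0**2 * (p.N_s * p.m_p) / sensor.Zq
            assert abs(resp.df - sauerbrey) / abs(sauerbrey) < 1e-3

    def test_lossless_shift_changes_sign_exactly_at_bond_resonance(self):
        p = _params(f_p_hz=2.0e7, gamma=0.0)

        def df_at(omega):
            return (1j * coupled_resonator_load(omega, p)).real

        # dense grid on both sides: exactly one sign change
        grid = np.concatenate(
            [
                np.linspace(0.01, 0.999, 400) * p.omega_p,
                np.linspace(1.001, 5.0, 400) * p.omega_p,
            ]
        )
        signs = np.sign([df_at(w) for w in grid])
        assert np.count_nonzero(np.diff(signs)) == 1
        # bisection brackets the crossing tightly around omega_p (stopping
        # short of the lossless pole itself)
        lo, hi = 0.5 * p.omega_p, 2.0 * p.omega_p
        while (hi - lo) / p.omega_p > 1e-9:
            mid = 0.5 * (lo + hi)
            if df_at(mid) < 0:
                lo = mid
            else:
                hi = mid
        assert lo <= p.omega_p <= hi
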