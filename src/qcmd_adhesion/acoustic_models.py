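"""Closed-form acoustics of a particle-loaded shear resonator.

Three pieces of physics drive every interpretation step in this package:

* the evanescent shear wave penetration depth ``delta(n)`` of a Newtonian
  liquid, which sets how far above the sensor each overtone "sees";
* the Sauerbrey relation between frequency shift and rigidly coupled areal
  mass, valid in the thin-rigid-film (inertial) limit; and
* the coupled-resonator (particle-on-a-spring) load, which explains why a
  micron-sized body tethered to the sensor through a stiff point contact can
  *raise* the resonance frequency (elastic loading, positive Delta f) at
  overtones above the bond resonance omega_p = sqrt(k/m_p).

All shift calculations go through the small-load approximation: for an areal
load impedance Z_L acting on the crystal face,

    Delta f_n    = (f0 / (pi * Zq)) * Re(i * Z_L(omega_n))
    Delta Gamma  = (f0 / (pi * Zq)) * Im(i * Z_L(omega_n))
    Delta D_n    = 2 * Delta Gamma / (n * f0)      (reported in ppm)

with the sign convention anchored so that a purely inertial load
Z_L = i * omega * m_a reproduces the Sauerbrey shift
Delta f_n = -2 n f0^2 m_a / Zq exactly, with zero dissipation.

Bond damping enters as a complex stiffness ``k (1 + i gamma)``; the loss
tangent ``gamma`` keeps the system passive (Delta D >= 0) and removes the
lossless pole at omega = omega_p.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import SingularLoadError
from .qcm_io import SensorParams

__all__ = [
    "FluidProperties",
    "CoupledResonatorParams",
    "OvertoneResponse",
    "penetration_depth",
    "sauerbrey_areal_mass",
    "coupled_resonator_load",
    "small_load_shifts",
    "DEFAULT_FLUID",
]

#: kg/m^2 -> ng/cm^2
_KG_M2_TO_NG_CM2 = 1.0e8


@dataclass(frozen=True)
class FluidProperties:
    """Newtonian medium adjacent to the sensor.

    Defaults describe phosphate-buffered saline near room temperature
    (eta = 0.98 mPa s, rho = 1000 kg/m^3), back-solved so that the printed
    penetration depths for a 5 MHz sensor round to 144 / 112 / 75 nm at
    n = 3 / 5 / 11.
    """

    eta: float = 9.8e-4  # dynamic viscosity, Pa s
    rho: float = 1000.0  # density, kg/m^3

    def __post_init__(self):
        if not (self.eta > 0 and self.rho > 0):
            raise ValueError("fluid viscosity and density must be positive")


DEFAULT_FLUID = FluidProperties()


@dataclass(frozen=True)
class CoupledResonatorParams:
    """A monolayer of identical tethered particles as a distributed load.

    m_p : per-particle mass, kg (a hydrated E. coli cell is ~1 pg)
    k   : stiffness of the particle-surface bond, N/m
    gamma : loss tangent of the bond (>= 0, dimensionless)
    N_s : particles per unit area, m^-2
    """

    m_p: float
    k: float
    gamma: float = 0.0
    N_s: float = 0.0

    def __post_init__(self):
        if not self.m_p > 0:
            raise ValueError("m_p must be positive")
        if not self.k > 0:
            raise ValueError("k must be positive")
        if self.gamma < 0:
            raise ValueError("gamma must be >= 0")
        if self.N_s < 0:
            raise ValueError("N_s must be >= 0")

    @property
    def omega_p(self) -> float:
        """Undamped particle (bond) resonance sqrt(k/m_p), rad/s."""
        return float(np.sqrt(self.k / self.m_p))


@dataclass(frozen=True)
class OvertoneResponse:
    """Frequency (Hz) and dissipation (ppm) shift at one overtone."""

    n: int
    df: float
    dd: float

    def __post_init__(self):
        if self.n < 1 or self.n % 2 == 0:
            raise ValueError("overtone must be an odd positive integer")


def penetration_depth(
    n: int,
    sensor: SensorParams | None = None,
    fluid: FluidProperties | None = None,
) -> float:
    """Shear-wave penetration depth ``delta`` at overtone ``n``, in nm.

    delta = sqrt(2 eta / (rho * 2 pi n f0)); strictly decreasing in n
    (delta ~ n^-1/2), so higher overtones probe thinner liquid slices.
    """
    sensor = sensor or SensorParams()
    fluid = fluid or DEFAULT_FLUID
    if n < 1:
        raise ValueError("overtone must be >= 1")
    omega = 2.0 * np.pi * n * sensor.f0
    delta_m = np.sqrt(2.0 * fluid.eta / (fluid.rho * omega))
    return float(delta_m * 1e9)


def sauerbrey_areal_mass(
    df_n: float, n: int, sensor: SensorParams | None = None
) -> float:
    """Rigidly coupled areal mass (ng/cm^2) from a raw frequency shift.

    m_a = -Zq * Delta f_n / (2 n f0^2); positive for negative shifts.
    Valid only for thin rigid films -- the comparison against microscopy
    counts in :mod:`.mass_reconciliation` probes exactly where it fails.
    """
    sensor = sensor or SensorParams()
    m_a = -sensor.Zq * df_n / (2.0 * n * sensor.f0**2)
    return float(m_a * _KG_M2_TO_NG_CM2)


def coupled_resonator_load(
    omega: float, params: CoupledResonatorParams
) -> complex:
    """Areal load impedance of the tethered-particle layer at ``omega``.

    Z_L(omega) = i (N_s m_p) omega * omega_p*^2 / (omega_p*^2 - omega^2)

    with complex bond resonance omega_p*^2 = k (1 + i gamma) / m_p.  Below
    the bond resonance the layer loads the crystal inertially (Sauerbrey
    limit as omega -> 0); far above it the bond acts as a pure spring,
    Z_L -> -i N_s k / omega, which raises the resonance frequency.
    """
    if not omega > 0:
        raise ValueError("omega must be positive")
    omega_p = params.omega_p
    if params.gamma == 0 and abs(omega - omega_p) <= 1e-12 * omega_p:
        raise SingularLoadError(
            "lossless coupled resonator evaluated at its pole omega == omega_p"
        )
    wp2 = params.k * (1.0 + 1j * params.gamma) / params.m_p
    return complex(
        1j * params.N_s * params.m_p * omega * wp2 / (wp2 - omega**2)
    )


def small_load_shifts(
    Z_L: complex, n: int, sensor: SensorParams | None = None
) -> OvertoneResponse:
    """Convert an areal load impedance into (Delta f, Delta D) at overtone n.

    The half-bandwidth shift Delta Gamma is folded into the dissipation
    factor Delta D = 2 Delta Gamma / (n f0), reported in ppm.
    """
    sensor = sensor or SensorParams()
    pref = sensor.f0 / (np.pi * sensor.Zq)
    iz = 1j * Z_L
    df = pref * iz.real
    dgamma = pref * iz.imag
    dd_ppm = 2.0 * dgamma / (n * sensor.f0) * 1e6
    return OvertoneResponse(n=n, df=float(df), dd=float(dd_ppm))
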