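"""Seeded forward simulation of complete QCM-D adhesion experiments.

Every analysis stage in this package is exercised against traces produced
here, so the generator carries the same physical and statistical structure
the analysis assumes:

* a population of identical tethered particles (cells) whose areal density
  ``N_s(t)`` follows attachment kinetics -- a fast initial-contact term, a
  slow accumulation term, an optional overshoot-recovery (initial mass that
  detaches again), an optional late "hook" detachment and a rinse step;
* the coupled-resonator load of that population, evaluated per overtone
  through :func:`~qcmd_adhesion.acoustic_models.small_load_shifts`, which
  yields the inertial / mixed / elastic sign structure depending on where
  the bond resonance omega_p sits relative to the measured overtone
  frequencies;
* a phenomenological trapped-water dissipation channel with its own
  kinetics.  A point-bond loss tangent alone cannot produce dissipation of
  the magnitude real bacterial adlayers show (viscous losses live in the
  water trapped at the interfaces, not in the tether), so the D channel is
  the sum of the small physical bond loss and this water term, scaled by
  sqrt(3/n) to mimic the shrinking sampled volume at higher overtones;
* i.i.d. Gaussian measurement noise, seeded.

Saturating terms use a *clamped* exponential rise that reaches its target
exactly at ``RISE_CLAMP`` time constants and is exactly constant afterwards.
This keeps the familiar exponential shape while giving the trace true
plateaus, so the generator can state its equilibrium values and change-point
times exactly (they double as the ground truth for recovery tests).

Six presets (c8_like, nh2_like, cooh_like, oh_like, oeg_like, sb_like) are
shipped as YAML files and emulate the adhesion archetypes on the
corresponding self-assembled monolayer chemistries: inertial-rigid,
inertial-dissipative with overshoot, and elastic (positive shifts at high
or at all overtones).
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import yaml

from .acoustic_models import (
    CoupledResonatorParams,
    FluidProperties,
    coupled_resonator_load,
    small_load_shifts,
)
from .errors import ConfigurationError
from .qcm_io import QcmTrace, SensorParams

__all__ = [
    "Kinetics",
    "AdhesionArchetype",
    "SimulationTruth",
    "SurfaceDensitySpec",
    "simulate_experiment",
    "generate_cell_density_table",
    "load_archetype",
    "preset_names",
    "RISE_CLAMP",
    "ARCHETYPE_CATEGORIES",
]

#: number of time constants after which a saturating rise is exactly complete
RISE_CLAMP = 4.0

ARCHETYPE_CATEGORIES = (
    "inertial_rigid",
    "inertial_dissipative",
    "elastic_mixed",
    "elastic_full",
)


def clamped_rise(dt, tau: float, clamp: float = RISE_CLAMP):
    """Normalized saturating rise: 0 at dt <= 0, exactly 1 at dt >= clamp*tau.

    (1 - exp(-x/tau)) / (1 - exp(-clamp)) with x clipped to [0, clamp*tau].
    """
    if not tau > 0:
        raise ValueError("time constant must be positive")
    x = np.clip(np.asarray(dt, dtype=float), 0.0, clamp * tau)
    return -np.expm1(-x / tau) / -np.expm1(-clamp)


@dataclass(frozen=True)
class Kinetics:
    """Attachment kinetics, anchored in Hz at the reference overtone (n = 3).

    Frequency channel (amplitudes are the equilibrium shift each term would
    contribute at the reference overtone; signs follow the loading regime,
    negative for inertial, positive for elastic surfaces):

    initial_amp_hz / initial_tau_h : fast initial-contact term
    accum_amp_hz / accum_tau_h     : slow accumulation term
    overshoot_recovery             : fraction of attached material that
                                     detaches again (0..1), tau recovery_tau_h
    hook_onset_h / hook_amp_hz /
    hook_tau_h                     : late detachment; onset is hours after
                                     injection; amplitude is signed opposite
                                     the plateau (toward zero)
    rinse_recovery                 : fraction removed by the buffer rinse
                                     (0..1), tau rinse_tau_h

    Dissipation (trapped-water) channel, in ppm at the reference overtone:

    dd_fast_ppm / dd_fast_tau_h, dd_slow_ppm / dd_slow_tau_h, dd_hook_ppm
    """

    initial_amp_hz: float = -12.0
    initial_tau_h: float = 0.025
    accum_amp_hz: float = -23.0
    accum_tau_h: float = 3.75
    overshoot_recovery: float = 0.0
    recovery_tau_h: float = 4.0
    hook_onset_h: float | None = None
    hook_amp_hz: float = 0.0
    hook_tau_h: float = 0.5
    rinse_recovery: float = 0.02
    rinse_tau_h: float = 0.1
    dd_fast_ppm: float = 2.0
    dd_fast_tau_h: float = 0.025
    dd_slow_ppm: float = 10.0
    dd_slow_tau_h: float = 0.5
    dd_hook_ppm: float = 0.0

    def __post_init__(self):
        for name in (
            "initial_tau_h", "accum_tau_h", "recovery_tau_h", "hook_tau_h",
            "rinse_tau_h", "dd_fast_tau_h", "dd_slow_tau_h",
        ):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be positive")
        for name in ("overshoot_recovery", "rinse_recovery"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.dd_fast_ppm < 0 or self.dd_slow_ppm < 0:
            raise ValueError("dissipation amplitudes must be >= 0")

    def frequency_anchor(self, dt, t_rinse_rel) -> np.ndarray:
        """Target Delta f at the reference overtone vs time since injection."""
        attach = self.initial_amp_hz * clamped_rise(dt, self.initial_tau_h)
        attach = attach + self.accum_amp_hz * clamped_rise(dt, self.accum_tau_h)
        g = attach * (
            1.0 - self.overshoot_recovery * clamped_rise(dt, self.recovery_tau_h)
        )
        if self.hook_onset_h is not None:
            g = g + self.hook_amp_hz * clamped_rise(
                dt - self.hook_onset_h, self.hook_tau_h
            )
        g = g * (
            1.0 - self.rinse_recovery * clamped_rise(dt - t_rinse_rel,
                                                     self.rinse_tau_h)
        )
        return g

    def water_dissipation(self, dt, t_rinse_rel) -> np.ndarray:
        """Trapped-water Delta D (ppm at reference overtone) vs time."""
        w = self.dd_fast_ppm * clamped_rise(dt, self.dd_fast_tau_h)
        w = w + self.dd_slow_ppm * clamped_rise(dt, self.dd_slow_tau_h)
        if self.hook_onset_h is not None:
            w = w - self.dd_hook_ppm * clamped_rise(
                dt - self.hook_onset_h, self.hook_tau_h
            )
        w = w * (
            1.0 - self.rinse_recovery * clamped_rise(dt - t_rinse_rel,
                                                     self.rinse_tau_h)
        )
        return w


@dataclass(frozen=True)
class AdhesionArchetype:
    """One simulated surface chemistry: kinetics + bond physics + noise.

    category     : which region of the inertial/elastic spectrum the mature
                   bond resonance must occupy (validated against the sensor's
                   overtone frequencies at simulation time)
    bond_freq_hz : bond resonance omega_p / 2 pi of a tethered cell
    gamma        : bond loss tangent
    m_p_kg       : per-cell mass (hydrated E. coli ~ 1 pg)
    sigma_f / sigma_d : Gaussian noise levels per sample (Hz, ppm)
    """

    category: str
    surface_label: str
    kinetics: Kinetics = field(default_factory=Kinetics)
    bond_freq_hz: float = 1.5e8
    gamma: float = 0.05
    m_p_kg: float = 1.0e-15
    sigma_f: float = 0.2
    sigma_d: float = 0.1
    baseline_start_h: float = 0.0
    injection_h: float = 1.0
    rinse_h: float = 47.5
    duration_h: float = 50.0
    dt_h: float = 0.01
    ref_overtone: int = 3

    def __post_init__(self):
        if self.category not in ARCHETYPE_CATEGORIES:
            raise ConfigurationError(
                f"unknown archetype category {self.category!r}"
            )
        if not (self.baseline_start_h < self.injection_h < self.rinse_h
                < self.duration_h):
            raise ConfigurationError(
                "events must satisfy baseline_start < injection < rinse "
                "< duration"
            )
        if not (self.bond_freq_hz > 0 and self.m_p_kg > 0):
            raise ConfigurationError("bond_freq_hz and m_p_kg must be positive")
        if self.gamma < 0:
            raise ConfigurationError("gamma must be >= 0")
        if self.sigma_f < 0 or self.sigma_d < 0:
            raise ConfigurationError("noise levels must be >= 0")

    @property
    def events(self) -> dict[str, float]:
        return {
            "baseline_start": self.baseline_start_h,
            "injection": self.injection_h,
            "rinse": self.rinse_h,
        }

    def resonator_params(self, n_s: float = 1.0) -> CoupledResonatorParams:
        omega_p = 2.0 * np.pi * self.bond_freq_hz
        return CoupledResonatorParams(
            m_p=self.m_p_kg,
            k=self.m_p_kg * omega_p**2,
            gamma=self.gamma,
            N_s=n_s,
        )


@dataclass(frozen=True)
class SimulationTruth:
    """Generator-side ground truth accompanying a simulated trace.

    df_eq / dd_eq    : exact noiseless equilibrium shift per overtone
                       (post-rinse plateau minus baseline)
    change_points_h  : absolute times (hours) of the kinetic knots between
                       injection and rinse -- end of the fast contact rise,
                       end of the trapped-water buildup, end of the slow
                       accumulation, and the hook onset when present
    n_s_plateau      : areal cell density at equilibrium, m^-2
    omega_p          : mature bond resonance, rad/s
    """

    surface_label: str
    category: str
    df_eq: dict[int, float]
    dd_eq: dict[int, float]
    change_points_h: tuple[float, ...]
    has_hook: bool
    n_s_plateau: float
    omega_p: float


def _validate_bond_placement(
    archetype: AdhesionArchetype, sensor: SensorParams
) -> None:
    omega_p = 2.0 * np.pi * archetype.bond_freq_hz
    freqs = [sensor.angular_frequency(n) for n in sensor.overtones]
    cat = archetype.category
    if cat in ("inertial_rigid", "inertial_dissipative"):
        ok = omega_p > max(freqs)
        need = "above the highest measured overtone frequency"
    elif cat == "elastic_full":
        ok = omega_p < min(freqs)
        need = "below the lowest measured overtone frequency"
    else:  # elastic_mixed
        ok = any(
            lo < omega_p < hi for lo, hi in zip(freqs, freqs[1:])
        )
        need = "strictly between two adjacent measured overtone frequencies"
    if not ok:
        raise ConfigurationError(
            f"archetype {archetype.surface_label!r} ({cat}): bond resonance "
            f"{archetype.bond_freq_hz:.4g} Hz must lie {need}"
        )


def simulate_experiment(
    archetype: AdhesionArchetype,
    sensor: SensorParams | None = None,
    fluid: FluidProperties | None = None,
    seed: int = 0,
) -> tuple[QcmTrace, SimulationTruth]:
    """Simulate one experiment; deterministic given (archetype, seed).

    ``fluid`` is accepted for interface symmetry with the analysis functions
    but does not enter the trace: shifts are differential against the buffer
    baseline, so the Newtonian liquid loading cancels.
    """
    sensor = sensor or SensorParams()
    _validate_bond_placement(archetype, sensor)
    kin = archetype.kinetics

    if archetype.ref_overtone not in sensor.overtones:
        raise ConfigurationError(
            f"reference overtone {archetype.ref_overtone} is not measured"
        )

    # per-particle unit responses at every overtone
    unit = archetype.resonator_params(n_s=1.0)
    unit_df = np.empty(len(sensor.overtones))
    unit_dd = np.empty(len(sensor.overtones))
    for j, n in enumerate(sensor.overtones):
        resp = small_load_shifts(
            coupled_resonator_load(sensor.angular_frequency(n), unit), n, sensor
        )
        unit_df[j] = resp.df
        unit_dd[j] = resp.dd
    ref_j = sensor.overtones.index(archetype.ref_overtone)
    if unit_df[ref_j] == 0.0:
        raise ConfigurationError(
            "per-particle response vanishes at the reference overtone; "
            "cannot anchor the kinetics"
        )

    time = np.arange(
        0.0, archetype.duration_h + 0.5 * archetype.dt_h, archetype.dt_h
    )
    dt_inj = time - archetype.injection_h
    t_rinse_rel = archetype.rinse_h - archetype.injection_h

    g = kin.frequency_anchor(dt_inj, t_rinse_rel)  # Hz at reference overtone
    n_s = g / unit_df[ref_j]
    if np.any(n_s < -1e-9):
        raise ConfigurationError(
            "kinetics drive the areal density negative; check amplitude "
            "signs against the archetype's loading regime"
        )
    n_s = np.maximum(n_s, 0.0)
    water = kin.water_dissipation(dt_inj, t_rinse_rel)
    if np.any(water < -1e-9):
        raise ConfigurationError("trapped-water dissipation went negative")
    water = np.maximum(water, 0.0)

    overtone_arr = np.asarray(sensor.overtones, dtype=float)
    water_scale = np.sqrt(archetype.ref_overtone / overtone_arr)
    df = n_s[:, None] * unit_df[None, :]
    dd = n_s[:, None] * unit_dd[None, :] + water[:, None] * water_scale[None, :]

    truth = SimulationTruth(
        surface_label=archetype.surface_label,
        category=archetype.category,
        df_eq={int(n): float(df[-1, j]) for j, n in enumerate(sensor.overtones)},
        dd_eq={int(n): float(dd[-1, j]) for j, n in enumerate(sensor.overtones)},
        change_points_h=_change_points(archetype),
        has_hook=kin.hook_onset_h is not None,
        n_s_plateau=float(n_s[-1]),
        omega_p=2.0 * np.pi * archetype.bond_freq_hz,
    )

    rng = np.random.default_rng(seed)
    if archetype.sigma_f > 0:
        df = df + rng.normal(0.0, archetype.sigma_f, size=df.shape)
    if archetype.sigma_d > 0:
        dd = dd + rng.normal(0.0, archetype.sigma_d, size=dd.shape)

    trace = QcmTrace(
        time=time,
        df=df,
        dd=dd,
        events=archetype.events,
        sensor=sensor,
        surface_label=archetype.surface_label,
    )
    return trace, truth


def _change_points(archetype: AdhesionArchetype) -> tuple[float, ...]:
    kin = archetype.kinetics
    cps = {
        round(archetype.injection_h + RISE_CLAMP * kin.initial_tau_h, 9),
        round(archetype.injection_h + RISE_CLAMP * kin.dd_slow_tau_h, 9),
        round(archetype.injection_h + RISE_CLAMP * kin.accum_tau_h, 9),
    }
    if kin.hook_onset_h is not None:
        cps.add(round(archetype.injection_h + kin.hook_onset_h, 9))
    return tuple(sorted(cp for cp in cps if cp < archetype.rinse_h))


# ---------------------------------------------------------------------------
# Cell-density tables
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SurfaceDensitySpec:
    """Target mean cell density for one simulated surface."""

    surface_label: str
    mean_density: float  # cells/mm^2
    n_fields: int = 6
    field_area_mm2: float = 0.01  # ~100 um x 100 um micrograph field

    def __post_init__(self):
        if self.mean_density < 0:
            raise ConfigurationError("mean_density must be >= 0")
        if self.n_fields < 1:
            raise ConfigurationError("n_fields must be >= 1")
        if not self.field_area_mm2 > 0:
            raise ConfigurationError("field_area_mm2 must be positive")


def generate_cell_density_table(
    surface_specs: list[SurfaceDensitySpec], seed: int = 0
):
    """Poisson-sampled per-field counts summarized as cells/mm^2 records."""
    from .mass_reconciliation import CellDensityRecord

    rng = np.random.default_rng(seed)
    records = []
    for spec in surface_specs:
        lam = spec.mean_density * spec.field_area_mm2
        counts = rng.poisson(lam, size=spec.n_fields)
        densities = counts / spec.field_area_mm2
        sd = float(np.std(densities, ddof=1)) if spec.n_fields > 1 else 0.0
        records.append(
            CellDensityRecord(
                surface_label=spec.surface_label,
                density=float(np.mean(densities)),
                density_sd=sd,
                n_fields=spec.n_fields,
            )
        )
    return records


# ---------------------------------------------------------------------------
# Presets
# ---------------------------------------------------------------------------

def preset_names() -> list[str]:
    """Names of the packaged archetype presets."""
    root = importlib.resources.files("qcmd_adhesion") / "presets"
    return sorted(p.name[:-5] for p in root.iterdir() if p.name.endswith(".yaml"))


def load_archetype(name_or_path: str, **overrides) -> AdhesionArchetype:
    """Load a packaged preset by name (e.g. ``"c8_like"``) or a YAML path.

    Keyword overrides replace top-level archetype fields; a ``kinetics``
    override may be a partial dict merged into the preset's kinetics.
    """
    path = Path(str(name_or_path))
    if path.suffix in (".yaml", ".yml") and path.exists():
        raw = yaml.safe_load(path.read_text())
    else:
        resource = (
            importlib.resources.files("qcmd_adhesion")
            / "presets" / f"{name_or_path}.yaml"
        )
        if not resource.is_file():
            raise ConfigurationError(
                f"unknown preset {name_or_path!r}; available: {preset_names()}"
            )
        raw = yaml.safe_load(resource.read_text())

    kin_kwargs = dict(raw.pop("kinetics", {}))
    kin_override = overrides.pop("kinetics", None)
    if isinstance(kin_override, Kinetics):
        kinetics = kin_override
    else:
        if kin_override:
            kin_kwargs.update(kin_override)
        kinetics = Kinetics(**kin_kwargs)
    raw.update(overrides)
    return AdhesionArchetype(kinetics=kinetics, **raw)
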