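"""Zero-crossing detection and bacterium-surface distance bounds.

The sign of the equilibrium frequency shift at each overtone discriminates
two loading regimes: inertial (negative shift; the acoustic wave still
reaches the cell body) and elastic (positive shift; only the tethering
appendages lie within the sampled depth).  Because the penetration depth
delta(n) shrinks with overtone number, the overtone at which the shifts
change sign -- the zero-crossing frequency f_ZC -- brackets the distance of
the cell body from the surface between two penetration depths:

* all shifts negative          -> inertial regime, direct surface contact
  (no numeric bound is reported);
* single - to + crossing       -> mixed regime; the cell body sits below the
  depth of the last inertial overtone: d < delta(n_last_negative);
* all shifts positive          -> elastic regime; the body is beyond reach of
  even the deepest wave: d > delta(smallest measured n).

Sign calls use a dead-band: shifts smaller than ``max(z * sd, abs_tol)`` are
indeterminate and are skipped when locating the crossing, so noisy
near-zero overtones cannot corrupt the bracket.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .acoustic_models import FluidProperties, penetration_depth
from .errors import AmbiguousSignPatternError, InsufficientSignalError
from .qcm_io import SensorParams
from .trace_analysis import OvertoneShiftSet

__all__ = [
    "DeadBand",
    "DistanceEstimate",
    "sign_pattern",
    "estimate_distance",
    "distance_report",
]


@dataclass(frozen=True)
class DeadBand:
    """Indeterminate-sign threshold: |df_eq| <= max(z * df_sd, abs_tol)."""

    z: float = 1.0
    abs_tol: float = 0.5  # Hz

    def threshold(self, sd: np.ndarray) -> np.ndarray:
        return np.maximum(self.z * np.asarray(sd, dtype=float), self.abs_tol)


@dataclass(frozen=True)
class DistanceEstimate:
    """Adhesion regime and distance bound deduced from the sign pattern.

    regime         : 'inertial', 'mixed' or 'elastic'
    zc_bracket     : (n_low, n_high) overtone pair straddling the zero
                     crossing, or None when there is no crossing within the
                     measured range
    bound_direction: 'contact' (direct contact, no numeric bound),
                     'upper' (d < bound_nm) or 'lower' (d > bound_nm)
    bound_nm       : numeric distance bound, nm (None in the contact case)
    depth_table    : penetration depth per measured overtone, nm
    """

    regime: str
    zc_bracket: tuple[int, int] | None
    bound_direction: str
    bound_nm: float | None
    depth_table: dict[int, float]

    def __post_init__(self):
        if self.regime not in ("inertial", "mixed", "elastic"):
            raise ValueError(f"unknown regime {self.regime!r}")
        if self.regime == "inertial":
            if self.bound_direction != "contact" or self.zc_bracket is not None:
                raise ValueError("inertial regime implies direct contact")
            if self.bound_nm is not None:
                raise ValueError("no numeric bound is defined for contact")
        elif self.regime == "mixed":
            if self.bound_direction != "upper" or self.zc_bracket is None:
                raise ValueError("mixed regime implies an upper bound")
            if self.bound_nm != self.depth_table[self.zc_bracket[0]]:
                raise ValueError(
                    "mixed-regime bound must equal the depth at the "
                    "bracket's lower overtone"
                )
        else:  # elastic
            if self.bound_direction != "lower" or self.zc_bracket is not None:
                raise ValueError("elastic regime implies a lower bound")
            n_min = min(self.depth_table)
            if self.bound_nm != self.depth_table[n_min]:
                raise ValueError(
                    "elastic-regime bound must equal the depth at the "
                    "smallest measured overtone"
                )


def sign_pattern(
    shifts: OvertoneShiftSet, dead_band: DeadBand | None = None
) -> np.ndarray:
    """Dead-banded shift signs per overtone: -1, 0 (indeterminate) or +1.

    Validates that the determinate signs are single-crossing (all negatives
    precede all positives with increasing overtone); any other arrangement
    is not interpretable under the zero-crossing model and raises
    :class:`AmbiguousSignPatternError`.
    """
    dead_band = dead_band or DeadBand()
    df = np.asarray(shifts.df_eq, dtype=float)
    thr = dead_band.threshold(shifts.df_sd)
    signs = np.where(np.abs(df) <= thr, 0, np.sign(df)).astype(int)
    det = signs[signs != 0]
    if len(det) and np.any(np.diff(det) < 0):  # a -1 after a +1
        pattern = ", ".join(
            {1: "+", -1: "-", 0: "?"}[s] for s in signs
        )
        raise AmbiguousSignPatternError(
            f"determinate signs ({pattern}) are not monotone; more than one "
            "sign change cannot be interpreted as a single zero crossing"
        )
    return signs


def estimate_distance(
    shifts: OvertoneShiftSet,
    sensor: SensorParams | None = None,
    fluid: FluidProperties | None = None,
    dead_band: DeadBand | None = None,
) -> DistanceEstimate:
    """Distance bound for the cell body from the equilibrium sign pattern.

    The bound uses the penetration depth at the *last negative* overtone
    (not an interpolated crossing frequency), so a crossing between n = 3
    and n = 5 on a 5 MHz sensor reports d < delta(3).
    """
    sensor = sensor or SensorParams()
    signs = sign_pattern(shifts, dead_band)
    overtones = np.asarray(shifts.overtones, dtype=int)
    depth_table = {
        int(n): penetration_depth(int(n), sensor, fluid) for n in overtones
    }
    det = signs != 0
    if not np.any(det):
        raise InsufficientSignalError(
            "every overtone shift lies inside the dead-band; no regime call"
        )
    neg = overtones[(signs == -1)]
    pos = overtones[(signs == +1)]
    if len(pos) == 0:
        return DistanceEstimate(
            regime="inertial",
            zc_bracket=None,
            bound_direction="contact",
            bound_nm=None,
            depth_table=depth_table,
        )
    if len(neg) == 0:
        n_min = int(overtones.min())
        return DistanceEstimate(
            regime="elastic",
            zc_bracket=None,
            bound_direction="lower",
            bound_nm=depth_table[n_min],
            depth_table=depth_table,
        )
    n_low = int(neg.max())
    n_high = int(pos.min())
    return DistanceEstimate(
        regime="mixed",
        zc_bracket=(n_low, n_high),
        bound_direction="upper",
        bound_nm=depth_table[n_low],
        depth_table=depth_table,
    )


def distance_report(estimate: DistanceEstimate, surface_label: str = "") -> dict:
    """JSON-serializable summary of one surface's distance estimate."""
    return {
        "surface_label": surface_label,
        "regime": estimate.regime,
        "zc_bracket": list(estimate.zc_bracket) if estimate.zc_bracket else None,
        "bound_direction": estimate.bound_direction,
        "bound_nm": estimate.bound_nm,
        "depth_table_nm": {str(k): v for k, v in estimate.depth_table.items()},
    }
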