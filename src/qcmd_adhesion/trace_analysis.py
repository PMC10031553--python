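"""Equilibrium shift extraction, rigidity ratios and adhesion-phase segmentation.

Equilibrium shifts follow the standard differential protocol: the trace is
split by its event annotations into (i) a buffer baseline before injection,
(ii) contact with the cell suspension and (iii) a post-rinse plateau; the
equilibrium shift per overtone is the mean over a stable trailing window of
(iii) minus the mean over a stable trailing window of (i).  "Stable" means
the fitted slope magnitude of the window is below a tolerance; window
selection is the longest trailing window (at candidate-step resolution)
that passes, never shorter than ``min_duration``.

The D-versus-f trajectory from injection to rinse is segmented into the
qualitative adhesion phases seen in long bacterial adhesion runs:

* ``contact_initiation``  - rapid frequency drop as first cells arrive;
* ``soft_buildup``        - dissipation grows much faster per Hz than in the
                            initial contact (soft, weakly bound cell layers);
* ``rigid_plateau``       - dissipation flat while mass may still accrue;
* ``reversal_drift``      - frequency relaxing toward positive at ~flat D
                            (loss of rigidly coupled mass);
* ``hook``                - simultaneous f increase and D decrease sustained
                            for >= 1 h, the late partial-detachment signature.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .errors import (
    SegmentationError,
    StabilizationError,
    UndefinedRatioError,
)
from .qcm_io import QcmTrace

__all__ = [
    "StableWindow",
    "WindowingParams",
    "OvertoneShiftSet",
    "SegmentationParams",
    "PhaseSegment",
    "stable_window",
    "extract_equilibrium_shifts",
    "dissipation_frequency_ratio",
    "segment_phases",
    "PHASE_LABELS",
]

PHASE_LABELS = (
    "contact_initiation",
    "soft_buildup",
    "rigid_plateau",
    "reversal_drift",
    "hook",
)


@dataclass(frozen=True)
class StableWindow:
    """A trailing averaging window together with its summary statistics."""

    t_start: float
    t_end: float
    mean: float
    sd: float
    slope: float
    n_samples: int


@dataclass(frozen=True)
class WindowingParams:
    """Stabilization-window settings for equilibrium extraction.

    min_duration : shortest acceptable window, hours (default 30 min)
    slope_tol_f  : stationarity tolerance for frequency series, Hz/h
    slope_tol_d  : stationarity tolerance for dissipation series, ppm/h
    slope_z      : a window also passes when its slope lies within this
                   many standard errors of zero (noise-floor allowance)
    """

    min_duration: float = 0.5
    slope_tol_f: float = 0.5
    slope_tol_d: float = 0.1
    slope_z: float = 4.0


@dataclass
class OvertoneShiftSet:
    """Equilibrium Delta f / Delta D per overtone with window uncertainties."""

    overtones: tuple[int, ...]
    df_eq: np.ndarray
    dd_eq: np.ndarray
    df_sd: np.ndarray
    dd_sd: np.ndarray

    def __post_init__(self):
        self.overtones = tuple(int(n) for n in self.overtones)
        for name in ("df_eq", "dd_eq", "df_sd", "dd_sd"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.shape != (len(self.overtones),):
                raise ValueError(f"{name} must have one entry per overtone")
            setattr(self, name, arr)
        if np.any(self.df_sd < 0) or np.any(self.dd_sd < 0):
            raise ValueError("standard deviations must be >= 0")

    def overtone_index(self, n: int) -> int:
        return self.overtones.index(n)

    def as_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "overtone": self.overtones,
                "df_eq_hz": self.df_eq,
                "dd_eq_ppm": self.dd_eq,
                "df_sd_hz": self.df_sd,
                "dd_sd_ppm": self.dd_sd,
            }
        )


def _ols_slope(t: np.ndarray, y: np.ndarray) -> float:
    t = t - t.mean()
    denom = float(np.dot(t, t))
    if denom == 0.0:
        return 0.0
    return float(np.dot(t, y - y.mean()) / denom)


def _ols_slope_se(t: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """OLS slope and its standard error from the fit residuals."""
    tc = t - t.mean()
    denom = float(np.dot(tc, tc))
    if denom == 0.0 or len(t) < 3:
        return 0.0, 0.0
    slope = float(np.dot(tc, y - y.mean()) / denom)
    resid = (y - y.mean()) - slope * tc
    sigma2 = float(np.dot(resid, resid)) / (len(t) - 2)
    return slope, float(np.sqrt(sigma2 / denom))


def _theil_slope(t: np.ndarray, y: np.ndarray, max_points: int = 201) -> float:
    if len(t) > max_points:
        idx = np.linspace(0, len(t) - 1, max_points).round().astype(int)
        t, y = t[idx], y[idx]
    if np.ptp(y) == 0.0:
        return 0.0
    return float(stats.theilslopes(y, t).slope)


def _window_slope(t: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Conservative stationarity slope and its noise floor.

    Returns ``(slope, se)`` where ``slope`` is the larger magnitude of the
    OLS and Theil-Sen fits and ``se`` the OLS slope standard error.  The
    robust (median-pairwise) slope alone is blind to a localized step or
    transient inside an otherwise flat window, while the OLS slope alone is
    noise-sensitive; taking the max of both rejects windows that still
    contain a settling transient.
    """
    ols, se = _ols_slope_se(t, y)
    return max(abs(ols), abs(_theil_slope(t, y))), se


def stable_window(
    time: np.ndarray,
    values: np.ndarray,
    t_end: float,
    min_duration: float = 0.5,
    slope_tol: float = 0.5,
    slope_z: float = 4.0,
) -> StableWindow:
    """Longest trailing window ending at ``t_end`` with slope <= ``slope_tol``.

    Candidate window starts are scanned from the beginning of the series
    toward ``t_end - min_duration`` at a resolution of ``min_duration / 2``;
    the first (i.e. longest) candidate whose fitted slope magnitude passes
    is returned.  A window passes when its slope is below ``slope_tol`` or
    statistically indistinguishable from zero (within ``slope_z`` standard
    errors of the fit), so measurement noise alone cannot block
    stabilization however tight the tolerance.  Raises
    :class:`StabilizationError` carrying the best achieved slope when no
    candidate passes.
    """
    time = np.asarray(time, dtype=float)
    values = np.asarray(values, dtype=float)
    stop = int(np.searchsorted(time, t_end, side="right"))
    t = time[:stop]
    y = values[:stop]
    if len(t) < 3 or (t_end - t[0]) < min_duration:
        raise ValueError(
            f"series covers {t_end - t[0] if len(t) else 0.0:.3g} h before "
            f"t_end; need at least min_duration = {min_duration} h"
        )
    step = min_duration / 2.0
    starts = np.arange(t[0], t_end - min_duration + 1e-12, step)
    if len(starts) == 0 or starts[-1] < t_end - min_duration - 1e-12:
        starts = np.append(starts, t_end - min_duration)

    best = np.inf
    for s in starts:
        lo = int(np.searchsorted(t, s - 1e-12, side="left"))
        tw, yw = t[lo:], y[lo:]
        if len(tw) < 3:
            continue
        slope, se = _window_slope(tw, yw)
        if slope <= max(slope_tol, slope_z * se):
            sd = float(np.std(yw, ddof=1))
            return StableWindow(
                t_start=float(tw[0]),
                t_end=float(t_end),
                mean=float(np.mean(yw)),
                sd=sd,
                slope=float(slope),
                n_samples=len(yw),
            )
        best = min(best, slope)
    raise StabilizationError(
        f"no trailing window of >= {min_duration} h ending at t = {t_end} h "
        f"reached slope tolerance {slope_tol}; best achieved slope was "
        f"{best:.4g}",
        best_slope=float(best),
    )


def extract_equilibrium_shifts(
    trace: QcmTrace, windowing: WindowingParams | None = None
) -> OvertoneShiftSet:
    """Equilibrium shifts per overtone: post-rinse plateau minus baseline.

    For every measured overtone the baseline window ends at the injection
    event and the equilibrium window ends at the last sample (restricted to
    the post-rinse region), so the result is invariant under any constant
    offset of the raw series.  Window standard deviations are propagated in
    quadrature.
    """
    windowing = windowing or WindowingParams()
    t = trace.time
    t_inj = trace.events["injection"]
    t_rinse = trace.events["rinse"]
    rinse_lo = int(np.searchsorted(t, t_rinse, side="left"))
    t_post = t[rinse_lo:]

    df_eq, dd_eq, df_sd, dd_sd = [], [], [], []
    for j, n in enumerate(trace.sensor.overtones):
        for channel, series, tol, out_eq, out_sd in (
            ("f", trace.df[:, j], windowing.slope_tol_f, df_eq, df_sd),
            ("D", trace.dd[:, j], windowing.slope_tol_d, dd_eq, dd_sd),
        ):
            try:
                base = stable_window(
                    t, series, t_end=t_inj,
                    min_duration=windowing.min_duration, slope_tol=tol,
                    slope_z=windowing.slope_z,
                )
                plateau = stable_window(
                    t_post, series[rinse_lo:], t_end=float(t[-1]),
                    min_duration=windowing.min_duration, slope_tol=tol,
                    slope_z=windowing.slope_z,
                )
            except StabilizationError as err:
                raise StabilizationError(
                    f"overtone n={n}, channel {channel}: {err}",
                    best_slope=err.best_slope,
                ) from err
            out_eq.append(plateau.mean - base.mean)
            out_sd.append(float(np.hypot(plateau.sd, base.sd)))
    return OvertoneShiftSet(
        overtones=trace.sensor.overtones,
        df_eq=np.array(df_eq),
        dd_eq=np.array(dd_eq),
        df_sd=np.array(df_sd),
        dd_sd=np.array(dd_sd),
    )


def dissipation_frequency_ratio(dd_eq: float, df_eq: float) -> float:
    """|Delta D / Delta f| in ppm/Hz -- the mass-independent rigidity metric.

    Low values indicate rigid, well-coupled adlayers; high values soft,
    hydrated ones.  Reported as a magnitude; raises
    :class:`UndefinedRatioError` for a zero frequency shift.
    """
    if df_eq == 0:
        raise UndefinedRatioError(
            "Delta D / Delta f is undefined for Delta f = 0"
        )
    return abs(dd_eq / df_eq)


# ---------------------------------------------------------------------------
# Phase segmentation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SegmentationParams:
    """Tunables of the D-versus-f phase segmentation.

    window            : sliding-window span for local slope estimates, hours;
                        also the tolerance within which detected boundaries
                        should be trusted.
    steepening        : factor by which dD/df must exceed the initial-contact
                        slope to call ``soft_buildup``.
    slope_tol_f       : |df/dt| below this (Hz/h) counts as "f flat".
    slope_tol_d       : |dD/dt| below this (ppm/h) counts as "D flat".
    min_segment       : runs shorter than this (hours) are absorbed into the
                        preceding segment (the first segment is exempt, so a
                        brief initial contact survives).
    hook_min_duration : minimum sustained duration (hours) for a hook call.
    noise_margin      : additive Gaussian noise level (ppm) up to which the
                        labelling is expected to be stable.
    """

    window: float = 0.5
    steepening: float = 2.0
    slope_tol_f: float = 0.5
    slope_tol_d: float = 0.1
    min_segment: float = 0.5
    hook_min_duration: float = 1.0
    noise_margin: float = 0.05


@dataclass(frozen=True)
class PhaseSegment:
    """One labelled phase of the D-versus-f trajectory."""

    label: str
    t_start: float
    t_end: float
    slope_dd_df: float

    def __post_init__(self):
        if self.label not in PHASE_LABELS:
            raise ValueError(f"unknown phase label {self.label!r}")
        if not self.t_start < self.t_end:
            raise ValueError("t_start must be < t_end")


def _rolling_slope(t: np.ndarray, y: np.ndarray, window: float) -> np.ndarray:
    """Centered local linear-fit slope of y(t) on a near-uniform grid."""
    from scipy.ndimage import uniform_filter1d

    dt = float(np.median(np.diff(t)))
    k = max(3, int(round(window / dt)) | 1)  # odd window length
    mt = uniform_filter1d(t, k, mode="nearest")
    my = uniform_filter1d(y, k, mode="nearest")
    mty = uniform_filter1d(t * y, k, mode="nearest")
    mtt = uniform_filter1d(t * t, k, mode="nearest")
    var = mtt - mt * mt
    cov = mty - mt * my
    with np.errstate(invalid="ignore", divide="ignore"):
        slope = np.where(var > 0, cov / np.where(var > 0, var, 1.0), 0.0)
    return slope


# internal per-point states
_S_BUILD_SHALLOW, _S_BUILD_STEEP, _S_PLATEAU, _S_REVERSAL, _S_HOOK = range(5)

_STATE_LABEL = {
    _S_BUILD_SHALLOW: "contact_initiation",
    _S_BUILD_STEEP: "soft_buildup",
    _S_PLATEAU: "rigid_plateau",
    _S_REVERSAL: "reversal_drift",
    _S_HOOK: "hook",
}


def segment_phases(
    trace: QcmTrace, n: int, params: SegmentationParams | None = None
) -> list[PhaseSegment]:
    """Piecewise segmentation of the (Delta f, Delta D) trajectory at overtone n.

    Operates on the injection-to-rinse interval.  Local df/dt and dD/dt are
    estimated by sliding-window linear fits; each sample is classified by
    direction rules (see module docstring), consecutive equal states are
    merged, and runs shorter than ``min_segment`` are absorbed into their
    predecessor.  A hook call must be sustained for ``hook_min_duration``,
    otherwise it is demoted to ``reversal_drift``.
    """
    params = params or SegmentationParams()
    j = trace.overtone_index(n)
    t_inj = trace.events["injection"]
    t_rinse = trace.events["rinse"]
    lo = int(np.searchsorted(trace.time, t_inj, side="left"))
    hi = int(np.searchsorted(trace.time, t_rinse, side="right"))
    t = trace.time[lo:hi]
    f = trace.df[lo:hi, j]
    d = trace.dd[lo:hi, j]
    if len(t) < 6 or (t[-1] - t[0]) < 3.0 * params.window:
        raise SegmentationError(
            "trace spans less than three change-point windows between "
            "injection and rinse"
        )

    vf = _rolling_slope(t, f, params.window)
    vd = _rolling_slope(t, d, params.window)
    ftol, dtol = params.slope_tol_f, params.slope_tol_d

    # slope of the D-vs-f trajectory, floored to avoid division blow-ups
    s = np.abs(vd) / np.maximum(np.abs(vf), ftol)
    # reference slope of the contact-initiation step: taken at the fastest
    # frequency drop within the first window, where initial attachment
    # dominates over any later soft-layer buildup
    ref_sel = np.flatnonzero(t <= t[0] + params.window)
    i_ref = ref_sel[np.argmax(np.abs(vf[ref_sel]))] if len(ref_sel) else 0
    s_ref = max(float(s[i_ref]), 1e-12)

    states = np.empty(len(t), dtype=int)
    for i in range(len(t)):
        if vf[i] > ftol and vd[i] < -dtol:
            states[i] = _S_HOOK
        elif vd[i] > dtol:
            states[i] = (
                _S_BUILD_STEEP
                if s[i] >= params.steepening * s_ref
                else _S_BUILD_SHALLOW
            )
        elif vf[i] > ftol:
            states[i] = _S_REVERSAL
        else:
            states[i] = _S_PLATEAU

    # run-length encode
    runs: list[list] = []  # [state, i_start, i_end)
    start = 0
    for i in range(1, len(states) + 1):
        if i == len(states) or states[i] != states[start]:
            runs.append([int(states[start]), start, i])
            start = i

    def _duration(run):
        return t[run[2] - 1] - t[run[1]]

    # absorb short runs into the preceding run (first run exempt) and merge
    # adjacent runs that end up in the same state
    merged = [runs[0]]
    for run in runs[1:]:
        if run[0] == merged[-1][0] or _duration(run) < params.min_segment:
            merged[-1][2] = run[2]
        else:
            merged.append(run)

    # demote unsustained hooks
    for run in merged:
        if run[0] == _S_HOOK and _duration(run) < params.hook_min_duration:
            run[0] = _S_REVERSAL

    # map states to final labels, then merge adjacent equal labels
    labelled: list[list] = []
    for idx, (state, i0, i1) in enumerate(merged):
        label = _STATE_LABEL[state]
        if idx == 0 and state in (_S_BUILD_SHALLOW, _S_BUILD_STEEP):
            label = "contact_initiation"
        elif state == _S_BUILD_SHALLOW:
            label = "soft_buildup"
        if labelled and labelled[-1][0] == label:
            labelled[-1][2] = i1
        else:
            labelled.append([label, i0, i1])

    segments: list[PhaseSegment] = []
    for label, i0, i1 in labelled:
        segments.append(
            PhaseSegment(
                label,
                float(t[i0]),
                float(t[i1 - 1]),
                _dd_df_slope(f[i0:i1], d[i0:i1]),
            )
        )
    return segments


def _dd_df_slope(f: np.ndarray, d: np.ndarray) -> float:
    """OLS slope of D against f over a segment, ppm/Hz (nan if degenerate)."""
    if len(f) < 2 or np.ptp(f) == 0.0:
        return float("nan")
    return _ols_slope(f, d)


def segments_as_frame(segments: Sequence[PhaseSegment]):
    import pandas as pd

    return pd.DataFrame(
        {
            "label": [s.label for s in segments],
            "t_start_h": [s.t_start for s in segments],
            "t_end_h": [s.t_end for s in segments],
            "slope_dd_df_ppm_per_hz": [s.slope_dd_df for s in segments],
        }
    )
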