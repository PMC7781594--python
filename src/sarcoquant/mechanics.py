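"""Passive and active fiber force-trace analysis.

Protocol segmentation from the sarcomere-length channel, elastic/viscous
decomposition of ramp-hold responses, time-matched cleavage-timecourse
normalization, force-vs-intact-titin regression, and active force drop.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.ndimage import gaussian_filter1d

from . import defaults
from .core import ForceTrace

__all__ = [
    "Phase",
    "ViscoelasticSummary",
    "TimecourseResult",
    "CorrelationFit",
    "ActivationResult",
    "segment_protocol",
    "decompose_viscoelastic",
    "normalize_timecourse",
    "percent_force_removed",
    "titin_force_correlation",
    "active_force_drop",
]


@dataclass
class Phase:
    kind: str            # ramp | hold | release
    start: int           # index range [start, stop)
    stop: int
    target_sl_um: float


@dataclass
class ViscoelasticSummary:
    per_sl: pd.DataFrame          # sl_um, elastic, viscous, peak
    normalization_reference: Optional[float] = None


@dataclass
class TimecourseResult:
    sample_times_min: np.ndarray
    normalized_force: np.ndarray
    control_reference: str = "time-matched control mean"

    def __post_init__(self) -> None:
        self.sample_times_min = np.asarray(self.sample_times_min, dtype=float)
        self.normalized_force = np.asarray(self.normalized_force, dtype=float)


@dataclass
class CorrelationFit:
    sl_um: float
    slope: float
    intercept: float
    r_squared: float
    ci95_band: dict = field(default_factory=dict)

    @property
    def strength_class(self) -> str:
        return "weak" if self.r_squared < 0.5 else "strong"


@dataclass
class ActivationResult:
    steady_state_first: float
    steady_state_second: float
    percent_drop: float
    control_corrected_drop: Optional[float] = None


# ---------------------------------------------------------------------------
# protocol segmentation
# ---------------------------------------------------------------------------

def segment_protocol(
    trace: ForceTrace,
    speed_threshold_um_s: float = 0.02,
    smooth_s: float = 0.15,
    min_phase_s: float = 0.25,
) -> list:
    """Detect ramp/hold/release phases from the SL-channel derivative.

    The SL channel is Gaussian-smoothed before differentiation and a 2:1
    hysteresis is applied to the speed threshold (enter a ramp above the
    threshold, return to hold below half of it), which makes the
    segmentation stable under percent-level SL noise.
    """
    sl = trace.sl_um
    t = trace.time_s
    if np.ptp(sl) < 1e-9:
        raise ValueError("SL channel is constant: no protocol to segment")
    fs = 1.0 / trace.dt
    sigma = max(1.0, smooth_s * fs)
    sl_s = gaussian_filter1d(sl, sigma)
    v = np.gradient(sl_s, t)

    hi, lo = speed_threshold_um_s, speed_threshold_um_s / 2.0
    states = np.zeros(len(v), dtype=int)  # 0 hold, +1 ramp, -1 release
    state = 0
    for i, vi in enumerate(v):
        if state == 0:
            if vi > hi:
                state = 1
            elif vi < -hi:
                state = -1
        elif abs(vi) < lo or np.sign(vi) != state:
            state = 0
        states[i] = state

    raw = []
    start = 0
    min_n = max(1, int(min_phase_s * fs))
    for i in range(1, len(states) + 1):
        if i == len(states) or states[i] != states[start]:
            if i - start >= min_n:
                raw.append((states[start], start, i))
            elif raw:
                raw[-1] = (raw[-1][0], raw[-1][1], i)
            start = i
    if not any(s != 0 for s, _, _ in raw):
        raise ValueError("SL channel shows no length changes above threshold")

    # Gaussian smoothing delays the hysteresis exit; snap ramp edges to the
    # half-maximum crossings of the speed profile, which blur preserves
    bounds = []
    for state, i0, i1 in raw:
        if state == 0:
            bounds.append([i0, i1])
            continue
        seg_v = np.abs(v[i0:i1])
        v_plateau = float(np.median(seg_v[seg_v > seg_v.max() / 2.0]))
        above = np.nonzero(seg_v >= v_plateau / 2.0)[0]
        bounds.append([i0 + int(above[0]), i0 + int(above[-1]) + 1])
    # keep the cover contiguous: holds absorb what the ramps released
    for k in range(1, len(bounds)):
        bounds[k][0] = max(bounds[k][0], bounds[k - 1][1])
        if k + 1 < len(bounds):
            bounds[k][1] = min(bounds[k][1], bounds[k + 1][0] + 1)
    for k, (state, _, _) in enumerate(raw):
        if state == 0:
            lo_i = bounds[k - 1][1] if k > 0 else 0
            hi_i = bounds[k + 1][0] if k + 1 < len(bounds) else len(states)
            bounds[k] = [lo_i, hi_i]

    phases = []
    for (state, _, _), (i0, i1) in zip(raw, bounds):
        if i1 <= i0:
            continue
        kind = {0: "hold", 1: "ramp", -1: "release"}[state]
        target = float(np.median(sl[i0:i1])) if kind == "hold" else float(sl_s[i1 - 1])
        phases.append(Phase(kind, i0, i1, target))
    return phases


# ---------------------------------------------------------------------------
# elastic / viscous decomposition
# ---------------------------------------------------------------------------

def decompose_viscoelastic(
    trace: ForceTrace,
    phases: Optional[list] = None,
    elastic_window_s: float = 1.0,
    ramp_peak_fraction: float = 0.05,
    normalize_to: Optional[float] = None,
) -> ViscoelasticSummary:
    """Split each ramp-hold step into elastic and viscous tension.

    Per hold following a stretch ramp: elastic = mean force over the final
    ``elastic_window_s`` of the hold; peak = maximum force within the
    terminal ``ramp_peak_fraction`` of the ramp; viscous = peak - elastic.
    ``normalize_to`` divides all components (e.g. by the maximum peak force
    of the pre-treatment run).
    """
    if phases is None:
        phases = segment_protocol(trace)
    fs = 1.0 / trace.dt
    rows = []
    for prev, cur in zip(phases, phases[1:]):
        if prev.kind != "ramp" or cur.kind != "hold":
            continue
        n_win = int(elastic_window_s * fs)
        hold_n = cur.stop - cur.start
        if hold_n < n_win:
            warnings.warn("hold shorter than the elastic averaging window; window shrunk")
            n_win = hold_n
        elastic = float(np.mean(trace.force[cur.stop - n_win:cur.stop]))
        ramp_n = prev.stop - prev.start
        tail = max(1, int(np.ceil(ramp_peak_fraction * ramp_n)))
        peak = float(np.max(trace.force[prev.stop - tail:prev.stop]))
        rows.append((cur.target_sl_um, elastic, peak - elastic, peak))
    if not rows:
        raise ValueError("no ramp-hold pair found in the trace")

    df = pd.DataFrame(rows, columns=["sl_um", "elastic", "viscous", "peak"])
    if normalize_to is not None:
        if normalize_to <= 0:
            raise ValueError("normalization reference must be positive")
        df[["elastic", "viscous", "peak"]] /= normalize_to
    return ViscoelasticSummary(per_sl=df, normalization_reference=normalize_to)


# ---------------------------------------------------------------------------
# cleavage timecourse
# ---------------------------------------------------------------------------

def normalize_timecourse(
    treated,
    controls,
    sample_times_min=defaults.TIMECOURSE_SAMPLE_MIN,
) -> TimecourseResult:
    """Treated force over the time-matched control mean, self-normalised at t=0.

    ``treated`` is a ForceTrace or list of them; ``controls`` a list.
    Each treated trace is divided by the mean control force interpolated at
    its own time points, then by its own value at t = 0, and finally the
    treated traces are averaged and sampled at the stated time grid.
    """
    if isinstance(treated, ForceTrace):
        treated = [treated]
    if isinstance(controls, ForceTrace):
        controls = [controls]
    if not treated or not controls:
        raise ValueError("need at least one treated and one control trace")

    grid_s = np.asarray(sample_times_min, dtype=float) * 60.0
    sampled = []
    for tr in treated:
        ctrl = np.mean(
            [np.interp(tr.time_s, c.time_s, c.force) for c in controls], axis=0
        )
        if np.any(ctrl <= 0):
            raise ValueError("control mean force is non-positive somewhere on the grid")
        ratio = tr.force / ctrl
        at0 = np.interp(0.0, tr.time_s, ratio)
        if at0 == 0:
            raise ValueError("treated/control ratio is zero at t=0")
        sampled.append(np.interp(grid_s, tr.time_s, ratio / at0))

    return TimecourseResult(
        sample_times_min=np.asarray(sample_times_min, dtype=float),
        normalized_force=np.mean(sampled, axis=0),
    )


def percent_force_removed(before: float, after: float) -> float:
    """Percent of force removed by treatment: 100 * (before - after) / before."""
    if before <= 0:
        raise ValueError("pre-treatment force must be positive")
    return 100.0 * (before - after) / before


# ---------------------------------------------------------------------------
# force vs intact-titin correlation
# ---------------------------------------------------------------------------

def titin_force_correlation(
    forces,
    intact_fractions,
    sl_um: float,
    ci_points: int = 50,
) -> CorrelationFit:
    """OLS of normalized force on intact-titin fraction at one SL.

    Returns slope, intercept, R^2 and a 95% confidence band on the mean
    response (evaluated on a grid spanning the data); fits with R^2 below
    0.5 are classed ``weak``, others ``strong``.
    """
    y = np.asarray(forces, dtype=float)
    x = np.asarray(intact_fractions, dtype=float)
    if len(y) < 3 or len(x) != len(y):
        raise ValueError("need at least 3 matched (force, fraction) points")
    X = sm.add_constant(x)
    fit = sm.OLS(y, X).fit()
    grid = np.linspace(x.min(), x.max(), ci_points)
    pred = fit.get_prediction(sm.add_constant(grid)).summary_frame(alpha=0.05)
    return CorrelationFit(
        sl_um=sl_um,
        slope=float(fit.params[1]),
        intercept=float(fit.params[0]),
        r_squared=float(fit.rsquared),
        ci95_band={
            "x": grid.tolist(),
            "lower": pred["mean_ci_lower"].tolist(),
            "upper": pred["mean_ci_upper"].tolist(),
        },
    )


# ---------------------------------------------------------------------------
# active contractions
# ---------------------------------------------------------------------------

def _steady_state(trace: ForceTrace, window_s: float, slope_tol: float) -> float:
    fs = 1.0 / trace.dt
    n = int(window_s * fs)
    if n < 2 or n > len(trace.force):
        raise ValueError("trace shorter than the steady-state window")
    f = trace.force[-n:]
    t = trace.time_s[-n:]
    mean = float(np.mean(f))
    slope = float(np.polyfit(t, f, 1)[0])
    if mean <= 0:
        raise ValueError("non-positive steady-state force")
    if abs(slope) * window_s > slope_tol * mean:
        raise ValueError("no plateau detected: terminal slope above tolerance")
    return mean


def active_force_drop(
    first: ForceTrace,
    second: ForceTrace,
    control_pair: Optional[tuple] = None,
    steady_window_s: float = defaults.ACTIVE_STEADY_WINDOW_S,
    plateau_tolerance: float = 0.05,
) -> ActivationResult:
    """Percent drop in steady-state active force between two contractions.

    Steady state is the mean force over the final ``steady_window_s``; a
    trace whose force still changes by more than ``plateau_tolerance`` of
    its mean across that window is rejected as non-plateaued. With a
    ``control_pair`` of untreated contractions the drop is additionally
    control-corrected (treated drop minus control drop).
    """
    f1 = _steady_state(first, steady_window_s, plateau_tolerance)
    f2 = _steady_state(second, steady_window_s, plateau_tolerance)
    drop = 100.0 * (1.0 - f2 / f1)
    corrected = None
    if control_pair is not None:
        c1 = _steady_state(control_pair[0], steady_window_s, plateau_tolerance)
        c2 = _steady_state(control_pair[1], steady_window_s, plateau_tolerance)
        corrected = drop - 100.0 * (1.0 - c2 / c1)
    return ActivationResult(
        steady_state_first=f1,
        steady_state_second=f2,
        percent_drop=drop,
        control_corrected_drop=corrected,
    )
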