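"""Hertz spherical-indenter analysis of AFM force-distance curves.

Contact-point detection (baseline intersection refined by a 3/2-power fit),
Young's-modulus extraction via F = (4/3) (E / (1 - nu^2)) sqrt(R) delta^(3/2),
indentation depth at the trigger force, and grouped summaries.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from . import defaults
from .core import IndentationCurve

__all__ = [
    "HertzFit",
    "find_contact_point",
    "fit_hertz",
    "batch_summary",
    "percent_change",
]


@dataclass
class HertzFit:
    E_kpa: float
    nu: float
    contact_nm: float
    depth_at_trigger_nm: float
    residual_rms_nn: float
    fit_window_nm: tuple
    baseline_sd_nn: float = float("nan")
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.E_kpa <= 0:
            raise ValueError("fitted modulus must be positive")
        if self.depth_at_trigger_nm <= 0:
            raise ValueError("trigger depth must be positive")


def find_contact_point(
    curve: IndentationCurve,
    baseline_fraction: float = 0.25,
    rise_sd_factor: float = 5.0,
) -> float:
    """Locate the piezo position where the tip first touches the sample.

    The pre-contact baseline (first ``baseline_fraction`` of samples) gives
    a mean and noise SD; the crossing where force exceeds mean + 5 SD seeds
    a least-squares fit of ``b + a * max(0, z - z0)^(3/2)`` whose ``z0`` is
    returned. Stores the result on ``curve.contact_nm``.
    """
    z, f = curve.position_nm, curve.force_nn
    n_base = max(4, int(baseline_fraction * len(z)))
    base_mean = float(np.mean(f[:n_base]))
    base_sd = float(np.std(f[:n_base]))
    thresh = base_mean + rise_sd_factor * max(base_sd, 1e-12)
    above = np.nonzero(f > thresh)[0]
    if len(above) == 0:
        raise ValueError("no rising branch: force never exceeds baseline + 5 SD")
    i_cross = int(above[0])

    def model(zz, b, a, z0):
        return b + a * np.clip(zz - z0, 0.0, None) ** 1.5

    a0 = max((f[-1] - base_mean), 1e-9) / max((z[-1] - z[i_cross]), 1.0) ** 1.5
    p0 = [base_mean, a0, z[i_cross]]
    try:
        popt, _ = curve_fit(model, z, f, p0=p0, maxfev=20000)
        z0 = float(popt[2])
    except RuntimeError:
        z0 = float(z[i_cross])
    z0 = float(np.clip(z0, z[0], z[-1]))
    curve.contact_nm = z0
    return z0


def fit_hertz(
    curve: IndentationCurve,
    nu: float = defaults.POISSON_RATIO,
    radius_um: Optional[float] = None,
    trigger_nn: float = defaults.TRIGGER_FORCE_NN,
    max_delta_fraction: float = defaults.HERTZ_MAX_DELTA_FRACTION,
    min_samples: int = 20,
) -> HertzFit:
    """Least-squares Hertz fit past the contact point.

    Requires ``curve.contact_nm`` (run :func:`find_contact_point` first).
    When the probe carries a cantilever spring constant, the measured piezo
    travel is corrected for cantilever deflection (delta = z - z0 - F/k_C;
    note N/m == nN/nm). The fit domain is capped at ``max_delta_fraction``
    of the bead radius to stay within Hertz validity. The depth at the
    trigger force is interpolated on the measured curve.
    """
    if curve.contact_nm is None:
        raise ValueError("contact point not set; run find_contact_point first")
    R_um = radius_um if radius_um is not None else curve.probe.radius_um
    if R_um <= 0:
        raise ValueError("probe radius must be positive")

    delta_nm = curve.position_nm - curve.contact_nm
    k_c = curve.probe.spring_constant_n_per_m
    if k_c:
        delta_nm = delta_nm - curve.force_nn / k_c
    cap_nm = max_delta_fraction * R_um * 1e3
    sel = (delta_nm > 0) & (delta_nm <= cap_nm)
    if sel.sum() < min_samples:
        raise ValueError("fewer than the minimum samples past contact")

    d_m = delta_nm[sel] * 1e-9
    f_n = curve.force_nn[sel] * 1e-9
    g = d_m**1.5
    c = float(np.sum(f_n * g) / np.sum(g * g))
    if c <= 0:
        raise ValueError("negative fitted modulus: check the contact point")
    E_pa = c * 0.75 * (1.0 - nu**2) / np.sqrt(R_um * 1e-6)
    resid = f_n - c * g

    f_sel = curve.force_nn[sel]
    if f_sel.max() >= trigger_nn:
        order = np.argsort(f_sel)
        depth = float(np.interp(trigger_nn, f_sel[order], delta_nm[sel][order]))
    elif f_sel.max() >= 0.95 * trigger_nn:
        # noise can leave the truncated curve marginally short of the
        # trigger; invert the fitted Hertz form for the missing sliver
        depth = float((trigger_nn * 1e-9 / c) ** (2.0 / 3.0) * 1e9)
    else:
        raise ValueError("curve never reaches the trigger force")

    return HertzFit(
        E_kpa=E_pa / 1e3,
        nu=nu,
        contact_nm=float(curve.contact_nm),
        depth_at_trigger_nm=depth,
        residual_rms_nn=float(np.sqrt(np.mean(resid**2)) * 1e9),
        fit_window_nm=(float(delta_nm[sel].min()), float(delta_nm[sel].max())),
        meta={"radius_um": R_um, "trigger_nn": trigger_nn, "n_samples": int(sel.sum())},
    )


def percent_change(before: float, after: float, direction: str = "increase") -> float:
    """Percent change between group means.

    ``increase``: 100 * (after - before) / before (e.g. indentation depth);
    ``decrease``: 100 * (before - after) / before (e.g. Young's modulus).
    """
    if before <= 0:
        raise ValueError("reference value must be positive")
    if direction == "increase":
        return 100.0 * (after - before) / before
    if direction == "decrease":
        return 100.0 * (before - after) / before
    raise ValueError(f"unknown direction {direction!r}")


def batch_summary(fits: list, groups: list) -> pd.DataFrame:
    """Per-group mean and SEM of depth-at-trigger and Young's modulus.

    ``groups`` assigns a hashable group key to each fit; returns a frame
    indexed by group with columns for n, means and SEMs.
    """
    if len(fits) != len(groups):
        raise ValueError("fits and groups must have matching length")
    if not fits:
        raise ValueError("no fits to summarise")
    df = pd.DataFrame(
        {
            "group": groups,
            "depth_nm": [f.depth_at_trigger_nm for f in fits],
            "E_kpa": [f.E_kpa for f in fits],
        }
    )
    out = df.groupby("group").agg(
        n=("E_kpa", "size"),
        depth_mean_nm=("depth_nm", "mean"),
        depth_sem_nm=("depth_nm", "sem"),
        E_mean_kpa=("E_kpa", "mean"),
        E_sem_kpa=("E_kpa", "sem"),
    )
    if (out["n"] == 0).any():
        raise ValueError("empty group")
    return out
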