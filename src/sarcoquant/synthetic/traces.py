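"""Viscoelastic ramp-hold force traces from a generalized Maxwell model.

The length input is piecewise linear (ramps and holds); each Maxwell arm is
integrated exactly over every linear segment, so traces are analytic up to
additive noise. The titin-attributable share of the response is scaled by
``titin_fraction`` on top of a titin-independent ``baseline_fraction``:

    force = [baseline + (1 - baseline) * titin_fraction] * viscoelastic(t)
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .. import defaults
from ..core import ForceTrace

__all__ = ["ViscoelasticModelSpec", "gen_ramp_hold_trace", "default_protocol"]


@dataclass
class ViscoelasticModelSpec:
    """Generalized Maxwell (standard-linear-solid family) parameters.

    ``maxwell_arms`` is a list of ``(stiffness, relaxation_time_s)`` pairs;
    up to three arms are supported.
    """

    k_elastic: float
    maxwell_arms: list = field(default_factory=list)
    titin_fraction: float = 1.0
    baseline_fraction: float = 0.0
    noise_sd: float = 0.0
    slack_sl_um: float = defaults.SLACK_SL_UM

    def __post_init__(self) -> None:
        if not (0.0 <= self.titin_fraction <= 1.0):
            raise ValueError("titin_fraction must lie in [0, 1]")
        if not (0.0 <= self.baseline_fraction <= 1.0):
            raise ValueError("baseline_fraction must lie in [0, 1]")
        if self.k_elastic <= 0:
            raise ValueError("k_elastic must be positive")
        if len(self.maxwell_arms) > 3:
            raise ValueError("at most 3 Maxwell arms supported")
        for k, tau in self.maxwell_arms:
            if k <= 0 or tau <= 0:
                raise ValueError("arm stiffnesses and time constants must be positive")

    @property
    def scale(self) -> float:
        return self.baseline_fraction + (1.0 - self.baseline_fraction) * self.titin_fraction


def default_protocol(
    n_steps: int = defaults.N_RAMP_STEPS,
    step_um: float = defaults.RAMP_STEP_UM,
    speed_um_s: float = defaults.RAMP_SPEED_UM_PER_S,
    hold_s: float = defaults.HOLD_S,
) -> list:
    """The stepwise stretch-hold protocol: n equal ramps with holds."""
    return [(step_um, speed_um_s, hold_s)] * n_steps


def gen_ramp_hold_trace(
    model: ViscoelasticModelSpec,
    protocol: list,
    seed: int = 0,
    sampling_hz: float = defaults.SAMPLING_HZ,
    settle_s: float = 1.0,
) -> ForceTrace:
    """Simulate the model under a ramp-hold protocol.

    ``protocol`` is a list of ``(delta_sl_um, speed_um_per_s, hold_s)``
    tuples; negative deltas are releases. A ``settle_s`` rest at slack
    precedes the first ramp. The force channel is noiseless-exact except for
    the additive Gaussian noise of the model spec.
    """
    if not protocol:
        raise ValueError("protocol must be non-empty")
    for delta, speed, hold in protocol:
        if speed <= 0:
            raise ValueError("ramp speed must be positive")
        if hold < 0:
            raise ValueError("hold duration must be non-negative")

    # breakpoints: (t_start, duration, rate) for each linear segment of x(t)
    segments = [(0.0, settle_s, 0.0)] if settle_s > 0 else []
    t = settle_s
    for delta, speed, hold in protocol:
        ramp_t = abs(delta) / speed
        segments.append((t, ramp_t, delta / ramp_t))
        t += ramp_t
        if hold > 0:
            segments.append((t, hold, 0.0))
            t += hold
    total_t = t

    dt = 1.0 / sampling_hz
    time = np.arange(0.0, total_t + dt / 2.0, dt)
    x = np.zeros_like(time)      # SL - slack, um
    force = np.zeros_like(time)

    arms = [(k, tau) for k, tau in model.maxwell_arms]
    x0 = 0.0
    q = np.zeros(len(arms))
    for t0, dur, v in segments:
        sel = (time >= t0 - dt / 4.0) & (time < t0 + dur - dt / 4.0)
        s = time[sel] - t0
        x[sel] = x0 + v * s
        for j, (k, tau) in enumerate(arms):
            decay = np.exp(-s / tau)
            qj = q[j] * decay + v * tau * (1.0 - decay)
            force[sel] += k * qj
        # advance the state exactly to the segment end
        for j, (k, tau) in enumerate(arms):
            d_end = np.exp(-dur / tau)
            q[j] = q[j] * d_end + v * tau * (1.0 - d_end)
        x0 += v * dur

    # last sample (t == total_t) sits at the final state
    sel_last = time >= total_t - dt / 4.0
    x[sel_last] = x0
    for j, (k, _) in enumerate(arms):
        force[sel_last] += k * q[j]

    force += model.k_elastic * x
    force *= model.scale

    rng = np.random.default_rng(seed)
    if model.noise_sd > 0:
        force = force + rng.normal(0.0, model.noise_sd, size=force.shape)

    return ForceTrace(
        time_s=time,
        sl_um=model.slack_sl_um + x,
        force=force,
        force_units="normalized",
        meta={"model": "generalized_maxwell", "n_arms": len(arms), "seed": seed},
    )
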