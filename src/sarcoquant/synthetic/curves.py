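"""Synthetic spherical-indenter (Hertz) AFM force-distance curves."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .. import defaults
from ..core import IndentationCurve, Probe

__all__ = ["HertzCurveSpec", "gen_indentation_curve", "hertz_prefactor_si", "hertz_depth_at_force_nm"]


@dataclass
class HertzCurveSpec:
    """Ground-truth parameters of a spherical Hertz indentation."""

    E_kpa: float
    nu: float = defaults.POISSON_RATIO
    R_um: float = defaults.BEAD_RADIUS_UM
    contact_offset_nm: float = 500.0
    max_force_nn: float = defaults.TRIGGER_FORCE_NN
    noise_sd_nn: float = 0.0

    def __post_init__(self) -> None:
        if self.E_kpa <= 0:
            raise ValueError("E_kpa must be positive")
        if not (0.0 <= self.nu <= 0.5):
            raise ValueError("nu must lie in [0, 0.5]")
        if self.R_um <= 0:
            raise ValueError("R_um must be positive")
        if self.max_force_nn <= 0:
            raise ValueError("max_force_nn must be positive")


def hertz_prefactor_si(E_kpa: float, nu: float, R_um: float) -> float:
    """Prefactor a of F = a * delta^(3/2) in SI units (N / m^1.5)."""
    return (4.0 / 3.0) * (E_kpa * 1e3 / (1.0 - nu**2)) * np.sqrt(R_um * 1e-6)


def hertz_depth_at_force_nm(force_nn: float, E_kpa: float, nu: float, R_um: float) -> float:
    """Closed-form inversion: indentation depth (nm) at a given force (nN)."""
    a = hertz_prefactor_si(E_kpa, nu, R_um)
    return (force_nn * 1e-9 / a) ** (2.0 / 3.0) * 1e9


def gen_indentation_curve(
    spec: HertzCurveSpec,
    seed: int = 0,
    step_nm: float = 1.0,
    position_range_nm: float | None = None,
) -> IndentationCurve:
    """Sample an approach curve: flat noisy baseline, then the Hertz rise.

    The curve is truncated at the first sample reaching ``max_force_nn``
    (the trigger). If ``position_range_nm`` is given and the trigger force is
    unreachable within it, a ``ValueError`` is raised.
    """
    delta_max_nm = hertz_depth_at_force_nm(spec.max_force_nn, spec.E_kpa, spec.nu, spec.R_um)
    needed = spec.contact_offset_nm + delta_max_nm
    if position_range_nm is None:
        position_range_nm = needed + 2.0 * step_nm
    elif position_range_nm < needed:
        raise ValueError("trigger force unreachable within the position range")

    z = np.arange(0.0, position_range_nm + step_nm / 2.0, step_nm)
    delta_nm = np.clip(z - spec.contact_offset_nm, 0.0, None)
    a = hertz_prefactor_si(spec.E_kpa, spec.nu, spec.R_um)
    force_nn = a * (delta_nm * 1e-9) ** 1.5 * 1e9

    # truncate at the trigger, keeping the first crossing sample
    over = np.nonzero(force_nn >= spec.max_force_nn)[0]
    if len(over):
        cut = over[0] + 1
        z, force_nn = z[:cut], force_nn[:cut]

    rng = np.random.default_rng(seed)
    if spec.noise_sd_nn > 0:
        force_nn = force_nn + rng.normal(0.0, spec.noise_sd_nn, size=force_nn.shape)

    return IndentationCurve(
        position_nm=z,
        force_nn=force_nn,
        probe=Probe(radius_um=spec.R_um),
    )
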