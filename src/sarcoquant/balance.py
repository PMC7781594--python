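"""Order-of-magnitude force balance for thick-filament centering.

A thick filament displaced off-centre by d stretches the titins on one side
by d and slackens the other side by the same amount; with a linear
per-molecule stiffness around the operating point, the net restoring force
per filament follows directly. Two accounting conventions are supported:
``one-sided`` counts the n lengthening molecules, ``differential`` counts
both flanks (2n molecules).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

from . import defaults

__all__ = ["BalanceParams", "BalanceResult", "titin_length_change", "centering_force"]


@dataclass
class BalanceParams:
    n_titins_per_half_filament: int = defaults.N_TITINS_PER_HALF_FILAMENT
    filament_density_per_um2: float = defaults.FILAMENT_DENSITY_PER_UM2
    mband_max_extension_nm: float = defaults.MBAND_MAX_EXTENSION_NM
    per_molecule_force_pn_at_ref: float = defaults.PER_MOLECULE_FORCE_PN
    reference_displacement_nm: float = defaults.REFERENCE_DISPLACEMENT_NM
    target_load_pn: float = defaults.TARGET_LOAD_PN
    p0_fraction: Optional[float] = None

    def __post_init__(self) -> None:
        for name in (
            "n_titins_per_half_filament",
            "filament_density_per_um2",
            "mband_max_extension_nm",
            "per_molecule_force_pn_at_ref",
            "target_load_pn",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.reference_displacement_nm == 0:
            raise ValueError("reference displacement must be non-zero")
        if self.p0_fraction is not None and not (0.0 < self.p0_fraction <= 1.0):
            raise ValueError("p0_fraction must lie in (0, 1]")


@dataclass
class BalanceResult:
    displacement_nm: float
    delta_titin_length_nm: float
    centering_force_pn: float
    stiffness_multiplier_required: Optional[float]
    convention: str
    flags: list = field(default_factory=list)


def titin_length_change(
    displacement_nm: float,
    mband_max_extension_nm: float = defaults.MBAND_MAX_EXTENSION_NM,
) -> dict:
    """Per-molecule titin length change from a thick-filament displacement.

    Molecules on one side lengthen by d, on the other shorten by d; the
    displacement is limited to half the maximal M-band extension.
    """
    if displacement_nm < 0:
        raise ValueError("displacement must be non-negative")
    if displacement_nm > mband_max_extension_nm / 2.0:
        raise ValueError("displacement exceeds half the maximal M-band extension")
    return {
        "lengthening_nm": displacement_nm,
        "shortening_nm": -displacement_nm,
        "magnitude_nm": displacement_nm,
    }


def centering_force(
    params: BalanceParams,
    displacement_nm: float,
    convention: str = "one-sided",
) -> BalanceResult:
    """Net titin-based restoring force on a displaced thick filament.

    Linear stiffness model: each molecule's force change is
    F_ref * d / d_ref. ``one-sided`` sums the n lengthening molecules;
    ``differential`` additionally credits the slackening flank (2n). The
    stiffness multiplier is the factor by which per-molecule stiffness must
    grow for the centering force to match the target load; it is undefined
    (None, flagged) at zero displacement.
    """
    if convention not in ("one-sided", "differential"):
        raise ValueError(f"unknown convention {convention!r}")
    d = abs(displacement_nm)
    change = titin_length_change(d, params.mband_max_extension_nm)
    per_molecule_pn = params.per_molecule_force_pn_at_ref * (
        d / params.reference_displacement_nm
    )
    n = params.n_titins_per_half_filament
    n_effective = n if convention == "one-sided" else 2 * n
    net_pn = n_effective * per_molecule_pn

    flags = []
    if net_pn > 0:
        multiplier = params.target_load_pn / net_pn
    else:
        multiplier = None
        flags.append("multiplier undefined at zero displacement")

    return BalanceResult(
        displacement_nm=displacement_nm,
        delta_titin_length_nm=change["magnitude_nm"],
        centering_force_pn=net_pn,
        stiffness_multiplier_required=multiplier,
        convention=convention,
        flags=flags,
    )
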