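"""Synthetic gel-lane densitometry profiles: Gaussian bands on a sloped baseline."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import norm

from ..core import LaneProfile

__all__ = ["LaneSpec", "gen_gel_lane", "BAND_NAMES", "default_band_layout"]

BAND_NAMES = ("N2A_intact", "T2_Cronos", "AM_fragment", "ZI_fragment", "NEB", "MyHC")


def default_band_layout() -> tuple:
    """Relative migration positions and widths for the six named bands.

    Positions increase toward smaller species; values are conventional (gel
    mobility depends on the run) and widely separated so windows never clash.
    """
    positions = {
        "N2A_intact": 0.15,
        "T2_Cronos": 0.28,
        "AM_fragment": 0.36,
        "ZI_fragment": 0.55,
        "NEB": 0.70,
        "MyHC": 0.85,
    }
    widths = {name: 0.008 for name in positions}
    return positions, widths


@dataclass
class LaneSpec:
    """One lane: band positions/widths, true area composition, baseline, noise."""

    band_positions: dict
    band_widths: dict
    composition: dict
    baseline_slope: float = 0.0
    baseline_intercept: float = 0.05
    noise_sd: float = 0.0
    n_samples: int = 2000
    total_area: float = 1.0

    def __post_init__(self) -> None:
        for name in self.composition:
            if name not in BAND_NAMES:
                raise ValueError(f"unknown band name {name!r}")
            if self.composition[name] < 0:
                raise ValueError("composition values must be non-negative")
            if name not in self.band_positions or name not in self.band_widths:
                raise ValueError(f"band {name!r} missing position or width")
        # windows must be disjoint at 3 SD
        items = sorted(
            ((self.band_positions[n], self.band_widths[n]) for n in self.composition),
        )
        for (p0, w0), (p1, w1) in zip(items, items[1:]):
            if p1 - p0 < 3.0 * (w0 + w1):
                raise ValueError("band windows overlap at 3 SD")


def gen_gel_lane(spec: LaneSpec, seed: int = 0):
    """Render the lane profile; returns ``(LaneProfile, true_areas dict)``.

    Band areas are proportional to the composition (summing to
    ``total_area`` when compositions sum to 1); band windows are attached to
    the profile at +/- 3 SD around each band position.
    """
    rng = np.random.default_rng(seed)
    x = np.linspace(0.0, 1.0, spec.n_samples)
    profile = spec.baseline_intercept + spec.baseline_slope * x

    total = sum(spec.composition.values())
    true_areas = {}
    windows = {}
    for name, frac in spec.composition.items():
        area = spec.total_area * (frac / total) if total > 0 else 0.0
        pos, width = spec.band_positions[name], spec.band_widths[name]
        profile = profile + area * norm.pdf(x, loc=pos, scale=width)
        true_areas[name] = area
        windows[name] = (max(0.0, pos - 3.0 * width), min(1.0, pos + 3.0 * width))

    if spec.noise_sd > 0:
        profile = profile + rng.normal(0.0, spec.noise_sd, size=profile.shape)

    return LaneProfile(position=x, intensity=profile, band_windows=windows), true_areas
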