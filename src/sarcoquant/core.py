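"""Shared data containers used across all analysis stages."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

MODALITIES = ("EM", "IEM", "IF")


@dataclass
class Micrograph:
    """A calibrated 2-D grayscale raster.

    Attributes
    ----------
    pixels : ndarray
        2-D non-negative intensity array (float, arbitrary units).
    nm_per_px : float
        Pixel size in nanometres; must be positive.
    modality : str
        One of ``EM``, ``IEM``, ``IF``.
    """

    pixels: np.ndarray
    nm_per_px: float
    modality: str = "EM"

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=float)
        if self.pixels.ndim != 2:
            raise ValueError("micrograph must be a 2-D array")
        if not np.all(np.isfinite(self.pixels)):
            raise ValueError("micrograph contains non-finite values")
        if not (self.nm_per_px > 0):
            raise ValueError("nm_per_px must be positive")
        if self.modality not in MODALITIES:
            raise ValueError(f"modality must be one of {MODALITIES}")

    @property
    def shape(self) -> tuple:
        return self.pixels.shape

    @property
    def height_nm(self) -> float:
        return self.pixels.shape[0] * self.nm_per_px

    @property
    def width_nm(self) -> float:
        return self.pixels.shape[1] * self.nm_per_px


@dataclass
class ForceTrace:
    """Synchronised time / sarcomere-length / force series.

    ``force_units`` tags whether the force channel is absolute (``mN``) or
    pre-normalised (``normalized``); analyses never mix the two.
    """

    time_s: np.ndarray
    sl_um: np.ndarray
    force: np.ndarray
    force_units: str = "normalized"
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.time_s = np.asarray(self.time_s, dtype=float)
        self.sl_um = np.asarray(self.sl_um, dtype=float)
        self.force = np.asarray(self.force, dtype=float)
        n = len(self.time_s)
        if len(self.sl_um) != n or len(self.force) != n:
            raise ValueError("time, length and force channels must have equal length")
        if n > 1 and not np.all(np.diff(self.time_s) > 0):
            raise ValueError("time must be strictly increasing")

    @property
    def dt(self) -> float:
        return float(np.median(np.diff(self.time_s)))


@dataclass
class Probe:
    """AFM probe geometry: spherical tip radius and optional cantilever stiffness."""

    radius_um: float
    spring_constant_n_per_m: Optional[float] = None

    def __post_init__(self) -> None:
        if not (self.radius_um > 0):
            raise ValueError("probe radius must be positive")


@dataclass
class IndentationCurve:
    """AFM force-distance curve (approach branch)."""

    position_nm: np.ndarray
    force_nn: np.ndarray
    probe: Probe = field(default_factory=lambda: Probe(radius_um=5.0))
    contact_nm: Optional[float] = None

    def __post_init__(self) -> None:
        self.position_nm = np.asarray(self.position_nm, dtype=float)
        self.force_nn = np.asarray(self.force_nn, dtype=float)
        if self.position_nm.shape != self.force_nn.shape:
            raise ValueError("position and force arrays must have equal length")
        if not np.all(np.isfinite(self.force_nn)):
            raise ValueError("force contains non-finite values")


@dataclass
class LaneProfile:
    """1-D gel-lane densitometry profile along the migration axis."""

    position: np.ndarray
    intensity: np.ndarray
    band_windows: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.position.shape != self.intensity.shape:
            raise ValueError("position and intensity must have equal length")
        if len(self.position) > 1 and not np.all(np.diff(self.position) > 0):
            raise ValueError("position must be strictly increasing")
        lo, hi = self.position[0], self.position[-1]
        spans = sorted(self.band_windows.values())
        for a, b in spans:
            if not (a < b):
                raise ValueError("band window start must precede end")
            if a < lo or b > hi:
                raise ValueError("band window outside profile axis")
        for (_, b0), (a1, _) in zip(spans, spans[1:]):
            if a1 < b0:
                raise ValueError("band windows overlap")
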