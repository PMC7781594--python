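"""Readers and writers for the standard on-disk formats.

Micrographs travel as 16-bit grayscale TIFF with the pixel size stored in
the resolution tags (px/cm) and ground truth in a JSON sidecar; traces,
indentation curves and lane profiles are plain CSV.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .core import ForceTrace, IndentationCurve, LaneProfile, Micrograph, Probe


def write_micrograph(path, img: Micrograph, truth: dict | None = None) -> None:
    """16-bit TIFF with nm/px encoded in the resolution tags (px per cm)."""
    path = Path(path)
    lo, hi = img.pixels.min(), img.pixels.max()
    scale = (img.pixels - lo) / (hi - lo) if hi > lo else np.zeros_like(img.pixels)
    data = (scale * 65535).astype(np.uint16)
    px_per_cm = 1e7 / img.nm_per_px
    tifffile.imwrite(
        path,
        data,
        resolution=(px_per_cm, px_per_cm),
        resolutionunit="CENTIMETER",
        metadata={"nm_per_px": img.nm_per_px, "modality": img.modality},
    )
    if truth is not None:
        path.with_suffix(".truth.json").write_text(json.dumps(truth, indent=2))


def read_micrograph(path, nm_per_px: float | None = None, modality: str = "EM") -> Micrograph:
    path = Path(path)
    with tifffile.TiffFile(path) as tf:
        page = tf.pages[0]
        data = page.asarray().astype(float)
        if nm_per_px is None:
            try:
                xres = page.tags["XResolution"].value
                px_per_cm = xres[0] / xres[1]
                nm_per_px = 1e7 / px_per_cm
            except (KeyError, ZeroDivisionError):
                raise ValueError("no resolution tag; pass nm_per_px explicitly")
    return Micrograph(pixels=data, nm_per_px=nm_per_px, modality=modality)


def write_trace(path, trace: ForceTrace) -> None:
    pd.DataFrame(
        {"time_s": trace.time_s, "sl_um": trace.sl_um, "force": trace.force}
    ).to_csv(path, index=False)


def read_trace(path, force_units: str = "normalized", meta: dict | None = None) -> ForceTrace:
    df = pd.read_csv(path)
    return ForceTrace(
        time_s=df["time_s"].to_numpy(),
        sl_um=df["sl_um"].to_numpy(),
        force=df["force"].to_numpy(),
        force_units=force_units,
        meta=meta or {},
    )


def write_curve(path, curve: IndentationCurve) -> None:
    pd.DataFrame(
        {"position_nm": curve.position_nm, "force_nn": curve.force_nn}
    ).to_csv(path, index=False)


def read_curve(path, radius_um: float = 5.0, spring_constant: float | None = None) -> IndentationCurve:
    df = pd.read_csv(path)
    if "position_nm" in df.columns:
        position_nm = df["position_nm"].to_numpy()
    elif "position_um" in df.columns:
        position_nm = df["position_um"].to_numpy() * 1e3
    else:
        raise ValueError("curve CSV needs a position_nm or position_um column")
    return IndentationCurve(
        position_nm=position_nm,
        force_nn=df["force_nn"].to_numpy(),
        probe=Probe(radius_um=radius_um, spring_constant_n_per_m=spring_constant),
    )


def write_lane_profile(path, profile: LaneProfile) -> None:
    pd.DataFrame({"position": profile.position, "intensity": profile.intensity}).to_csv(
        path, index=False
    )


def read_lane_profile(path, band_windows: dict | None = None) -> LaneProfile:
    df = pd.read_csv(path)
    return LaneProfile(
        position=df["position"].to_numpy(),
        intensity=df["intensity"].to_numpy(),
        band_windows=band_windows or {},
    )
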