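"""Z-disk disorder quantification from electron micrographs.

The score ("fracture area", nm^2) measures how far segmented Z-disk lines
deviate from straightness and mutual parallelism:

1. dark transverse ridges are segmented to 1-px-wide pixel paths;
2. each path gets an orthogonal (total-least-squares) line fit;
3. per-segment mean squared orthogonal residuals are weighted by the
   segment's angular deviation from the length-weighted mean orientation,
   and averaged (length-weighted) across segments.

Straight, parallel Z-disks score zero; waviness and angular scatter both
increase the score.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.ndimage import gaussian_filter, map_coordinates
from skimage.feature import hessian_matrix, hessian_matrix_eigvals
from skimage.filters import threshold_otsu
from skimage.measure import label as cc_label
from skimage.morphology import closing, remove_small_objects, skeletonize

from . import defaults
from .core import Micrograph

__all__ = [
    "ZDiskSegment",
    "FractureResult",
    "segment_zdisks",
    "fit_segment_line",
    "fracture_area",
    "score_image",
]


@dataclass
class ZDiskSegment:
    """One candidate Z-disk line: pixel-path coordinates and (once fitted)
    its orthogonal-regression line, axial angle, residuals and length."""

    coords_nm: np.ndarray                  # (N, 2) columns (x_nm, y_nm)
    segment_id: int = 0
    touches_border: bool = False
    direction: Optional[np.ndarray] = None  # unit vector of the fitted line
    centroid_nm: Optional[np.ndarray] = None
    angle_deg: Optional[float] = None       # axial, in (-90, 90]
    residuals_nm: Optional[np.ndarray] = None
    length_nm: Optional[float] = None

    def __post_init__(self) -> None:
        self.coords_nm = np.asarray(self.coords_nm, dtype=float)
        if self.coords_nm.ndim != 2 or self.coords_nm.shape[1] != 2:
            raise ValueError("coords_nm must be an (N, 2) array")
        if len(self.coords_nm) < 2:
            raise ValueError("segment needs at least 2 coordinates")

    @property
    def fitted(self) -> bool:
        return self.residuals_nm is not None

    @property
    def mean_squared_residual_nm2(self) -> float:
        if not self.fitted:
            raise ValueError("segment not fitted")
        return float(np.mean(self.residuals_nm**2))


@dataclass
class FractureResult:
    fracture_area_nm2: float
    reference_angle_deg: float
    per_segment: list                      # (id, msr_nm2, dtheta_deg, weight, contribution_nm2, length_nm)
    n_segments: int
    provenance: dict = field(default_factory=dict)


def _axial_wrap(angle_deg: float) -> float:
    """Map an angle to the axial range (-90, 90]."""
    a = (angle_deg + 90.0) % 180.0 - 90.0
    return 90.0 if a == -90.0 else a


def _axial_mean_deg(angles_deg: np.ndarray, weights: np.ndarray) -> float:
    """Length-weighted axial (period-180) circular mean via angle doubling."""
    two = np.radians(2.0 * np.asarray(angles_deg))
    s = float(np.sum(weights * np.sin(two)))
    c = float(np.sum(weights * np.cos(two)))
    return _axial_wrap(np.degrees(0.5 * np.arctan2(s, c)))


def _refine_subpixel(response, coords_nm, normal, nm_per_px):
    """Shift each skeleton coordinate along the ridge normal by the apex of
    a parabola through the response at offsets (-1, 0, +1) px, removing the
    quantisation bias of integer-pixel paths."""
    h, w = response.shape
    pts_px = coords_nm / nm_per_px

    def sample(offset_px):
        p = pts_px + offset_px * normal
        rc = np.vstack([np.clip(p[:, 1], 0, h - 1), np.clip(p[:, 0], 0, w - 1)])
        return map_coordinates(response, rc, order=1)

    r_m, r_0, r_p = sample(-1.0), sample(0.0), sample(+1.0)
    denom = r_m - 2.0 * r_0 + r_p
    with np.errstate(divide="ignore", invalid="ignore"):
        shift = 0.5 * (r_m - r_p) / denom
    shift = np.where(np.abs(denom) > 1e-12, shift, 0.0)
    shift = np.clip(shift, -1.0, 1.0)
    return coords_nm + (shift[:, None] * nm_per_px) * normal[None, :]


def _is_dark_line(smoothed_inverted, coords_nm, normal, nm_per_px,
                  probe_offset_nm: float = 60.0, min_contrast: float = 0.02) -> bool:
    """True when the path is a genuine dark line (intensity dip on BOTH
    sides along the normal), rejecting step-edge shoulders which are darker
    on one side only. Operates on the inverted, smoothed image."""
    n = len(coords_nm)
    idx = np.linspace(0, n - 1, min(n, 15)).astype(int)
    pts_px = coords_nm[idx] / nm_per_px          # (x, y) in px
    off_px = (probe_offset_nm / nm_per_px) * normal
    h, w = smoothed_inverted.shape

    def sample(points_px):
        rc = np.vstack([
            np.clip(points_px[:, 1], 0, h - 1),
            np.clip(points_px[:, 0], 0, w - 1),
        ])
        return map_coordinates(smoothed_inverted, rc, order=1)

    center = sample(pts_px)
    left = sample(pts_px - off_px)
    right = sample(pts_px + off_px)
    # inverted image: a dark line is a ridge, so the centre must exceed both
    # flanks by the contrast margin (in normalised units)
    return bool(
        np.median(center - left) > min_contrast
        and np.median(center - right) > min_contrast
    )


def segment_zdisks(
    img: Micrograph,
    smoothing_sigma_px: float | None = None,
    smoothing_sigma_nm: float = defaults.SMOOTHING_SIGMA_NM,
    ridge_threshold_quantile: float | None = None,
    min_length_nm: float = defaults.MIN_SEGMENT_LENGTH_NM,
    orientation_gate_deg: float = defaults.ORIENTATION_GATE_DEG,
) -> list:
    """Isolate dark transverse ridges as 1-px-wide skeleton paths.

    Filter chain: intensity inversion -> Gaussian smoothing -> ridge response
    (negated smallest Hessian eigenvalue) -> threshold -> morphological
    closing -> skeletonization -> connected components -> length and
    orientation gating. Coordinates are returned in nm with the line fit
    left for :func:`fit_segment_line`.

    The threshold defaults to Otsu's method on the positive ridge response,
    which adapts to the (strongly bimodal) ridge-vs-background separation;
    pass ``ridge_threshold_quantile`` to use a fixed quantile instead.

    Returns an empty list (with a warning) when nothing passes the filters.
    """
    pix = img.pixels
    lo, hi = pix.min(), pix.max()
    if hi <= lo:
        warnings.warn("constant-intensity image: no ridges found")
        return []
    # smoothing is calibrated in nm so scores covary with pixel size
    if smoothing_sigma_px is None:
        smoothing_sigma_px = max(1.0, smoothing_sigma_nm / img.nm_per_px)
    inv = (hi - pix) / (hi - lo)
    sm = gaussian_filter(inv, smoothing_sigma_px)

    helems = hessian_matrix(sm, sigma=1.0, order="rc", use_gaussian_derivatives=False)
    eigs = hessian_matrix_eigvals(helems)
    response = np.clip(-eigs[-1], 0.0, None)  # bright ridges: strongly negative eigenvalue
    # derivative filters ring at the image edge; blank a thin border band so
    # the artifact frame cannot bridge distinct ridges
    border = int(np.ceil(2.0 * smoothing_sigma_px + 2.0))
    response[:border, :] = 0.0
    response[-border:, :] = 0.0
    response[:, :border] = 0.0
    response[:, -border:] = 0.0
    if not np.any(response > 0):
        warnings.warn("no ridge response above zero")
        return []

    pos = response[response > 0]
    if ridge_threshold_quantile is not None:
        thr = np.quantile(pos, ridge_threshold_quantile)
    elif pos.min() == pos.max():
        thr = pos.min() / 2.0
    else:
        thr = threshold_otsu(pos)
    mask = response > thr
    # drop isolated noise speckle before closing so it cannot bridge ridges
    min_px = max(4, int(0.25 * min_length_nm / img.nm_per_px))
    mask = remove_small_objects(mask, max_size=min_px - 1)
    mask = closing(mask)
    skel = skeletonize(mask)

    labels = cc_label(skel, connectivity=2)
    nmpp = img.nm_per_px
    h, w = pix.shape

    candidates = []
    for lab in range(1, labels.max() + 1):
        rows, cols = np.nonzero(labels == lab)
        if len(rows) < 2:
            continue
        coords = np.column_stack([cols * nmpp, rows * nmpp])
        c = coords - coords.mean(axis=0)
        _, _, vt = np.linalg.svd(c, full_matrices=False)
        coords = _refine_subpixel(response, coords, vt[1], nmpp)
        c = coords - coords.mean(axis=0)
        proj = c @ vt[0]
        # skeleton endpoints are unreliable (branch stubs); trim 2 px per end
        keep = (proj >= proj.min() + 2 * nmpp) & (proj <= proj.max() - 2 * nmpp)
        if keep.sum() < 2:
            continue
        coords = coords[keep]
        length = float(proj[keep].max() - proj[keep].min())
        if length < min_length_nm:
            continue
        if not _is_dark_line(sm, coords, vt[1], nmpp):
            continue  # edge shoulder (e.g. A-band border), not a dark line
        angle = _axial_wrap(np.degrees(np.arctan2(vt[0, 1], vt[0, 0])))
        border = bool(
            rows.min() == 0 or cols.min() == 0 or rows.max() == h - 1 or cols.max() == w - 1
        )
        candidates.append((coords, length, angle, border))

    if not candidates:
        warnings.warn("no ridge passed the length filter")
        return []

    lengths = np.array([c[1] for c in candidates])
    angles = np.array([c[2] for c in candidates])
    dominant = _axial_mean_deg(angles, lengths)

    segments = []
    sid = 0
    for coords, length, angle, border in candidates:
        dtheta = abs(_axial_wrap(angle - dominant))
        if dtheta > orientation_gate_deg:
            continue
        segments.append(
            ZDiskSegment(coords_nm=coords, segment_id=sid, touches_border=border)
        )
        sid += 1
    if not segments:
        warnings.warn("no ridge passed the orientation gate")
    return segments


def fit_segment_line(seg: ZDiskSegment) -> ZDiskSegment:
    """Fill in the orthogonal-regression line of a segment, in place.

    The line is the first principal direction of the coordinate scatter
    through the centroid; residuals are signed orthogonal distances, so the
    mean signed residual is zero by construction. The angle is reported
    axially (period 180 deg).
    """
    coords = seg.coords_nm
    if len(np.unique(coords, axis=0)) < 2:
        raise ValueError("degenerate segment: all coordinates identical")
    centroid = coords.mean(axis=0)
    c = coords - centroid
    _, svals, vt = np.linalg.svd(c, full_matrices=False)
    if svals[0] == 0:
        raise ValueError("degenerate segment: zero scatter")
    direction = vt[0]
    normal = vt[1] if vt.shape[0] > 1 else np.array([-direction[1], direction[0]])
    proj = c @ direction
    seg.direction = direction
    seg.centroid_nm = centroid
    seg.angle_deg = _axial_wrap(float(np.degrees(np.arctan2(direction[1], direction[0]))))
    seg.residuals_nm = c @ normal
    seg.length_nm = float(proj.max() - proj.min())
    if seg.length_nm <= 0:
        raise ValueError("degenerate segment: zero extent along fitted line")
    return seg


def fracture_area(
    segments: list,
    theta_ref_deg: float = defaults.THETA_REF_DEG,
    weight_mode: str = "affine",
) -> FractureResult:
    """Length-weighted, angle-weighted average of mean squared residuals.

    Per segment i with mean squared orthogonal residual MSR_i, axial angular
    deviation dtheta_i from the length-weighted mean orientation, and weight

        affine (default):  w_i = 1 + |dtheta_i| / theta_ref
        radians:           w_i = 1 + |dtheta_i| in radians

    the score is sum(L_i * MSR_i * w_i) / sum(L_i), in nm^2. Zero for
    straight parallel lines; increases with both waviness and angular spread.
    """
    if not segments:
        raise ValueError("no Z-disks to score")
    for seg in segments:
        if not seg.fitted:
            raise ValueError(f"segment {seg.segment_id} not fitted")
    if theta_ref_deg <= 0:
        raise ValueError("theta_ref_deg must be positive")

    lengths = np.array([s.length_nm for s in segments])
    angles = np.array([s.angle_deg for s in segments])
    ref = _axial_mean_deg(angles, lengths)

    per_segment = []
    contribs = np.empty(len(segments))
    for i, seg in enumerate(segments):
        dtheta = _axial_wrap(seg.angle_deg - ref)
        if weight_mode == "affine":
            w = 1.0 + abs(dtheta) / theta_ref_deg
        elif weight_mode == "radians":
            w = 1.0 + abs(np.radians(dtheta))
        else:
            raise ValueError(f"unknown weight mode {weight_mode!r}")
        msr = seg.mean_squared_residual_nm2
        contribs[i] = msr * w
        per_segment.append((seg.segment_id, msr, dtheta, w, contribs[i], seg.length_nm))

    fa = float(np.sum(lengths * contribs) / np.sum(lengths))
    return FractureResult(
        fracture_area_nm2=fa,
        reference_angle_deg=ref,
        per_segment=per_segment,
        n_segments=len(segments),
        provenance={"theta_ref_deg": theta_ref_deg, "weight_mode": weight_mode},
    )


def save_overlay(img: Micrograph, segments: list, path) -> None:
    """QC overlay: segment pixel paths and their fitted lines over the image."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    nmpp = img.nm_per_px
    fig, ax = plt.subplots(figsize=(8, 8 * img.pixels.shape[0] / img.pixels.shape[1]))
    ax.imshow(img.pixels, cmap="gray", interpolation="nearest")
    for seg in segments:
        ax.plot(seg.coords_nm[:, 0] / nmpp, seg.coords_nm[:, 1] / nmpp,
                ".", ms=1, label=f"segment {seg.segment_id}")
        if seg.fitted:
            half = seg.length_nm / 2.0
            p0 = (seg.centroid_nm - half * seg.direction) / nmpp
            p1 = (seg.centroid_nm + half * seg.direction) / nmpp
            ax.plot([p0[0], p1[0]], [p0[1], p1[1]], "-", lw=0.8)
    ax.set_axis_off()
    fig.savefig(path, dpi=150, bbox_inches="tight")
    plt.close(fig)


def per_segment_table(result: FractureResult):
    """Per-segment scores as a pandas DataFrame (for the CSV output)."""
    import pandas as pd

    return pd.DataFrame(
        result.per_segment,
        columns=["segment_id", "msr_nm2", "dtheta_deg", "weight",
                 "contribution_nm2", "length_nm"],
    )


def score_image(
    img: Micrograph,
    smoothing_sigma_px: float | None = None,
    ridge_threshold_quantile: float | None = None,
    min_length_nm: float = defaults.MIN_SEGMENT_LENGTH_NM,
    orientation_gate_deg: float = defaults.ORIENTATION_GATE_DEG,
    theta_ref_deg: float = defaults.THETA_REF_DEG,
    weight_mode: str = "affine",
    exclude_ids: Optional[list] = None,
    drop_border: bool = False,
) -> FractureResult:
    """segment -> fit -> score, with optional semi-automatic curation.

    ``exclude_ids`` drops individual segments by id (recorded in
    provenance); ``drop_border`` removes segments touching the image border.
    """
    segments = segment_zdisks(
        img,
        smoothing_sigma_px=smoothing_sigma_px,
        ridge_threshold_quantile=ridge_threshold_quantile,
        min_length_nm=min_length_nm,
        orientation_gate_deg=orientation_gate_deg,
    )
    excluded = set(exclude_ids or [])
    kept = []
    for seg in segments:
        if seg.segment_id in excluded:
            continue
        if drop_border and seg.touches_border:
            continue
        kept.append(fit_segment_line(seg))
    result = fracture_area(kept, theta_ref_deg=theta_ref_deg, weight_mode=weight_mode)
    result.provenance.update(
        {
            "excluded_ids": sorted(excluded),
            "drop_border": drop_border,
            "n_candidates": len(segments),
            "smoothing_sigma_px": smoothing_sigma_px,
            "ridge_threshold_quantile": ridge_threshold_quantile,
            "min_length_nm": min_length_nm,
            "orientation_gate_deg": orientation_gate_deg,
        }
    )
    return result
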