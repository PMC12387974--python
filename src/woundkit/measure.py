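"""Wound surface area and depth from a depth map plus wound mask.

Area is the sum of per-pixel metric footprints over the wound mask, with
an optional angle adjustment: when the surrounding skin plane is tilted
by theta relative to the image plane, the summed (projected) area is
divided by cos(theta) to recover the true oblique area.

Depth follows the reference-surface construction: a plane is fitted to
the back-projected boundary ring of healthy skin around the wound
(estimating the intact-skin level prior to injury), every wound pixel's
signed distance along the plane normal is computed (positive = below
skin), and the reported depth DF is the extremum of largest magnitude —
negative when an elevation (hyper-granulation growth) dominates.  The
sensor class resolves depth only to +/- 3 mm, so magnitudes under 3 mm
are reported as a sentinel ("+/-3") rather than a number.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np
from scipy import ndimage

from .geometry import (CameraModel, DepthMap, GeometryError, Plane,
                       backproject_grid, fit_plane, pixel_footprint)
from .segmentation.maps import TissueFractions, TissueMap, tissue_fractions

#: depth-resolution floor of the sensor class, mm
DEPTH_SENTINEL_MM = 3.0
#: default boundary-ring width for the reference surface, px
DEFAULT_RING_WIDTH_PX = 5
#: minimum valid depth pixels in the boundary ring for a plane fit
MIN_RING_POINTS = 30
#: text rendering of the sub-resolution sentinel in reports
SENTINEL_TEXT = "+/-3"


class MeasurementError(ValueError):
    """Raised when a measurement precondition fails."""


@dataclass(frozen=True)
class AreaResult:
    area_cm2: float
    n_pixels: int
    mean_footprint_mm2: float
    tilt_correction_applied: bool
    tilt_deg: float


@dataclass(frozen=True)
class DepthResult:
    """Estimated wound depth DF.

    depth_mm is signed (negative = growth above skin level) and set to
    0.0 when sentinel is true, i.e. the underlying extremum magnitude is
    below the 3 mm resolution floor.
    """

    depth_mm: float
    sentinel: bool
    deepest_pixel: Tuple[int, int]
    reference_plane: Plane

    def display(self) -> str:
        return SENTINEL_TEXT if self.sentinel else f"{self.depth_mm:.1f}"


def _check_aligned(mask: np.ndarray, depth: DepthMap) -> np.ndarray:
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != depth.shape:
        raise MeasurementError(
            f"mask shape {mask.shape} does not match depth map {depth.shape}")
    return mask


def compute_wound_area(mask: np.ndarray, depth: DepthMap, cam: CameraModel,
                       angle_adjust: bool = True,
                       ring_width_px: int = DEFAULT_RING_WIDTH_PX) -> AreaResult:
    """Metric wound surface area in cm^2.

    Sums pixel_footprint(range) over wound pixels; with angle_adjust,
    divides by cos(tilt) of the surrounding-skin plane to undo
    projective foreshortening of a tilted wound.  Missing depth inside
    the mask is tolerated up to 20% (those pixels get the mean footprint
    of the valid ones); above that the measurement is refused.
    """
    mask = _check_aligned(mask, depth)
    n = int(mask.sum())
    if n == 0:
        return AreaResult(0.0, 0, 0.0, False, 0.0)
    valid = mask & depth.valid & (depth.values > 0)
    n_missing = n - int(valid.sum())
    if n_missing > 0.2 * n:
        raise MeasurementError(
            f"{n_missing}/{n} wound pixels lack a depth return (> 20%)")
    feet = pixel_footprint(depth.values[valid], cam)
    mean_foot = float(feet.mean())
    area_mm2 = float(feet.sum()) + n_missing * mean_foot
    tilt = 0.0
    applied = False
    if angle_adjust:
        try:
            plane = reconstruct_reference_surface(mask, depth, cam,
                                                  ring_width_px)
            tilt = plane.tilt_deg()
            area_mm2 /= np.cos(np.radians(tilt))
            applied = True
        except (GeometryError, MeasurementError):
            pass  # no usable skin ring: report uncorrected area
    return AreaResult(area_cm2=area_mm2 / 100.0, n_pixels=n,
                      mean_footprint_mm2=mean_foot,
                      tilt_correction_applied=applied, tilt_deg=float(tilt))


def boundary_ring(mask: np.ndarray, ring_width_px: int) -> np.ndarray:
    """Ring of healthy-skin pixels around the wound: dilation minus mask."""
    dil = ndimage.binary_dilation(mask, iterations=int(ring_width_px))
    return dil & ~mask


def reconstruct_reference_surface(
        mask: np.ndarray, depth: DepthMap, cam: CameraModel,
        ring_width_px: int = DEFAULT_RING_WIDTH_PX) -> Plane:
    """Fit the intact-skin reference plane to the wound's boundary ring.

    The ring (mask dilated by ring_width_px, minus the mask) is
    back-projected to 3-D and a total-least-squares plane is fitted.
    Fails when fewer than 30 valid ring pixels remain (e.g. the wound
    touches the image border on several sides).
    """
    mask = _check_aligned(mask, depth)
    ring = boundary_ring(mask, ring_width_px) & depth.valid
    if int(ring.sum()) < MIN_RING_POINTS:
        raise GeometryError(
            f"boundary ring has {int(ring.sum())} valid depth pixels "
            f"(need >= {MIN_RING_POINTS}); wound too close to image border?")
    pts = backproject_grid(depth, cam)[ring]
    return fit_plane(pts)


def estimate_wound_depth(mask: np.ndarray, depth: DepthMap, cam: CameraModel,
                         ring_width_px: int = DEFAULT_RING_WIDTH_PX) -> DepthResult:
    """Wound depth DF relative to the reconstructed skin surface.

    Signed distance along the reference-plane normal is computed for
    every pixel (positive = beyond the plane, i.e. a depression), the
    field is median-filtered (3x3) to suppress single-pixel range noise,
    and the extremum of largest magnitude over the wound mask is
    reported: depression positive, elevation negative, ties going to the
    depression.  Magnitudes below the 3 mm sensor floor set the sentinel
    and a depth of 0.
    """
    mask = _check_aligned(mask, depth)
    plane = reconstruct_reference_surface(mask, depth, cam, ring_width_px)
    pts = backproject_grid(depth, cam)
    signed = pts @ plane.normal - plane.offset     # (H, W), NaN when missing
    signed = np.where(depth.valid, signed, np.nan)
    filt = ndimage.median_filter(np.nan_to_num(signed), size=3)
    filt = np.where(mask & depth.valid, filt, np.nan)
    if not np.isfinite(filt).any():
        raise MeasurementError("no valid depth returns inside the wound mask")
    dmax = float(np.nanmax(filt))
    dmin = float(np.nanmin(filt))
    value = dmax if dmax >= -dmin else dmin
    idx = np.nanargmax(filt) if value == dmax else np.nanargmin(filt)
    deepest = tuple(int(x) for x in np.unravel_index(idx, filt.shape))
    if abs(value) < DEPTH_SENTINEL_MM:
        return DepthResult(0.0, True, deepest, plane)
    return DepthResult(float(value), False, deepest, plane)


def measure(mask: np.ndarray, depth: DepthMap, cam: CameraModel,
            tissue: Optional[TissueMap] = None, angle_adjust: bool = True,
            mask_source: str = "ground-truth") -> dict:
    """End-to-end measurement report: area, depth and tissue fractions.

    Returns a plain dict (JSON-serializable, stable key order via
    report_json) combining AreaResult, DepthResult and TissueFractions.
    """
    area = compute_wound_area(mask, depth, cam, angle_adjust=angle_adjust)
    try:
        dep = estimate_wound_depth(mask, depth, cam)
        depth_block = {
            "depth_mm": 0.0 if dep.sentinel else round(dep.depth_mm, 3),
            "display": dep.display(),
            "sentinel": dep.sentinel,
            "deepest_pixel": list(dep.deepest_pixel),
            "reference_plane_tilt_deg": round(dep.reference_plane.tilt_deg(), 3),
            "reference_plane_rms_mm": round(dep.reference_plane.rms_residual, 3),
        }
    except (GeometryError, MeasurementError) as exc:
        depth_block = {"error": f"depth: {exc}"}
    frac = tissue_fractions(tissue) if tissue is not None else None
    report = {
        "area": {
            "area_cm2": round(area.area_cm2, 3),
            "n_pixels": area.n_pixels,
            "mean_footprint_mm2": round(area.mean_footprint_mm2, 6),
            "tilt_correction_applied": area.tilt_correction_applied,
            "tilt_deg": round(area.tilt_deg, 3),
        },
        "depth": depth_block,
        "tissue": None if frac is None else {
            "slough_pct": round(frac.slough_pct, 2),
            "necrosis_pct": round(frac.necrosis_pct, 2),
            "wound_pixels": frac.wound_pixels,
        },
        "provenance": {"mask_source": mask_source},
    }
    return report


def report_json(report: dict) -> str:
    """Deterministic JSON rendering (sorted keys, fixed float handling)."""
    return json.dumps(report, sort_keys=True, indent=2, allow_nan=False)
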