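"""Pinhole-camera raster geometry for time-of-flight depth maps.

A depth map here is what a time-of-flight sensor actually reports: the
*range along the ray* from the optical centre to the first surface hit,
in millimetres, on a small sensor grid (192 x 256 for the device class
this package models).  Back-projection converts ranges to metric 3-D
points; a least-squares plane fitted to points around a wound gives the
reconstructed healthy-skin reference surface from which depth is read.

Conventions
-----------
* pixels are 0-based, row-major; a pixel's sample point is its centre;
* camera frame: +z along the optical axis into the scene, +x right
  (columns), +y down (rows);
* missing returns are NaN in memory (0 mm is a legal, degenerate range).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Tuple

import numpy as np
from scipy import ndimage


class GeometryError(ValueError):
    """Raised for degenerate geometry (collinear points, bad shapes...)."""


@dataclass(frozen=True)
class CameraModel:
    """Ideal pinhole camera.

    Parameters
    ----------
    focal_length_px : float
        Focal length in pixel units (square pixels assumed).
    principal_point : (float, float)
        Optical-axis piercing point as (row, col), in pixels.
    image_size : (int, int)
        Sensor grid as (rows, cols).
    camera_to_scene_distance_hint : float, optional
        Nominal working distance in mm (the device class needs > 300 mm).
    view_tilt_deg : float, optional
        Metadata: angle between optical axis and the scene normal.
    """

    focal_length_px: float
    principal_point: Tuple[float, float]
    image_size: Tuple[int, int]
    camera_to_scene_distance_hint: Optional[float] = None
    view_tilt_deg: Optional[float] = None

    def __post_init__(self) -> None:
        if not self.focal_length_px > 0:
            raise ValueError("focal_length_px must be > 0")
        rows, cols = self.image_size
        if rows < 2 or cols < 2:
            raise ValueError("image_size components must be >= 2")
        r0, c0 = self.principal_point
        if not (0 <= r0 <= rows - 1 and 0 <= c0 <= cols - 1):
            raise ValueError("principal_point must lie inside image bounds")

    @property
    def shape(self) -> Tuple[int, int]:
        return tuple(self.image_size)

    def ray_directions(self) -> np.ndarray:
        """Unit ray direction for every pixel centre, shape (H, W, 3)."""
        rows, cols = self.image_size
        r0, c0 = self.principal_point
        f = self.focal_length_px
        cc, rr = np.meshgrid(np.arange(cols), np.arange(rows))
        d = np.stack([(cc - c0) / f, (rr - r0) / f, np.ones_like(rr, float)], axis=-1)
        return d / np.linalg.norm(d, axis=-1, keepdims=True)

    def ray_scale(self) -> np.ndarray:
        """Per-pixel ratio range/z, i.e. ||((c-c0)/f, (r-r0)/f, 1)||."""
        rows, cols = self.image_size
        r0, c0 = self.principal_point
        f = self.focal_length_px
        cc, rr = np.meshgrid(np.arange(cols), np.arange(rows))
        return np.sqrt(((cc - c0) / f) ** 2 + ((rr - r0) / f) ** 2 + 1.0)


def default_camera(skin_distance: Optional[float] = 350.0) -> CameraModel:
    """The package's default sensor: 192 x 256 px, f = 210 px (~60 deg HFOV)."""
    return CameraModel(
        focal_length_px=210.0,
        principal_point=(95.5, 127.5),
        image_size=(192, 256),
        camera_to_scene_distance_hint=skin_distance,
    )


@dataclass
class DepthMap:
    """Grid of ranges along per-pixel rays, in mm; NaN marks missing returns."""

    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("DepthMap values must be a 2-D grid")
        with np.errstate(invalid="ignore"):
            if np.any(self.values[np.isfinite(self.values)] < 0):
                raise ValueError("non-missing ranges must be >= 0 mm")

    @property
    def shape(self) -> Tuple[int, int]:
        return self.values.shape

    @property
    def valid(self) -> np.ndarray:
        return np.isfinite(self.values)

    @classmethod
    def from_z_depth(cls, z: np.ndarray, cam: CameraModel) -> "DepthMap":
        """Build from a grid of z-coordinates (distance along the optical
        axis), converting to range along each pixel's ray."""
        z = np.asarray(z, dtype=float)
        if z.shape != cam.shape:
            raise GeometryError("z grid shape does not match camera")
        return cls(z * cam.ray_scale())

    def z_depth(self, cam: CameraModel) -> np.ndarray:
        """Convert ranges back to z-coordinates (NaN preserved)."""
        if self.shape != cam.shape:
            raise GeometryError("depth map shape does not match camera")
        return self.values / cam.ray_scale()


@dataclass(frozen=True)
class Plane:
    """Plane n . p = offset with unit normal; residuals of the fit kept."""

    normal: np.ndarray
    offset: float
    rms_residual: float
    n_support_points: int

    def __post_init__(self) -> None:
        object.__setattr__(self, "normal", np.asarray(self.normal, dtype=float))
        if abs(np.linalg.norm(self.normal) - 1.0) > 1e-9:
            raise ValueError("plane normal must be unit length")
        if self.n_support_points < 3:
            raise ValueError("a plane needs >= 3 support points")

    def signed_distance(self, points: np.ndarray) -> np.ndarray:
        """Signed distance of points to the plane, along +normal."""
        return np.asarray(points, float) @ self.normal - self.offset

    def tilt_deg(self) -> float:
        """Angle between the plane normal and the optical axis, degrees."""
        return float(np.degrees(np.arccos(np.clip(abs(self.normal[2]), -1, 1))))


def backproject_grid(depth: DepthMap, cam: CameraModel) -> np.ndarray:
    """Per-pixel 3-D points, shape (H, W, 3); missing pixels are NaN rows."""
    if depth.shape != cam.shape:
        raise GeometryError(
            f"depth map shape {depth.shape} does not match camera {cam.shape}"
        )
    return cam.ray_directions() * depth.values[..., None]


def backproject(depth: DepthMap, cam: CameraModel) -> Tuple[np.ndarray, np.ndarray]:
    """Back-project a depth map to metric 3-D points.

    Returns
    -------
    points : (M, 3) float array, mm
    pixels : (M, 2) int array of (row, col) indices, aligned with points
    """
    pts = backproject_grid(depth, cam)
    valid = depth.valid
    if not valid.any():
        raise GeometryError("depth map has no valid returns")
    rr, cc = np.nonzero(valid)
    return pts[rr, cc], np.stack([rr, cc], axis=1)


def project(points: np.ndarray, cam: CameraModel) -> np.ndarray:
    """Project 3-D camera-frame points to (row, col) pixel coordinates."""
    p = np.atleast_2d(np.asarray(points, float))
    z = p[:, 2]
    if np.any(z <= 0):
        raise GeometryError("cannot project points with z <= 0")
    r0, c0 = cam.principal_point
    f = cam.focal_length_px
    rc = np.stack([p[:, 1] / z * f + r0, p[:, 0] / z * f + c0], axis=1)
    return rc if np.asarray(points).ndim == 2 else rc[0]


def pixel_footprint(z, cam: CameraModel):
    """Physical area (mm^2) covered by one pixel on a fronto-parallel
    surface at z-distance ``z`` mm: (z / f)^2.  Vectorised in z."""
    z = np.asarray(z, dtype=float)
    if np.any(z <= 0):
        raise ValueError("pixel footprint requires z > 0")
    out = (z / cam.focal_length_px) ** 2
    return float(out) if out.ndim == 0 else out


def fit_plane(points: np.ndarray) -> Plane:
    """Total-least-squares plane through a point cloud.

    Orthogonal regression via eigen-decomposition of the scatter matrix:
    the normal is the eigenvector of the smallest eigenvalue, which
    minimises the sum of squared orthogonal residuals.  Symmetric in the
    coordinate axes, hence stable for steeply tilted clouds.
    """
    p = np.asarray(points, dtype=float)
    if p.ndim != 2 or p.shape[1] != 3:
        raise GeometryError("points must be (N, 3)")
    p = p[np.all(np.isfinite(p), axis=1)]
    n = len(p)
    if n < 3:
        raise GeometryError("plane fit needs >= 3 points")
    centroid = p.mean(axis=0)
    q = p - centroid
    cov = q.T @ q / n
    evals, evecs = np.linalg.eigh(cov)
    # collinear (or coincident) points: two vanishing eigenvalues
    scale = max(evals[-1], 1e-12)
    if evals[1] / scale < 1e-10:
        raise GeometryError("points are collinear; plane is not determined")
    normal = evecs[:, 0]
    # orient away from the camera (+z) when possible, else first nonzero > 0
    if normal[2] < 0 or (normal[2] == 0 and normal[(normal != 0).argmax()] < 0):
        normal = -normal
    normal = normal / np.linalg.norm(normal)
    return Plane(
        normal=normal,
        offset=float(normal @ centroid),
        rms_residual=float(np.sqrt(max(evals[0], 0.0))),
        n_support_points=n,
    )


def upsample_depth(depth: DepthMap, target_size: Tuple[int, int]) -> DepthMap:
    """Bilinear upsampling of a depth map (align-corners grid mapping).

    Output values never leave the [min, max] of the source; any target
    pixel whose bilinear support touches a missing source pixel is
    itself missing.
    """
    rows, cols = depth.shape
    trows, tcols = target_size
    if trows < rows or tcols < cols:
        raise ValueError("target size must be >= source size in both axes")
    rr = np.linspace(0.0, rows - 1.0, trows)
    cc = np.linspace(0.0, cols - 1.0, tcols)
    grid = np.meshgrid(rr, cc, indexing="ij")
    filled = np.nan_to_num(depth.values, nan=0.0)
    out = ndimage.map_coordinates(filled, grid, order=1, mode="nearest")
    support = ndimage.map_coordinates(
        depth.valid.astype(float), grid, order=1, mode="nearest"
    )
    out[support < 1.0 - 1e-9] = np.nan
    return DepthMap(out)
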