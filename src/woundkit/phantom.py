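"""Parametric wound phantoms and a time-of-flight sensor simulator.

The in-vitro phantom mirrors the adjustable-cube bench model used to
validate depth sensing on this device class: a flat "skin" plane with a
rectangular or elliptical aperture whose walls descend at a set edge
angle to a flat floor (or rise to a bump for hyper-granulation).  Moving
the cubes together narrows the aperture while deepening the wound, so
aperture, depth and edge steepness are the free parameters.

Rendering is analytic first-hit ray casting against the piecewise planar
/ quadric primitives of the phantom (skin plane, walls, floor), so
occlusion of the cavity floor by its own walls — the failure mode of
steep-edged, narrow wounds — emerges from the geometry rather than being
modelled separately.  Gaussian range noise is added per pixel, seeded.

A companion RGB renderer paints skin, granulation, slough and necrosis
with distinct colour/texture distributions and returns pixel-aligned
ground-truth masks; it stands in for the (unavailable) clinical photo
corpus when training the segmentation networks.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import ndimage

from .geometry import CameraModel, DepthMap, default_camera
from .segmentation.maps import TissueMap

_EPS = 1e-9

#: default per-pixel range noise, mm (sensor-class effective resolution
#: is +/- 3 mm; 1 mm i.i.d. noise plus estimator smoothing lands there)
DEFAULT_NOISE_SD = 1.0


@dataclass(frozen=True)
class PhantomSpec:
    """Parametric in-vitro wound scene.

    true_depth >= 0 is a cavity depth below the skin plane; a negative
    value models hyper-granulation: a bump of that height above skin.
    edge_angle_deg is wall steepness from the skin plane (90 = vertical).
    """

    skin_distance: float = 350.0
    aperture: Tuple[float, float] = (40.0, 40.0)
    true_depth: float = 10.0
    edge_angle_deg: float = 90.0
    shape: str = "rectangular"
    skin_tilt_deg: float = 0.0
    noise_sd: float = DEFAULT_NOISE_SD
    seed: int = 0
    center_offset: Tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        if not self.skin_distance > 0:
            raise ValueError("skin_distance must be > 0")
        if not (self.aperture[0] > 0 and self.aperture[1] > 0):
            raise ValueError("aperture components must be > 0")
        if not (0 < self.edge_angle_deg <= 90):
            raise ValueError("edge_angle_deg must be in (0, 90]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.shape not in ("rectangular", "elliptical"):
            raise ValueError("shape must be 'rectangular' or 'elliptical'")

    @property
    def floor_width(self) -> Tuple[float, float]:
        """Width of the flat floor along each aperture axis (clipped at 0;
        0 means the walls meet in a V before reaching true_depth)."""
        cot = _cot(self.edge_angle_deg)
        shrink = 2.0 * abs(self.true_depth) * cot
        return (max(0.0, self.aperture[0] - shrink),
                max(0.0, self.aperture[1] - shrink))


@dataclass(frozen=True)
class TissueLayout:
    """Target composition of the wound bed for the RGB renderer."""

    slough_fraction: float = 0.0
    necrosis_fraction: float = 0.0
    patch_granularity: float = 6.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.slough_fraction < 0 or self.necrosis_fraction < 0:
            raise ValueError("tissue fractions must be >= 0")
        if self.slough_fraction + self.necrosis_fraction > 1 + 1e-12:
            raise ValueError("slough + necrosis fractions must be <= 1")
        if self.patch_granularity <= 0:
            raise ValueError("patch_granularity must be > 0")


def _cot(angle_deg: float) -> float:
    return 0.0 if angle_deg == 90 else 1.0 / np.tan(np.radians(angle_deg))


@dataclass
class Scene:
    """A phantom scene: skin plane plus at most one wound.

    The surface is the height field w(u, v) over the skin plane, where
    (u, v) are planar coordinates centred on the wound and w is signed
    distance beyond the plane (away from the camera): positive in a
    cavity, negative on a bump, 0 on intact skin.
    """

    spec: PhantomSpec
    layout: Optional[TissueLayout] = None
    has_wound: bool = True

    # -- skin-plane frame -------------------------------------------------
    def frame(self):
        """Orthonormal frame (e_u, e_v, n) of the skin plane and its anchor
        point p0 (on the optical axis, skin_distance from the camera)."""
        th = np.radians(self.spec.skin_tilt_deg)
        e_u = np.array([1.0, 0.0, 0.0])
        e_v = np.array([0.0, np.cos(th), np.sin(th)])
        n = np.array([0.0, -np.sin(th), np.cos(th)])
        p0 = np.array([0.0, 0.0, self.spec.skin_distance])
        return e_u, e_v, n, p0

    def _halves(self) -> Tuple[float, float]:
        return self.spec.aperture[0] / 2.0, self.spec.aperture[1] / 2.0

    def inward_distance(self, u, v):
        """Distance from (u, v) to the aperture boundary, positive inside."""
        u = np.asarray(u, float) - self.spec.center_offset[0]
        v = np.asarray(v, float) - self.spec.center_offset[1]
        a, b = self._halves()
        if not self.has_wound:
            return np.full_like(u, -np.inf)
        if self.spec.shape == "rectangular":
            return np.minimum.reduce([a - u, a + u, b - v, b + v])
        r = np.sqrt((u / a) ** 2 + (v / b) ** 2)
        return (1.0 - r) * min(a, b)

    def height_field(self, u, v):
        """Signed surface height w(u, v): the scene's defining formula."""
        d = self.inward_distance(u, v)
        depth = self.spec.true_depth
        if not self.has_wound or depth == 0:
            return np.zeros_like(np.asarray(u, float))
        ang = self.spec.edge_angle_deg
        if ang == 90:
            mag = np.where(d > 0, abs(depth), 0.0)
        else:
            mag = np.clip(np.maximum(d, 0.0) * np.tan(np.radians(ang)),
                          0.0, abs(depth))
        return np.sign(depth) * mag

    def inside(self, u, v):
        return self.inward_distance(u, v) > 0

    # -- analytic first-hit ray casting -----------------------------------
    def ray_cast(self, cam: CameraModel):
        """Noise-free first-surface ranges for every pixel ray.

        Returns (ranges, wound_mask, uv): ranges (H, W) in mm along each
        unit ray; wound_mask flags pixels whose first hit lies inside
        the aperture; uv holds the skin-frame planar coordinates of the
        hit points, shape (H, W, 2).
        """
        spec = self.spec
        e_u, e_v, n, p0 = self.frame()
        if spec.true_depth < 0 and abs(spec.true_depth) >= p0 @ n:
            raise ValueError("camera lies inside the scene geometry")
        dirs = cam.ray_directions()          # (H, W, 3), unit
        au = dirs @ e_u
        av = dirs @ e_v
        aw = dirs @ n
        if np.any(aw <= 1e-9):
            raise ValueError("scene is not within the camera field of view")
        cu, cv = spec.center_offset
        bu, bv_off = -(p0 @ e_u) - cu, -(p0 @ e_v) - cv
        bw = -(p0 @ n)
        # u'(t) = au*t + bu ; v'(t) = av*t + bv_off ; w(t) = aw*t + bw
        cands = [self._t_skin(au, av, aw, bu, bv_off, bw)]
        if self.has_wound and spec.true_depth != 0:
            if spec.shape == "rectangular":
                cands += self._t_rect_walls(au, av, aw, bu, bv_off, bw)
            else:
                cands.append(self._t_ellipse_wall(au, av, aw, bu, bv_off, bw))
            cands.append(self._t_floor(au, av, aw, bu, bv_off, bw))
        t = np.nanmin(np.stack(cands), axis=0)
        if not np.all(np.isfinite(t)):
            raise ValueError("some rays miss the scene surface")
        uu = au * t + bu + cu
        vv = av * t + bv_off + cv
        if self.has_wound:
            # a wound pixel's first hit is inside the aperture or off the
            # skin level (vertical-wall hits sit exactly on the boundary)
            ww = aw * t + bw
            mask = self.inside(uu, vv) | (np.abs(ww) > 1e-7)
        else:
            mask = np.zeros(t.shape, bool)
        return t, mask, np.stack([uu, vv], axis=-1)

    def _t_skin(self, au, av, aw, bu, bv, bw):
        t = -bw / aw
        bad = t <= 0
        if self.has_wound and self.spec.true_depth != 0:
            uu, vv = au * t + bu, av * t + bv
            bad |= self._inward_local(uu, vv) > _EPS
        return np.where(bad, np.nan, t)

    def _inward_local(self, u, v):
        a, b = self._halves()
        if self.spec.shape == "rectangular":
            return np.minimum.reduce([a - u, a + u, b - v, b + v])
        return (1.0 - np.sqrt((u / a) ** 2 + (v / b) ** 2)) * min(a, b)

    def _depth_caps(self):
        spec = self.spec
        sg = 1.0 if spec.true_depth >= 0 else -1.0
        return sg, abs(spec.true_depth), _cot(spec.edge_angle_deg)

    def _t_rect_walls(self, au, av, aw, bu, bv, bw):
        a, b = self._halves()
        sg, dep, cot = self._depth_caps()
        out = []
        # each wall: lim - xi(t) = sg * w(t) * cot  (xi is +/-u' or +/-v')
        walls = [(au, bu, a, 1.0), (au, bu, a, -1.0),
                 (av, bv, b, 1.0), (av, bv, b, -1.0)]
        for axis_a, axis_b, lim, sign in walls:
            denom = sign * axis_a + sg * cot * aw
            with np.errstate(divide="ignore", invalid="ignore"):
                t = (lim - sign * axis_b - sg * cot * bw) / denom
            uu, vv, ww = au * t + bu, av * t + bv, aw * t + bw
            d_this = lim - sign * (uu if axis_a is au else vv)
            d_all = np.minimum.reduce([a - uu, a + uu, b - vv, b + vv])
            ok = ((t > 0) & (np.abs(denom) > 1e-12)
                  & (sg * ww >= -1e-7) & (sg * ww <= dep + 1e-7)
                  & (d_this <= d_all + 1e-7))
            out.append(np.where(ok, t, np.nan))
        return out

    def _t_ellipse_wall(self, au, av, aw, bu, bv, bw):
        a, b = self._halves()
        sg, dep, cot = self._depth_caps()
        k = cot / min(a, b)
        # r(t) = 1 - sg*k*w(t);  (u/a)^2 + (v/b)^2 = r^2  -> quadratic in t
        pu, qu = au / a, bu / a
        pv, qv = av / b, bv / b
        w1, w0 = -sg * k * aw, 1.0 - sg * k * bw
        A = pu * pu + pv * pv - w1 * w1
        B = 2 * (pu * qu + pv * qv - w1 * w0)
        C = qu * qu + qv * qv - w0 * w0
        with np.errstate(divide="ignore", invalid="ignore"):
            disc = B * B - 4 * A * C
            sq = np.sqrt(np.where(disc >= 0, disc, np.nan))
            roots = [(-B - sq) / (2 * A), (-B + sq) / (2 * A), -C / B]
        wmax = dep if cot == 0 else min(dep, min(a, b) / cot)
        best = np.full(au.shape, np.nan)
        for i, t in enumerate(roots):
            lin = np.abs(A) < 1e-14
            t = np.where(lin if i == 2 else ~lin, t, np.nan)
            ww = aw * t + bw
            r = 1.0 - sg * k * ww
            ok = ((t > 0) & (sg * ww >= -1e-7) & (sg * ww <= wmax + 1e-7)
                  & (r >= -1e-9) & (r <= 1 + 1e-7))
            if cot == 0:  # vertical cylinder wall: r == 1 by construction
                ok &= sg * ww <= dep + 1e-7
            t = np.where(ok, t, np.nan)
            best = np.fmin(best, t)
        return best

    def _t_floor(self, au, av, aw, bu, bv, bw):
        sg, dep, cot = self._depth_caps()
        t = (sg * dep - bw) / aw
        uu, vv = au * t + bu, av * t + bv
        ok = (t > 0) & (self._inward_local(uu, vv) >= dep * cot - 1e-7)
        return np.where(ok, t, np.nan)


def make_cavity_scene(spec: PhantomSpec,
                      layout: Optional[TissueLayout] = None) -> Scene:
    """Build the adjustable-cube phantom scene (cavity, or bump when
    true_depth < 0) with an optional tissue layout for RGB rendering."""
    return Scene(spec=spec, layout=layout, has_wound=True)


def make_skin_scene(spec: PhantomSpec) -> Scene:
    """A wound-free scene: intact skin only (negative training examples)."""
    return Scene(spec=spec, layout=None, has_wound=False)


def render_lidar(scene: Scene, cam: Optional[CameraModel] = None,
                 noise_sd: Optional[float] = None,
                 seed: Optional[int] = None) -> DepthMap:
    """Render the scene to a range map with seeded Gaussian noise.

    noise_sd / seed default to the values in the scene's PhantomSpec.
    Deterministic for a fixed seed.
    """
    cam = cam or default_camera(scene.spec.skin_distance)
    sd = scene.spec.noise_sd if noise_sd is None else noise_sd
    seed = scene.spec.seed if seed is None else seed
    ranges, _, _ = scene.ray_cast(cam)
    if sd > 0:
        rng = np.random.default_rng(seed)
        ranges = ranges + rng.normal(0.0, sd, size=ranges.shape)
    return DepthMap(np.maximum(ranges, 0.0))


def render_ground_truth_mask(scene: Scene, cam: CameraModel) -> np.ndarray:
    """Wound mask at the given camera's resolution (first-hit geometry)."""
    _, mask, _ = scene.ray_cast(cam)
    return mask


# -- RGB rendering ---------------------------------------------------------

#: per-class mean colour (R, G, B) and texture noise sd, 8-bit scale
RGB_CLASS_COLORS = {
    "skin": ((205.0, 170.0, 145.0), 9.0),
    "granulation": ((168.0, 58.0, 52.0), 11.0),
    "slough": ((221.0, 205.0, 126.0), 12.0),
    "necrosis": ((48.0, 34.0, 28.0), 8.0),
}
#: multiplicative lighting-gradient amplitude across the frame
RGB_LIGHTING_AMPLITUDE = 0.12


def default_rgb_camera(size: int = 128) -> CameraModel:
    """Square camera used for synthetic wound photos (training corpus).

    The focal length frames the wound the way clinical photos do: a
    40 mm wound at 375 mm spans roughly half the image width."""
    c = (size - 1) / 2.0
    return CameraModel(focal_length_px=size * 430.0 / 128.0,
                       principal_point=(c, c), image_size=(size, size))


def _tissue_labels(wound_mask: np.ndarray, layout: TissueLayout) -> np.ndarray:
    """Patchy tissue labels inside the wound via quantile-thresholded
    smoothed Gaussian fields (fractions land on target up to pixel
    rounding; patch size set by the field correlation length)."""
    labels = np.zeros(wound_mask.shape, np.uint8)
    nw = int(wound_mask.sum())
    if nw == 0:
        return labels
    rng = np.random.default_rng(layout.seed)
    g = layout.patch_granularity
    f_nec = ndimage.gaussian_filter(rng.standard_normal(wound_mask.shape), g)
    f_slo = ndimage.gaussian_filter(rng.standard_normal(wound_mask.shape), g)
    fn = min(layout.necrosis_fraction, 1.0)
    if fn > 0:
        thr = np.quantile(f_nec[wound_mask], fn)
        labels[wound_mask & (f_nec <= thr)] = 2
    remaining = wound_mask & (labels == 0)
    nr = int(remaining.sum())
    if layout.slough_fraction > 0 and nr > 0:
        level = min(1.0, layout.slough_fraction * nw / nr)
        thr = np.quantile(f_slo[remaining], level)
        labels[remaining & (f_slo <= thr)] = 1
    return labels


def render_rgb(scene: Scene, cam: Optional[CameraModel] = None,
               seed: Optional[int] = None):
    """Render a synthetic wound photo with aligned ground truth.

    Returns (rgb uint8 (H, W, 3), wound_mask bool (H, W), TissueMap).
    Skin is beige, granulation red, slough yellow-fibrous, necrosis
    near-black; a mild lighting gradient and seeded texture noise are
    applied on top.
    """
    cam = cam or default_rgb_camera()
    layout = scene.layout or TissueLayout(seed=scene.spec.seed)
    seed = scene.spec.seed if seed is None else seed
    if scene.has_wound:
        _, wound_mask, _ = scene.ray_cast(cam)
    else:
        wound_mask = np.zeros(cam.shape, bool)
    labels = _tissue_labels(wound_mask, layout)

    rng = np.random.default_rng(seed)
    h, w = cam.shape
    img = np.empty((h, w, 3), float)
    class_of = np.zeros((h, w), np.uint8)       # 0 skin 1 gran 2 slough 3 nec
    class_of[wound_mask] = 1
    class_of[labels == 1] = 2
    class_of[labels == 2] = 3
    names = ["skin", "granulation", "slough", "necrosis"]
    for idx, name in enumerate(names):
        mean, sd = RGB_CLASS_COLORS[name]
        sel = class_of == idx
        img[sel] = mean
        img[sel] += rng.normal(0.0, sd, size=(int(sel.sum()), 3))
    # low-frequency mottle and a linear lighting gradient
    mottle = ndimage.gaussian_filter(rng.standard_normal((h, w)), 3.0) * 18.0
    img += mottle[..., None]
    ang = rng.uniform(0, 2 * np.pi)
    gx, gy = np.meshgrid(np.linspace(-1, 1, w), np.linspace(-1, 1, h))
    light = 1.0 + RGB_LIGHTING_AMPLITUDE * (np.cos(ang) * gx + np.sin(ang) * gy)
    img *= light[..., None]
    rgb = np.clip(img, 0, 255).astype(np.uint8)
    return rgb, wound_mask, TissueMap(labels=labels, wound_mask=wound_mask)


# -- dataset generation ----------------------------------------------------

DATASET_SPLITS = (0.70, 0.20, 0.10)


@dataclass
class Dataset:
    """In-memory synthetic training corpus with a split manifest."""

    images: np.ndarray        # (N, H, W, 3) uint8
    wound_masks: np.ndarray   # (N, H, W) bool
    tissue: np.ndarray        # (N, H, W) uint8 {0 other, 1 slough, 2 necrosis}
    manifest: pd.DataFrame    # id, split, spec/layout fields

    def indices(self, split: str) -> np.ndarray:
        return np.flatnonzero((self.manifest["split"] == split).to_numpy())

    def subset(self, split: str):
        idx = self.indices(split)
        return self.images[idx], self.wound_masks[idx], self.tissue[idx]


def split_sizes(n: int, split: Sequence[float] = DATASET_SPLITS):
    """Train/val/test sizes at the stated proportions, rounded; the test
    split absorbs the remainder so the sizes are exhaustive."""
    tr = int(round(split[0] * n))
    va = int(round(split[1] * n))
    return tr, va, n - tr - va


def sample_spec(rng: np.random.Generator, image_size: int = 128) -> Tuple[
        PhantomSpec, Optional[TissueLayout], bool]:
    """Draw one random study condition for the synthetic photo corpus."""
    has_wound = rng.random() >= 0.10          # ~10% intact-skin negatives
    shape = "elliptical" if rng.random() < 0.5 else "rectangular"
    spec = PhantomSpec(
        skin_distance=rng.uniform(300.0, 450.0),
        aperture=(rng.uniform(20.0, 55.0), rng.uniform(20.0, 55.0)),
        true_depth=rng.uniform(0.0, 12.0),
        edge_angle_deg=rng.uniform(40.0, 90.0),
        shape=shape,
        skin_tilt_deg=rng.uniform(0.0, 15.0),
        noise_sd=DEFAULT_NOISE_SD,
        seed=int(rng.integers(0, 2**31 - 1)),
        center_offset=(rng.uniform(-12.0, 12.0), rng.uniform(-12.0, 12.0)),
    )
    if not has_wound:
        return spec, None, False
    slough = rng.uniform(0.0, 0.7) if rng.random() > 0.15 else 0.0
    necrosis = (rng.uniform(0.0, min(0.5, 1.0 - slough))
                if rng.random() > 0.30 else 0.0)
    layout = TissueLayout(slough_fraction=slough, necrosis_fraction=necrosis,
                          patch_granularity=rng.uniform(4.0, 10.0),
                          seed=int(rng.integers(0, 2**31 - 1)))
    return spec, layout, True


def generate_dataset(n: int, seed: int = 0,
                     split: Sequence[float] = DATASET_SPLITS,
                     image_size: int = 128) -> Dataset:
    """Generate n synthetic wound photos with ground truth and a
    disjoint, exhaustive train/val/test split at the stated proportions."""
    if n < 10:
        raise ValueError("dataset generation needs n >= 10")
    rng = np.random.default_rng(seed)
    cam = default_rgb_camera(image_size)
    images = np.empty((n, image_size, image_size, 3), np.uint8)
    masks = np.empty((n, image_size, image_size), bool)
    tissue = np.empty((n, image_size, image_size), np.uint8)
    rows = []
    for i in range(n):
        spec, layout, has_wound = sample_spec(rng, image_size)
        scene = (make_cavity_scene(spec, layout) if has_wound
                 else make_skin_scene(spec))
        rgb, wmask, tmap = render_rgb(scene, cam)
        images[i], masks[i], tissue[i] = rgb, wmask, tmap.labels
        rows.append({
            "id": i, "has_wound": has_wound,
            "skin_distance": spec.skin_distance,
            "aperture_w": spec.aperture[0], "aperture_l": spec.aperture[1],
            "true_depth": spec.true_depth,
            "edge_angle_deg": spec.edge_angle_deg, "shape": spec.shape,
            "skin_tilt_deg": spec.skin_tilt_deg, "seed": spec.seed,
            "slough_fraction": layout.slough_fraction if layout else 0.0,
            "necrosis_fraction": layout.necrosis_fraction if layout else 0.0,
        })
    tr, va, te = split_sizes(n, split)
    labels = np.array(["train"] * tr + ["val"] * va + ["test"] * te)
    manifest = pd.DataFrame(rows)
    manifest["split"] = labels
    return Dataset(images=images, wound_masks=masks, tissue=tissue,
                   manifest=manifest)


# -- in-vitro depth sweep --------------------------------------------------

def default_invitro_grid(min_floor_mm: float = 4.0) -> List[Tuple[float, float, float]]:
    """The bench protocol grid: (depth, aperture, edge angle) combinations
    covering 5-35 mm depths at edge angles >= 40 deg, keeping only
    configurations whose flat floor is at least min_floor_mm wide (the
    bench model's cubes were always set so a floor remained)."""
    out = []
    for depth in (5, 10, 15, 20, 25, 30, 35):
        for aperture in (20, 35, 50):
            for angle in (40, 60, 80, 90):
                floor = aperture - 2 * depth * _cot(angle)
                if floor >= min_floor_mm:
                    out.append((float(depth), float(aperture), float(angle)))
    return out


def sweep_invitro(depths: Sequence[float], apertures: Sequence[float],
                  edge_angles: Sequence[float], repeats: int = 8,
                  seed: int = 0, noise_sd: float = DEFAULT_NOISE_SD,
                  cam: Optional[CameraModel] = None,
                  min_floor_mm: Optional[float] = None) -> pd.DataFrame:
    """Render every (depth, aperture, edge-angle) configuration `repeats`
    times with fresh noise and estimate depth on each render.

    Returns a tidy table with one row per rendered image: configuration,
    repeat index, true depth, estimated depth, sentinel flag and error.
    min_floor_mm, when given, drops configurations whose floor (clipped
    V-profile) is narrower than that.
    """
    from .measure import estimate_wound_depth

    configs = [(d, a, g) for d in depths for a in apertures for g in edge_angles]
    if min_floor_mm is not None:
        configs = [(d, a, g) for d, a, g in configs
                   if a - 2 * abs(d) * _cot(g) >= min_floor_mm]
    if not configs:
        raise ValueError("sweep grid is empty")
    cam = cam or default_camera()
    ss = np.random.SeedSequence(seed)
    seeds = ss.generate_state(len(configs) * repeats) % (2**31 - 1)
    rows = []
    i = 0
    for depth, aperture, angle in configs:
        spec = PhantomSpec(aperture=(aperture, aperture), true_depth=depth,
                           edge_angle_deg=angle, noise_sd=noise_sd)
        scene = make_cavity_scene(spec)
        ranges, mask, _ = scene.ray_cast(cam)
        for rep in range(repeats):
            rng = np.random.default_rng(int(seeds[i]))
            i += 1
            noisy = ranges + rng.normal(0, noise_sd, ranges.shape) \
                if noise_sd > 0 else ranges
            res = estimate_wound_depth(mask, DepthMap(noisy), cam)
            est = np.nan if res.sentinel else res.depth_mm
            rows.append({
                "true_depth": depth, "aperture": aperture,
                "edge_angle_deg": angle, "repeat": rep,
                "estimated_depth": est, "sentinel": res.sentinel,
                "error": est - depth if np.isfinite(est) else np.nan,
            })
    return pd.DataFrame(rows)
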