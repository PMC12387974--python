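"""Shared fixtures and the independent ray-intersection oracle."""

from __future__ import annotations

import numpy as np
import pytest

from woundkit.geometry import CameraModel, default_camera
from woundkit.phantom import PhantomSpec, Scene, make_cavity_scene


@pytest.fixture(scope="session")
def sensor_cam() -> CameraModel:
    return default_camera()


@pytest.fixture(scope="session")
def hires_cam() -> CameraModel:
    """2x the sensor camera: the resolution wound photos are masked at."""
    return CameraModel(focal_length_px=420.0, principal_point=(191.5, 255.5),
                       image_size=(384, 512))


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


def dense_first_hit(scene: Scene, cam: CameraModel, row: int, col: int,
                    t_max: float = 600.0, step: float = 0.5,
                    iters: int = 60) -> float:
    """Independent first-intersection oracle for one pixel ray.

    Walks the ray in small steps until the point first reaches the
    surface (signed height w >= surface height w_surf), then bisects.
    Uses only the scene's defining height-field formula, not the
    analytic primitive intersections of the renderer.
    """
    e_u, e_v, n, p0 = scene.frame()
    d = cam.ray_directions()[row, col]

    def below(t: float) -> bool:
        p = t * d
        u = (p - p0) @ e_u
        v = (p - p0) @ e_v
        w = (p - p0) @ n
        return w >= float(scene.height_field(np.array(u), np.array(v)))

    ts = np.arange(step, t_max, step)
    hit = None
    for t in ts:
        if below(float(t)):
            hit = float(t)
            break
    assert hit is not None, "oracle ray never reached the surface"
    lo, hi = hit - step, hit
    for _ in range(iters):
        mid = 0.5 * (lo + hi)
        if below(mid):
            hi = mid
        else:
            lo = mid
    return 0.5 * (lo + hi)
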