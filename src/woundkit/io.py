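"""File formats: palette masks, RGB images, 16-bit depth maps + sidecars.

On-disk dialects
----------------
* RGB images: 8-bit PNG/TIFF.  16-bit inputs are down-converted (with a
  logged warning) by dropping the low byte.
* Wound masks: palette PNG, 0 = background, 1 = wound.
* Tissue maps: palette PNG, 0 = other, 1 = slough, 2 = necrosis.
* Depth maps: 16-bit grayscale PNG storing mm / scale, with a JSON
  sidecar ``<name>.json`` holding
  ``{"scale_mm_per_unit", "missing_value", "focal_length_px",
  "principal_point"}``.  The default quantisation of 0.1 mm/unit is
  well below the 3 mm depth-resolution floor of the sensor class.
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
from dataclasses import asdict
from typing import Optional, Tuple

import numpy as np
from PIL import Image

from .geometry import CameraModel, DepthMap

log = logging.getLogger("woundkit")

DEFAULT_DEPTH_SCALE = 0.1       # mm per raw unit
DEFAULT_MISSING_VALUE = 65535

WOUND_MASK_PALETTE = {0: (0, 0, 0), 1: (255, 255, 255)}
TISSUE_PALETTE = {0: (60, 60, 60), 1: (230, 210, 120), 2: (40, 30, 25)}


class FormatError(ValueError):
    """Raised for malformed or unsupported files."""


def write_image(path: str, rgb: np.ndarray) -> None:
    rgb = np.asarray(rgb)
    if rgb.ndim != 3 or rgb.shape[2] != 3:
        raise FormatError("expected an (H, W, 3) RGB array")
    Image.fromarray(rgb.astype(np.uint8), mode="RGB").save(path)


def read_image(path: str) -> np.ndarray:
    img = Image.open(path)
    arr = np.asarray(img)
    if arr.dtype == np.uint16:
        log.warning("%s: 16-bit image down-converted to 8-bit", path)
        arr = (arr >> 8).astype(np.uint8)
    if arr.ndim == 2:
        arr = np.stack([arr] * 3, axis=-1)
    if arr.shape[2] == 4:
        arr = arr[..., :3]
    return arr.astype(np.uint8)


def _write_palette(path: str, labels: np.ndarray, palette: dict) -> None:
    img = Image.fromarray(labels.astype(np.uint8), mode="P")
    flat = []
    for i in range(max(palette) + 1):
        flat.extend(palette.get(i, (0, 0, 0)))
    img.putpalette(flat)
    img.save(path)


def _read_palette(path: str, n_classes: int) -> np.ndarray:
    arr = np.asarray(Image.open(path).convert("P"))
    bad = np.unique(arr[arr >= n_classes])
    if bad.size:
        raise FormatError(
            f"{path}: palette index {int(bad[0])} outside the documented "
            f"palette (0..{n_classes - 1})")
    return arr.astype(np.uint8)


def write_mask(path: str, mask: np.ndarray) -> None:
    _write_palette(path, np.asarray(mask, bool).astype(np.uint8),
                   WOUND_MASK_PALETTE)


def read_mask(path: str) -> np.ndarray:
    return _read_palette(path, 2).astype(bool)


def write_tissue(path: str, labels: np.ndarray) -> None:
    _write_palette(path, labels, TISSUE_PALETTE)


def read_tissue(path: str) -> np.ndarray:
    return _read_palette(path, 3)


def _sidecar_path(depth_path: str) -> str:
    base, _ = os.path.splitext(depth_path)
    return base + ".json"


def write_depth(path: str, depth: DepthMap, cam: CameraModel,
                scale_mm_per_unit: float = DEFAULT_DEPTH_SCALE,
                missing_value: int = DEFAULT_MISSING_VALUE) -> None:
    raw = np.round(depth.values / scale_mm_per_unit)
    raw = np.where(depth.valid, raw, missing_value)
    if np.any(raw[depth.valid] >= missing_value):
        raise FormatError("depth values overflow the 16-bit range; "
                          "increase scale_mm_per_unit")
    Image.fromarray(raw.astype(np.uint16)).save(path)
    sidecar = {
        "scale_mm_per_unit": scale_mm_per_unit,
        "missing_value": missing_value,
        "focal_length_px": cam.focal_length_px,
        "principal_point": list(cam.principal_point),
    }
    with open(_sidecar_path(path), "w") as fh:
        json.dump(sidecar, fh, sort_keys=True, indent=2)


def read_depth(path: str) -> Tuple[DepthMap, CameraModel]:
    side = _sidecar_path(path)
    if not os.path.exists(side):
        raise FormatError(f"depth map {path} has no JSON sidecar {side}")
    with open(side) as fh:
        meta = json.load(fh)
    for key in ("scale_mm_per_unit", "missing_value", "focal_length_px",
                "principal_point"):
        if key not in meta:
            raise FormatError(f"{side}: missing required field '{key}'")
    raw = np.asarray(Image.open(path), dtype=np.float64)
    values = raw * float(meta["scale_mm_per_unit"])
    values[raw == meta["missing_value"]] = np.nan
    depth = DepthMap(values)
    cam = CameraModel(focal_length_px=float(meta["focal_length_px"]),
                      principal_point=tuple(meta["principal_point"]),
                      image_size=depth.shape)
    return depth, cam


# -- scene bundles ---------------------------------------------------------

def save_scene_bundle(directory: str, rgb: np.ndarray, wound_mask: np.ndarray,
                      tissue_labels: np.ndarray, depth: DepthMap,
                      depth_cam: CameraModel, spec_fields: dict) -> None:
    """Write a phantom scene to disk: rgb.png, depth.png (+ sidecar),
    wound_mask.png, tissue.png and spec.json."""
    os.makedirs(directory, exist_ok=True)
    write_image(os.path.join(directory, "rgb.png"), rgb)
    write_mask(os.path.join(directory, "wound_mask.png"), wound_mask)
    write_tissue(os.path.join(directory, "tissue.png"), tissue_labels)
    write_depth(os.path.join(directory, "depth.png"), depth, depth_cam)
    with open(os.path.join(directory, "spec.json"), "w") as fh:
        json.dump(spec_fields, fh, sort_keys=True, indent=2)


def load_scene_bundle(directory: str):
    rgb = read_image(os.path.join(directory, "rgb.png"))
    mask = read_mask(os.path.join(directory, "wound_mask.png"))
    tissue = read_tissue(os.path.join(directory, "tissue.png"))
    depth, cam = read_depth(os.path.join(directory, "depth.png"))
    with open(os.path.join(directory, "spec.json")) as fh:
        spec = json.load(fh)
    return rgb, mask, tissue, depth, cam, spec


def config_hash(obj) -> str:
    """Short stable digest of a JSON-serializable configuration."""
    text = json.dumps(obj, sort_keys=True, default=str)
    return hashlib.sha256(text.encode()).hexdigest()[:12]
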