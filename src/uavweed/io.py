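"""Readers and writers for the pipeline's on-disk formats.

Cameras and scene configs travel as YAML, alignment models as JSON,
waypoints as CSV, and image stacks as multiband TIFF (band-interleaved,
or assembled from one single-band TIFF per lens the way multi-lens cameras
store their channels).
"""

from __future__ import annotations

import dataclasses
import glob
import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from .alignment import (
    BandAlignmentModel,
    BandParams,
    DEFAULT_BAND_CENTERS,
    MultibandStack,
)
from .mission import CameraSpec, MissionPlan

__all__ = [
    "load_camera",
    "save_camera",
    "read_stack",
    "write_stack",
    "assemble_stack",
    "load_alignment_model",
    "save_alignment_model",
    "waypoints_to_csv",
]


def load_camera(path: str | Path) -> CameraSpec:
    """Read a camera spec from YAML (field names match CameraSpec)."""
    with open(path) as fh:
        data = yaml.safe_load(fh)
    return CameraSpec(**data)


def save_camera(camera: CameraSpec, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(dataclasses.asdict(camera), fh, sort_keys=False)


def read_stack(path: str | Path,
               band_centers: tuple[float, ...] | None = None,
               bit_depth: int = 10,
               master_index: int | None = None) -> MultibandStack:
    """Read a multiband TIFF (H x W x B or B x H x W) into a stack."""
    arr = tifffile.imread(str(path))
    if arr.ndim == 2:
        arr = arr[:, :, None]
    elif arr.ndim == 3 and arr.shape[0] < min(arr.shape[1:]):
        arr = np.moveaxis(arr, 0, -1)  # planar (B, H, W) -> (H, W, B)
    b = arr.shape[2]
    if band_centers is None:
        band_centers = DEFAULT_BAND_CENTERS[:b] if b <= 6 else tuple(range(b))
    if master_index is None:
        master_index = b - 1
    return MultibandStack(pixels=arr, band_centers=tuple(band_centers),
                          bit_depth=bit_depth, master_index=master_index)


def write_stack(stack: MultibandStack, path: str | Path) -> None:
    """Write band-interleaved multiband TIFF (float stacks are kept float)."""
    px = stack.pixels
    if np.issubdtype(px.dtype, np.floating) and not np.isnan(px).any():
        if np.all(px == np.round(px)):
            px = px.astype(np.uint16 if stack.bit_depth > 8 else np.uint8)
    tifffile.imwrite(str(path), px)


def assemble_stack(pattern: str,
                   band_centers: tuple[float, ...] = DEFAULT_BAND_CENTERS,
                   bit_depth: int = 10,
                   master_index: int | None = None) -> MultibandStack:
    """Assemble per-channel single-band TIFFs (sorted glob) into one stack."""
    paths = sorted(glob.glob(pattern))
    if not paths:
        raise FileNotFoundError(f"no files match {pattern!r}")
    bands = [tifffile.imread(p) for p in paths]
    shapes = {b.shape for b in bands}
    if len(shapes) != 1:
        raise ValueError(f"channel images differ in shape: {shapes}")
    arr = np.stack(bands, axis=-1)
    if master_index is None:
        master_index = arr.shape[2] - 1
    return MultibandStack(pixels=arr, band_centers=tuple(band_centers[:arr.shape[2]]),
                          bit_depth=bit_depth, master_index=master_index)


def save_alignment_model(model: BandAlignmentModel, path: str | Path) -> None:
    data = {
        "master_index": model.master_index,
        "focal_length": model.focal_length,
        "pixel_pitch": model.pixel_pitch,
        "bands": [dataclasses.asdict(b) for b in model.bands],
    }
    with open(path, "w") as fh:
        json.dump(data, fh, indent=2)


def load_alignment_model(path: str | Path) -> BandAlignmentModel:
    with open(path) as fh:
        data = json.load(fh)
    bands = tuple(BandParams(dx=b["dx"], dy=b["dy"], rotation=b["rotation"],
                             scale=b["scale"],
                             baseline=tuple(b.get("baseline", (0.0, 0.0))))
                  for b in data["bands"])
    return BandAlignmentModel(bands=bands, master_index=data["master_index"],
                              focal_length=data.get("focal_length", 9.6),
                              pixel_pitch=data.get("pixel_pitch", 0.0052))


def waypoints_to_csv(plan: MissionPlan, path: str | Path) -> None:
    """Export the serpentine waypoint list as (x_m, y_m, alt_m, seq)."""
    df = pd.DataFrame(
        [(x, y, a, k) for k, (x, y, a) in enumerate(plan.waypoints)],
        columns=["x_m", "y_m", "alt_m", "seq"],
    )
    df.to_csv(path, index=False)
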